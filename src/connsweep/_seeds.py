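"""Deterministic seed derivation.

All stochastic stages derive their seeds from a single master seed via a
cryptographic hash of a string path, so results are reproducible and
independent of iteration order or process-level hash randomization.
"""

from __future__ import annotations

import hashlib


def derive_seed(*parts: object) -> int:
    """Derive a sub-seed (< 2**31) from a master seed and a label path.

    Parameters are stringified and joined, then hashed with SHA-256.  The
    same parts always give the same seed, on any platform.
    """
    key = "|".join(str(p) for p in parts)
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
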