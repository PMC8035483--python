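"""Shared configuration for the numbered analysis scripts.

Each script is a thin driver over :mod:`connsweep`: it reads what the
previous step wrote under ``scratch/analysis/`` (bulky intermediates) and
writes its findings as small tables under ``results/``.
"""

from __future__ import annotations

import argparse
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

DEFAULT_SEED = 1
CANDIDATE_GRID = (0.05, 0.50, 0.01)
N_NULL = 20


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED,
                        help="master seed for every stochastic step")
    args = parser.parse_args()
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    return args
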