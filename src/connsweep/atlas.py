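"""Atlas label table: 90 regions (78 cortical + 12 subcortical), AAL-style
abbreviations with hemisphere suffixes, and the default-mode flag used to
mark the seeded regions."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd


class AtlasError(ValueError):
    pass


def load_atlas_labels(path: str | Path | None = None,
                      expected_regions: int | None = None) -> pd.DataFrame:
    """Load the region label table (columns: index, name, abbreviation, class, dmn).

    With no ``path`` the packaged 90-region table is returned.  Duplicate
    abbreviations or a row count conflicting with ``expected_regions`` raise.
    """
    if path is None:
        with resources.files("connsweep.data").joinpath("aal90.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    required = {"index", "name", "abbreviation", "class", "dmn"}
    if not required.issubset(df.columns):
        raise AtlasError(f"atlas table must have columns {sorted(required)}")
    if df["abbreviation"].duplicated().any():
        dupes = df.loc[df["abbreviation"].duplicated(), "abbreviation"].tolist()
        raise AtlasError(f"duplicate abbreviations: {dupes}")
    if expected_regions is not None and len(df) != expected_regions:
        raise AtlasError(f"atlas has {len(df)} regions, expected {expected_regions}")
    if not df["class"].isin(["cortical", "subcortical"]).all():
        raise AtlasError("class must be 'cortical' or 'subcortical'")
    return df
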