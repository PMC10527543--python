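"""CSV dataset manifests: the bookkeeping backbone of the pipeline.

A manifest is a table with one row per image: its path, mask path, phenotype
class, split assignment, provenance (``real`` or ``augmented``), an optional
JSON transform record, the parent path for augmented rows, and the seed used
to generate or transform it.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["MANIFEST_COLUMNS", "SPLITS", "read_manifest", "write_manifest", "validate_manifest"]

MANIFEST_COLUMNS = [
    "path",
    "mask_path",
    "class",
    "split",
    "provenance",
    "transform",
    "parent",
    "seed",
]
SPLITS = {"train", "val", "test", "unassigned"}
PROVENANCES = {"real", "augmented"}


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    """Check structure and referential integrity; return the frame unchanged."""
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    dup = df["path"].duplicated()
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # +2: header plus 1-based
        raise ValueError(f"duplicate paths in manifest at lines {lines}")
    bad_split = ~df["split"].isin(SPLITS)
    if bad_split.any():
        lines = (df.index[bad_split] + 2).tolist()
        raise ValueError(f"invalid split values at lines {lines}")
    bad_prov = ~df["provenance"].isin(PROVENANCES)
    if bad_prov.any():
        lines = (df.index[bad_prov] + 2).tolist()
        raise ValueError(f"invalid provenance values at lines {lines}")
    aug = df[df["provenance"] == "augmented"]
    if len(aug):
        real_paths = set(df.loc[df["provenance"] == "real", "path"])
        orphans = aug[~aug["parent"].isin(real_paths)]
        if len(orphans):
            lines = (orphans.index + 2).tolist()
            raise ValueError(f"augmented rows with missing parent at lines {lines}")
    return df


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "seed" in df.columns:
        df["seed"] = pd.to_numeric(df["seed"], errors="coerce").fillna(0).astype(int)
    return validate_manifest(df)


def write_manifest(df: pd.DataFrame, path: str) -> None:
    validate_manifest(df)
    df.to_csv(path, index=False)
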