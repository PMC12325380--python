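"""Reading and writing the canonical long-format CSV."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from . import __version__
from .datatypes import OBS_COLUMNS

__all__ = ["read_long_csv", "write_long_csv"]

_DTYPES = {
    "family_id": "int64",
    "individual_id": "int64",
    "wave": "int64",
    "age": "float64",
    "wellbeing": "float64",
}


def read_long_csv(
    path, *, wellbeing_range: tuple[float, float] = (0.0, 10.0), enforce_range: bool = True
) -> pd.DataFrame:
    """Read a canonical long-format table.

    Unknown columns are preserved but ignored downstream.  Rows with
    wellbeing outside ``wellbeing_range`` are excluded with a warning
    (``df.attrs['n_excluded']`` carries the count); pass
    ``enforce_range=False`` for continuous latent scores.
    """
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    for col, dtype in _DTYPES.items():
        df[col] = df[col].astype(dtype)
    n_excluded = 0
    if enforce_range:
        lo, hi = wellbeing_range
        bad = (df["wellbeing"] < lo) | (df["wellbeing"] > hi)
        n_excluded = int(bad.sum())
        if n_excluded:
            warnings.warn(
                f"excluded {n_excluded} rows with wellbeing outside [{lo}, {hi}]",
                stacklevel=2,
            )
            df = df[~bad].reset_index(drop=True)
    df.attrs["n_excluded"] = n_excluded
    return df


def write_long_csv(df: pd.DataFrame, path, *, seed: int | None = None, metadata: dict | None = None) -> None:
    """Write the canonical columns (one header row) plus a JSON sidecar
    recording the seed and package version."""
    path = Path(path)
    out = df[OBS_COLUMNS]
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    meta = {"package": "twinwell", "version": __version__, "seed": seed, "n_rows": len(out)}
    if metadata:
        meta.update(metadata)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")
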