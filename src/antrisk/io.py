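"""CSV readers/writers with schema validation (formats documented in docs/FORMATS.md)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

TUBE_COLUMNS = ["tube_id", "x", "y", "period", "scale"]
MODEL_TABLE_COLUMNS = ["tube_id", "y", "landuse5", "road_dist", "x", "y_coord"]


def read_tubes(path) -> pd.DataFrame:
    """Read and validate a tube CSV (tube_id,x,y,period,scale)."""
    df = pd.read_csv(path)
    missing = [c for c in TUBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    scales = df["scale"].to_numpy()
    bad = ~np.isin(scales, (0, 1, 2, 3))
    if bad.any():
        row = int(np.argmax(bad))
        raise ValueError(
            f"{path}: row {row + 2} (tube_id={df['tube_id'].iloc[row]}) has "
            f"invalid severity scale {scales[row]}; must be 0-3"
        )
    return df


def write_tubes(df: pd.DataFrame, path) -> None:
    df[TUBE_COLUMNS].to_csv(path, index=False)


def read_model_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MODEL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    ybad = ~np.isin(df["y"].to_numpy(), (0, 1))
    if ybad.any():
        row = int(np.argmax(ybad))
        raise ValueError(f"{path}: row {row + 2} has non-binary y")
    if not np.isfinite(df["road_dist"].to_numpy(float)).all():
        raise ValueError(f"{path}: non-finite road_dist")
    return df


def write_model_table(df: pd.DataFrame, path) -> None:
    df[MODEL_TABLE_COLUMNS].to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
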