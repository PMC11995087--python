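"""Readers, writers and run manifests for the long-format trial CSV."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "participant", "trial", "phase", "block", "stimulus", "diameter_mm",
    "role", "reinforced", "k", "r", "size_rating", "expectancy_rating",
]

SIZE_RANGE = (0.0, 200.0)
EXPECTANCY_RANGE = (1.0, 10.0)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format trial table.

    Checks required columns, rating ranges (size on 0-200, expectancy on
    1-10) and uniqueness of (participant, trial); rows come back sorted by
    participant then trial.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty trial table")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.duplicated(subset=["participant", "trial"]).any():
        raise ValueError(f"{path}: duplicate (participant, trial) rows")
    s = df.size_rating.to_numpy(dtype=float)
    if np.any((s < SIZE_RANGE[0]) | (s > SIZE_RANGE[1])):
        raise ValueError(f"{path}: size ratings outside {SIZE_RANGE}")
    e = df.expectancy_rating.to_numpy(dtype=float)
    if np.any((e < EXPECTANCY_RANGE[0]) | (e > EXPECTANCY_RANGE[1])):
        raise ValueError(f"{path}: expectancy ratings outside {EXPECTANCY_RANGE}")
    return df.sort_values(["participant", "trial"]).reset_index(drop=True)


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_manifest(path: str | Path, **entries) -> None:
    """JSON run manifest: config, seeds, package versions, diagnostics."""
    import percgen

    manifest = {
        "percgen_version": percgen.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        **entries,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in obj.__dict__.items() if not k.startswith("_")}
    return str(obj)
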