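"""CSV/JSON output helpers.

Every tabular artefact is written twice: once at full float precision
(the machine copy) and once with presentation rounding that matches the
conventions used for reporting (correlations and CI bounds to 2 dp,
percentages to 1 dp, milliseconds and microvolts to 1 dp).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import FormatError
from .containers import EpochSet

_TWO_DP = ("rho", "p", "ci_low", "ci_high")


def round_presentation(frame: pd.DataFrame) -> pd.DataFrame:
    """Presentation copy: rho/p/CI to 2 dp, percentages to 1 dp, other
    floats to 1 dp; non-float columns untouched."""
    out = frame.copy()
    for col in out.columns:
        if not pd.api.types.is_float_dtype(out[col]):
            continue
        if col in _TWO_DP:
            out[col] = out[col].round(2)
        else:
            out[col] = out[col].round(1)
    return out


def write_tables(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named frame as ``<name>.csv`` plus a rounded
    ``<name>_presentation.csv``; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in tables.items():
        full = out_dir / f"{name}.csv"
        frame.to_csv(full, index=False, float_format="%.12g")
        pres = out_dir / f"{name}_presentation.csv"
        round_presentation(frame).to_csv(pres, index=False)
        paths += [full, pres]
    return paths


def write_epochset(epochs: EpochSet, out_dir: str | Path, stem: str = "epochs") -> tuple[Path, Path]:
    """Binary-free epoch fixture: wide CSV (one row per trial x channel)
    plus a JSON sidecar holding fs, t0_index and per-trial flags."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_trials, n_channels, n_samples = epochs.data.shape
    rows = epochs.data.reshape(n_trials * n_channels, n_samples)
    frame = pd.DataFrame(rows, columns=[f"s{k}" for k in range(n_samples)])
    frame.insert(0, "trial", np.repeat(np.arange(n_trials), n_channels))
    frame.insert(1, "channel", np.tile(epochs.channel_names, n_trials))
    csv_path = out_dir / f"{stem}.csv"
    frame.to_csv(csv_path, index=False, float_format="%.9g")

    sidecar = {
        "fs": epochs.fs,
        "t0_index": int(epochs.t0_index),
        "channel_names": list(epochs.channel_names),
        "condition": list(epochs.condition),
        "accepted": [bool(a) for a in epochs.accepted],
        "reason": list(epochs.reason),
        "rt_ms": [None if np.isnan(v) else float(v) for v in epochs.rt_ms],
        "onset_sample": (None if epochs.onset_sample is None
                         else [int(v) for v in epochs.onset_sample]),
    }
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_epochset(out_dir: str | Path, stem: str = "epochs") -> EpochSet:
    out_dir = Path(out_dir)
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"
    if not csv_path.exists() or not json_path.exists():
        raise FormatError(f"missing epoch fixture files under {out_dir}")
    meta = json.loads(json_path.read_text())
    frame = pd.read_csv(csv_path)
    n_channels = len(meta["channel_names"])
    n_trials = len(meta["condition"])
    sample_cols = [c for c in frame.columns if c.startswith("s") and c[1:].isdigit()]
    data = frame[sample_cols].to_numpy().reshape(n_trials, n_channels, len(sample_cols))
    return EpochSet(
        data=data,
        fs=meta["fs"],
        t0_index=meta["t0_index"],
        channel_names=meta["channel_names"],
        condition=np.array(meta["condition"], dtype=object),
        accepted=np.array(meta["accepted"], dtype=bool),
        reason=np.array(meta["reason"], dtype=object),
        rt_ms=np.array([np.nan if v is None else v for v in meta["rt_ms"]]),
        onset_sample=(None if meta.get("onset_sample") is None
                      else np.array(meta["onset_sample"], dtype=int)),
    )
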