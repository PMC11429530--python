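"""Trial classification and behavioural summary measures.

A Go trial is valid when the first button press after stimulus onset lands
strictly inside (100, 600) ms; presses at <= 100 ms are fast-RT errors, at
>= 600 ms slow-RT errors (the closed inequalities as printed), and absent
presses within the SOA window are omissions.  A NoGo trial is valid when no
press occurs within the SOA window; otherwise it is a commission error.

Error percentages are computed over the full trial log of the relevant
condition; mean RT and RT variability (SD, n-1 denominator) are computed
over the RTs of Go trials that survived preprocessing ("assessed" trials).
Only the first press within an SOA window counts; later presses are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

GO_CATEGORIES = ("valid_go", "omission", "fast_rt", "slow_rt")
NOGO_CATEGORIES = ("valid_nogo", "commission")

FAST_RT_MS = 100.0
SLOW_RT_MS = 600.0


@dataclass(frozen=True)
class TrialClass:
    condition: str        # "Go" | "NoGo"
    category: str
    rt_ms: float | None   # first press latency within the SOA window


def classify_trials(events: pd.DataFrame, responses: pd.DataFrame,
                    soa_ms: float, fs: float) -> list[TrialClass]:
    """Classify every trial in the event log.

    ``events`` needs columns onset_sample and condition; ``responses``
    needs press_sample.  Events must be sorted by onset.
    """
    onsets = events["onset_sample"].to_numpy()
    if len(onsets) > 1 and (np.diff(onsets) < 0).any():
        raise InvalidInputError("events must be sorted by onset")
    presses = np.sort(responses["press_sample"].to_numpy()) if len(responses) else np.array([])
    soa_samples = soa_ms * fs / 1000.0

    out: list[TrialClass] = []
    for onset, condition in zip(onsets, events["condition"]):
        in_window = presses[(presses > onset) & (presses < onset + soa_samples)]
        rt_ms = (in_window[0] - onset) * 1000.0 / fs if len(in_window) else None
        if condition == "Go":
            if rt_ms is None:
                category = "omission"
            elif rt_ms <= FAST_RT_MS:
                category = "fast_rt"
            elif rt_ms >= SLOW_RT_MS:
                category = "slow_rt"
            else:
                category = "valid_go"
        elif condition == "NoGo":
            category = "valid_nogo" if rt_ms is None else "commission"
        else:
            raise InvalidInputError(f"unknown condition {condition!r}")
        out.append(TrialClass(condition, category, rt_ms))
    return out


@dataclass
class BehaviourSummary:
    commission_pct: float
    total_go_error_pct: float
    omission_pct: float
    fast_rt_pct: float
    slow_rt_pct: float
    mean_rt: float          # ms, NaN when no assessed Go RTs
    rt_variability: float   # ms (SD of RT), NaN when < 2 assessed Go RTs

    def to_dict(self) -> dict[str, float]:
        return {
            "commission_pct": self.commission_pct,
            "total_go_error_pct": self.total_go_error_pct,
            "omission_pct": self.omission_pct,
            "fast_rt_pct": self.fast_rt_pct,
            "slow_rt_pct": self.slow_rt_pct,
            "mean_rt": self.mean_rt,
            "rt_variability": self.rt_variability,
        }


def summarise(classes: list[TrialClass],
              assessed_go_rts: np.ndarray | list[float]) -> BehaviourSummary:
    """Behavioural measures from the full trial log plus assessed Go RTs."""
    go = [c for c in classes if c.condition == "Go"]
    nogo = [c for c in classes if c.condition == "NoGo"]

    def pct(count: int, total: int) -> float:
        return 100.0 * count / total if total else 0.0

    n_go, n_nogo = len(go), len(nogo)
    omission = sum(c.category == "omission" for c in go)
    fast = sum(c.category == "fast_rt" for c in go)
    slow = sum(c.category == "slow_rt" for c in go)
    commission = sum(c.category == "commission" for c in nogo)

    rts = np.asarray(assessed_go_rts, dtype=float)
    rts = rts[~np.isnan(rts)]
    mean_rt = float(rts.mean()) if len(rts) else float("nan")
    rt_var = float(rts.std(ddof=1)) if len(rts) > 1 else float("nan")

    return BehaviourSummary(
        commission_pct=pct(commission, n_nogo),
        total_go_error_pct=pct(omission + fast + slow, n_go),
        omission_pct=pct(omission, n_go),
        fast_rt_pct=pct(fast, n_go),
        slow_rt_pct=pct(slow, n_go),
        mean_rt=mean_rt,
        rt_variability=rt_var,
    )
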