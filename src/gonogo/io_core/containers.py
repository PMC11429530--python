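"""Central data containers shared by every pipeline stage.

All signal data are held in microvolts.  Events and responses are pandas
DataFrames keyed by sample index so they survive resampling bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..errors import InvalidInputError
from ..montage import EEG_CHANNELS, EOG_CHANNELS

EVENT_COLUMNS = ["onset_sample", "condition", "block"]
RESPONSE_COLUMNS = ["press_sample"]


@dataclass
class Recording:
    """Continuous multichannel recording in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
    fs : float
        Sampling rate, Hz.
    channel_names : list of str
        Unique labels; conventionally 19 EEG + 4 EOG (+ optional reference).
    events : DataFrame with columns onset_sample, condition, block
    responses : DataFrame with column press_sample
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))
    responses: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RESPONSE_COLUMNS))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidInputError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise InvalidInputError("channel_names length does not match data")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise InvalidInputError("channel_names must be unique")
        if self.fs <= 0:
            raise InvalidInputError("fs must be positive")
        if len(self.events) and (
            (self.events["onset_sample"] < 0).any()
            or (self.events["onset_sample"] >= self.n_samples).any()
        ):
            raise InvalidInputError("event onsets outside the recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, names: list[str]) -> np.ndarray:
        try:
            return np.array([self.channel_names.index(n) for n in names])
        except ValueError as exc:
            raise InvalidInputError(str(exc)) from None

    @property
    def eeg_index(self) -> np.ndarray:
        return self.channel_index([c for c in EEG_CHANNELS if c in self.channel_names])

    @property
    def eog_index(self) -> np.ndarray:
        return self.channel_index([c for c in EOG_CHANNELS if c in self.channel_names])

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            channel_names=list(self.channel_names),
            events=self.events.copy(),
            responses=self.responses.copy(),
        )


REJECTION_REASONS = [
    "edge",            # epoch does not fit in the recording
    "eog_dropout",     # automated surrogate for the manual EOG screen
    "extreme",         # |v| beyond the absolute threshold
    "jump",            # step between consecutive samples beyond threshold
    "flat",            # below minimum change within a sliding window
    "prestim_press",   # button press inside the prestimulus window
    "match_surplus",   # deselected during Go/NoGo trial-count matching
]


@dataclass
class EpochSet:
    """Stimulus-locked trials: data shape (n_trials, n_channels, n_samples).

    ``t0_index`` is the sample index of stimulus onset within the epoch;
    sample k carries time (k - t0_index) / fs.  Each trial carries an
    accepted flag and, when rejected, exactly one reason from
    :data:`REJECTION_REASONS`.
    """

    data: np.ndarray
    fs: float
    t0_index: int
    channel_names: list[str]
    condition: np.ndarray            # str per trial ("Go"/"NoGo")
    accepted: np.ndarray             # bool per trial
    reason: np.ndarray               # str per trial, "" iff accepted
    rt_ms: np.ndarray                # float per trial, NaN when no press
    onset_sample: np.ndarray | None = None  # provenance: onset in the recording

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidInputError("epoch data must be 3-D")
        n = self.data.shape[0]
        self.condition = np.asarray(self.condition, dtype=object)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=object)
        self.rt_ms = np.asarray(self.rt_ms, dtype=float)
        for name, arr in (("condition", self.condition), ("accepted", self.accepted),
                          ("reason", self.reason), ("rt_ms", self.rt_ms)):
            if len(arr) != n:
                raise InvalidInputError(f"{name} length does not match trial count")
        if not 0 <= self.t0_index < self.data.shape[2]:
            raise InvalidInputError("t0_index outside epoch")
        bad = [(a, r) for a, r in zip(self.accepted, self.reason)
               if (a and r != "") or (not a and r == "")]
        if bad:
            raise InvalidInputError("accepted flag and rejection reason disagree")
        if self.onset_sample is not None:
            self.onset_sample = np.asarray(self.onset_sample, dtype=int)
            if len(self.onset_sample) != n:
                raise InvalidInputError("onset_sample length does not match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return (np.arange(self.n_samples) - self.t0_index) * 1000.0 / self.fs

    def channel_index(self, names: list[str]) -> np.ndarray:
        try:
            return np.array([self.channel_names.index(n) for n in names])
        except ValueError as exc:
            raise InvalidInputError(str(exc)) from None

    @property
    def eeg_index(self) -> np.ndarray:
        return self.channel_index([c for c in EEG_CHANNELS if c in self.channel_names])

    @property
    def eog_index(self) -> np.ndarray:
        return self.channel_index([c for c in EOG_CHANNELS if c in self.channel_names])

    def accepted_mask(self, condition: str | None = None) -> np.ndarray:
        mask = self.accepted.copy()
        if condition is not None:
            mask &= self.condition == condition
        return mask

    def reject(self, index: int, reason: str) -> None:
        """Flag one trial as rejected; first reason wins."""
        if reason not in REJECTION_REASONS:
            raise InvalidInputError(f"unknown rejection reason {reason!r}")
        if self.accepted[index]:
            self.accepted[index] = False
            self.reason[index] = reason

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            channel_names=list(self.channel_names),
            condition=self.condition.copy(),
            accepted=self.accepted.copy(),
            reason=self.reason.copy(),
            rt_ms=self.rt_ms.copy(),
            onset_sample=None if self.onset_sample is None else self.onset_sample.copy(),
        )


class MeasureTable:
    """One row per subject, uniquely named measure columns.

    Thin wrapper over a DataFrame that enforces the structural invariants
    needed by the linkage stage; ``domain`` maps each column to one of
    {"EEG", "ERP-Go", "ERP-NoGo", "behaviour"}.
    """

    def __init__(self, frame: pd.DataFrame, domain: dict[str, str]):
        if frame.index.duplicated().any():
            raise InvalidInputError("duplicate subject rows")
        if frame.columns.duplicated().any():
            raise InvalidInputError("duplicate measure columns")
        missing = set(frame.columns) - set(domain)
        if missing:
            raise InvalidInputError(f"columns without a domain tag: {sorted(missing)}")
        self.frame = frame.astype(float)
        self.domain = {c: domain[c] for c in frame.columns}

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def columns_in(self, domain: str) -> list[str]:
        return [c for c in self.frame.columns if self.domain[c] == domain]

    def join(self, other: "MeasureTable") -> "MeasureTable":
        frame = self.frame.join(other.frame, how="inner")
        return MeasureTable(frame, {**self.domain, **other.domain})
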