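"""Corrected single-sided prestimulus amplitude spectra.

The estimator takes the 256-sample (500 ms at 512 Hz) prestimulus segment,
removes its mean, applies a 10% cosine-taper window (5% raised-cosine ramp
at each end, so the mean window gain is 0.95 and its reciprocal rounds to
the 1.05 window correction), zero-pads to 512 points, and computes the
single-sided DFT amplitude.  A blanket x2 correction undoes the amplitude
halving introduced by doubling the DFT length with zeros, and the x1.05
window correction restores the taper loss.  Bin spacing is fs/512 = 1 Hz;
bins 0..30 Hz are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from .errors import InvalidInputError
from .io_core.containers import EpochSet

SEGMENT_LEN = 256
PADDED_LEN = 512
TAPER_FRACTION = 0.1
N_BINS = 31  # 0..30 Hz inclusive at 1 Hz
PADDING_CORRECTION = 2.0


def taper_window(n: int = SEGMENT_LEN, fraction: float = TAPER_FRACTION) -> np.ndarray:
    """Periodic cosine-taper (Tukey) window with total taper ``fraction``."""
    return tukey(n, alpha=fraction, sym=False)


def window_correction(n: int = SEGMENT_LEN, fraction: float = TAPER_FRACTION) -> float:
    """Reciprocal of the window's mean gain (1/0.95 ~= 1.05)."""
    return 1.0 / taper_window(n, fraction).mean()


def amplitude_spectrum(segment: np.ndarray, fs: float = 512.0) -> np.ndarray:
    """31 corrected single-sided amplitudes (microvolts), DC..30 Hz.

    ``segment`` may be 1-D (``SEGMENT_LEN``,) or n-D with samples last;
    the spectrum is computed along the last axis.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.shape[-1] != SEGMENT_LEN:
        raise InvalidInputError(
            f"expected {SEGMENT_LEN}-sample segments, got {segment.shape[-1]}")
    if fs != 2 * SEGMENT_LEN:
        raise InvalidInputError("estimator is defined for fs = 512 Hz")
    # DC correction removes the window-weighted mean, so the windowed
    # segment sums exactly to zero and the DC bin vanishes identically
    w = taper_window()
    x = segment - (segment * w).sum(axis=-1, keepdims=True) / w.sum()
    x = x * w
    spectrum = np.fft.rfft(x, n=PADDED_LEN, axis=-1)
    amp = np.abs(spectrum[..., :N_BINS]) / PADDED_LEN
    amp[..., 1:] *= 2.0  # single-sided: fold the negative frequencies
    amp *= PADDING_CORRECTION * window_correction()
    return amp


def freqs() -> np.ndarray:
    """Bin centre frequencies, Hz."""
    return np.arange(N_BINS, dtype=float)


@dataclass
class SpectrumSet:
    """Mean prestimulus amplitude spectra per subject x channel x condition.

    ``amplitude`` has shape (n_subjects, n_channels, n_conditions, 31);
    conditions are ordered as in ``conditions``.
    """

    amplitude: np.ndarray
    subjects: list[str]
    channel_names: list[str]
    conditions: list[str]
    n_trials: np.ndarray  # (n_subjects, n_conditions)

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.shape != (len(self.subjects), len(self.channel_names),
                                    len(self.conditions), N_BINS):
            raise InvalidInputError("SpectrumSet amplitude shape mismatch")
        if (self.amplitude < 0).any():
            raise InvalidInputError("amplitudes must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        """Long-format (subject, channel, condition, freq, amplitude)."""
        n_s, n_c, n_k, n_f = self.amplitude.shape
        idx = pd.MultiIndex.from_product(
            [self.subjects, self.channel_names, self.conditions, freqs()],
            names=["subject", "channel", "condition", "freq"])
        return (pd.DataFrame({"amplitude": self.amplitude.reshape(-1)}, index=idx)
                .reset_index())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SpectrumSet":
        subjects = list(pd.unique(frame["subject"].astype(str)))
        channels = list(pd.unique(frame["channel"]))
        conditions = list(pd.unique(frame["condition"]))
        pivot = frame.assign(subject=frame["subject"].astype(str)).pivot_table(
            index=["subject", "channel", "condition"], columns="freq",
            values="amplitude", sort=False)
        amp = np.full((len(subjects), len(channels), len(conditions), N_BINS), np.nan)
        for (s, c, k), row in pivot.iterrows():
            amp[subjects.index(s), channels.index(c), conditions.index(k)] = row.to_numpy()
        if np.isnan(amp).any():
            raise InvalidInputError("incomplete spectrum table")
        return cls(amp, subjects, channels, conditions,
                   np.zeros((len(subjects), len(conditions)), dtype=int))


def trial_spectra(epochs: EpochSet, channels: list[str] | None = None) -> np.ndarray:
    """Per-trial prestimulus spectra, shape (n_trials, n_channels, 31)."""
    idx = epochs.eeg_index if channels is None else epochs.channel_index(channels)
    t0 = epochs.t0_index
    if t0 < SEGMENT_LEN:
        raise InvalidInputError("epochs lack a full 256-sample prestimulus segment")
    prestim = epochs.data[:, idx, t0 - SEGMENT_LEN:t0]
    return amplitude_spectrum(prestim, fs=epochs.fs)


def mean_spectra(per_subject_epochs: dict[str, EpochSet],
                 conditions: tuple[str, str] = ("Go", "NoGo")) -> SpectrumSet:
    """Within-subject mean amplitude spectra per channel and condition.

    Averages amplitude spectra (not complex spectra) over accepted trials.
    """
    subjects = list(per_subject_epochs)
    first = per_subject_epochs[subjects[0]]
    ch_names = [first.channel_names[i] for i in first.eeg_index]
    amp = np.empty((len(subjects), len(ch_names), len(conditions), N_BINS))
    n_trials = np.zeros((len(subjects), len(conditions)), dtype=int)
    for si, subject in enumerate(subjects):
        epochs = per_subject_epochs[subject]
        spectra = trial_spectra(epochs, ch_names)
        for ki, condition in enumerate(conditions):
            mask = epochs.accepted_mask(condition)
            if not mask.any():
                raise InvalidInputError(
                    f"subject {subject}: no accepted {condition} trials")
            amp[si, :, ki] = spectra[mask].mean(axis=0)
            n_trials[si, ki] = int(mask.sum())
    return SpectrumSet(amp, subjects, ch_names, list(conditions), n_trials)
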