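"""Continuous recording -> matched, artifact-free epochs.

Fixed stage order (logged): bandpass filter -> linked-ears re-reference ->
(down-sample) -> epoch extraction -> automated EOG-dropout screen ->
regression-based ocular correction -> spherical-spline channel
interpolation -> baseline correction -> three-step automatic artifact
rejection -> prestimulus-press rejection -> Go/NoGo trial-count matching.

Time-grid convention: sample k carries time k/fs relative to stimulus
onset; the default epoch spans samples k in [-256, 307] at 512 Hz
(564 samples, -500.0 to 599.6 ms) and the prestimulus segment is the
half-open [-500, 0) ms, i.e. exactly 256 samples.

Threshold semantics follow the printed strict inequalities: an epoch is
rejected when any EEG channel shows |v| > 150 uV, a between-sample step
> 50 uV, or a maximum voltage change < 0.05 uV within any 100 ms window
(per channel, independently).  Thresholds are applied post-baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import signal
from scipy.ndimage import binary_dilation, maximum_filter1d, minimum_filter1d

from . import montage
from .behaviour import classify_trials
from .errors import (
    FormatError,
    InvalidConfigError,
    InvalidInputError,
    UnsupportedOperationError,
)
from .io_core.containers import EpochSet, Recording

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.1, 30.0)
DEFAULT_WINDOW_MS = (-500.0, 600.0)
BASELINE_MS = (-100.0, 0.0)
TARGET_FS = 512.0
MAX_INTERPOLATED = 3


@dataclass(frozen=True)
class RejectionThresholds:
    extreme_abs: float = 150.0   # uV
    jump: float = 50.0           # uV between consecutive samples
    flat_delta: float = 0.05     # uV
    flat_window_ms: float = 100.0

    def __post_init__(self) -> None:
        if min(self.extreme_abs, self.jump, self.flat_delta, self.flat_window_ms) <= 0:
            raise InvalidConfigError("all rejection thresholds must be positive")


@dataclass
class EmcpModel:
    """Fitted ocular-correction model: per (EOG channel, EEG channel)
    propagation coefficients for blink and non-blink periods, plus the
    per-trial blink sample mask."""

    blink_coefficients: np.ndarray    # (n_eog, n_eeg)
    saccade_coefficients: np.ndarray  # (n_eog, n_eeg)
    blink_mask: np.ndarray            # (n_trials, n_samples) bool


# ---------------------------------------------------------------------------
# continuous-domain stages
# ---------------------------------------------------------------------------

def bandpass_zero_phase(recording: Recording, low: float = DEFAULT_BAND[0],
                        high: float = DEFAULT_BAND[1], order: int = 4) -> Recording:
    """Zero-phase Butterworth bandpass (forward-backward application)."""
    if not 0 < low < high < recording.fs / 2:
        raise InvalidConfigError(f"invalid band ({low}, {high}) at fs {recording.fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=recording.fs,
                        output="sos")
    out = recording.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    return out


def reref_linked_ears(recording: Recording, ear_channels: list[str]) -> Recording:
    """Re-reference EEG channels to the digital equivalent of linked ears.

    With both ear channels present the mean of the two is subtracted; with
    a single separately-recorded ear (the other having been the online
    reference) half of that channel is subtracted.
    """
    missing = [c for c in ear_channels if c not in recording.channel_names]
    if missing or not ear_channels:
        raise FormatError(f"missing ear channels: {missing or ear_channels}")
    idx = recording.channel_index(ear_channels)
    if len(idx) == 2:
        ref = recording.data[idx].mean(axis=0)
    elif len(idx) == 1:
        ref = recording.data[idx[0]] / 2.0
    else:
        raise FormatError("expected one or two ear channels")
    out = recording.copy()
    out.data[out.eeg_index] -= ref
    return out


def resample(recording: Recording, target_fs: float = TARGET_FS) -> Recording:
    """Anti-aliased polyphase down-sampling; event/response indices are
    rescaled to the new grid and rounded to the nearest sample."""
    if target_fs == recording.fs:
        return recording.copy()
    if target_fs > recording.fs:
        raise UnsupportedOperationError("upsampling is not supported")
    frac = Fraction(target_fs / recording.fs).limit_denominator(10000)
    out = recording.copy()
    out.data = signal.resample_poly(out.data, frac.numerator, frac.denominator, axis=1)
    ratio = target_fs / recording.fs
    out.fs = target_fs
    for frame, col in ((out.events, "onset_sample"), (out.responses, "press_sample")):
        if len(frame):
            frame[col] = np.round(frame[col].to_numpy() * ratio).astype(int)
    n = out.data.shape[1]
    out.events = out.events[out.events["onset_sample"] < n].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# epoch-domain stages
# ---------------------------------------------------------------------------

def epoch_sample_range(fs: float, window_ms=DEFAULT_WINDOW_MS) -> tuple[int, int]:
    """First/last epoch sample index relative to onset (closed range).

    The lower edge is included exactly; the upper edge is half-open so the
    last sample lies strictly before ``window_ms[1]``.
    """
    first = int(round(window_ms[0] * fs / 1000.0))
    last = int(np.ceil(window_ms[1] * fs / 1000.0)) - 1
    return first, last


def extract_epochs(recording: Recording, window_ms=DEFAULT_WINDOW_MS,
                   soa_ms: float = 1100.0) -> EpochSet:
    """Extract stimulus-locked epochs for valid Go and NoGo trials.

    Validity follows the behavioural classification (a press in the open
    (100, 600) ms window for Go; no press within the SOA for NoGo); error
    trials do not become epochs.  Onsets too close to the recording edge
    are dropped with a logged reason.
    """
    first, last = epoch_sample_range(recording.fs, window_ms)
    n_epoch = last - first + 1
    classes = classify_trials(recording.events, recording.responses, soa_ms,
                              recording.fs)
    rows, conditions, rts, onsets = [], [], [], []
    for (_, event), cls in zip(recording.events.iterrows(), classes):
        if cls.category not in ("valid_go", "valid_nogo"):
            continue
        onset = int(event["onset_sample"])
        if onset + first < 0 or onset + last >= recording.n_samples:
            logger.info("trial at sample %d dropped: epoch outside recording", onset)
            continue
        rows.append(recording.data[:, onset + first: onset + last + 1])
        conditions.append(event["condition"])
        rts.append(np.nan if cls.rt_ms is None else cls.rt_ms)
        onsets.append(onset)
    n = len(rows)
    data = np.stack(rows) if n else np.empty((0, len(recording.channel_names), n_epoch))
    epochs = EpochSet(
        data=data, fs=recording.fs, t0_index=-first,
        channel_names=list(recording.channel_names),
        condition=np.array(conditions, dtype=object),
        accepted=np.ones(n, dtype=bool),
        reason=np.array([""] * n, dtype=object),
        rt_ms=np.array(rts, dtype=float),
        onset_sample=np.array(onsets, dtype=int),
    )
    return epochs


def _window_ptp_min(data: np.ndarray, window: int) -> np.ndarray:
    """Minimum over window placements of (max - min) within each sliding
    ``window``-sample span; data shape (..., n_samples)."""
    mx = maximum_filter1d(data, size=window, axis=-1, mode="nearest")
    mn = minimum_filter1d(data, size=window, axis=-1, mode="nearest")
    left = window // 2
    right = (window - 1) // 2
    n = data.shape[-1]
    valid = slice(left, n - right)
    return (mx - mn)[..., valid].min(axis=-1)


def screen_eog_dropout(epochs: EpochSet,
                       thresholds: RejectionThresholds = RejectionThresholds()
                       ) -> EpochSet:
    """Automated surrogate for the manual pre-correction EOG screen:
    rejects trials whose EOG channels contain a flatline or a clipped
    plateau (a 100 ms span pinned at the channel's absolute maximum)."""
    out = epochs.copy()
    eog = out.data[:, out.eog_index]
    window = max(2, int(round(thresholds.flat_window_ms * out.fs / 1000.0)))
    flat = _window_ptp_min(eog, window) < thresholds.flat_delta  # (n, n_eog)
    ch_absmax = np.abs(eog).max(axis=(0, 2), keepdims=True)
    pinned = np.isclose(np.abs(eog), ch_absmax) & (ch_absmax > 0)
    clipped = maximum_filter1d((~pinned).astype(np.int8), size=window, axis=-1,
                               mode="constant", cval=1)
    plateau = (clipped == 0).any(axis=-1)
    for t in np.flatnonzero((flat | plateau).any(axis=1)):
        out.reject(t, "eog_dropout")
        logger.info("trial %d rejected: eog_dropout", t)
    return out


def detect_blinks(veog: np.ndarray, fs: float, z: float = 3.0,
                  dilate_ms: float = 50.0) -> np.ndarray:
    """Blink sample mask from vertical EOG: |v| beyond ``z`` robust SDs
    (MAD x 1.4826), dilated by +/-``dilate_ms``; shape as input."""
    flat = veog.reshape(-1)
    med = np.median(flat)
    robust_sd = 1.4826 * np.median(np.abs(flat - med))
    if robust_sd == 0:
        return np.zeros(veog.shape, dtype=bool)
    mask = np.abs(veog - med) > z * robust_sd
    width = int(round(dilate_ms * fs / 1000.0))
    if width > 0:
        structure = np.ones(2 * width + 1, dtype=bool)
        mask = np.stack([binary_dilation(row, structure=structure) for row in
                         np.atleast_2d(mask)]).reshape(mask.shape)
    return mask


def emcp_correct(epochs: EpochSet) -> tuple[EpochSet, EmcpModel]:
    """Regression-based ocular artifact correction.

    1. Blinks are detected on the bipolar vertical EOG.
    2. Condition-wise event-related averages are subtracted from both EEG
       and EOG to form residuals.
    3. Propagation coefficients are estimated by least squares of residual
       EEG on residual EOG, separately for blink and non-blink samples.
    4. Raw EEG is corrected by subtracting EOG x coefficients (blink
       coefficients within blink samples, saccade coefficients elsewhere).
    """
    out = epochs.copy()
    eeg_idx, eog_idx = out.eeg_index, out.eog_index
    eeg = out.data[:, eeg_idx]
    eog = out.data[:, eog_idx]
    n_trials, n_eeg, n_samp = eeg.shape
    n_eog = len(eog_idx)
    zeros = (np.zeros((n_eog, n_eeg)), np.zeros((n_eog, n_eeg)))

    if eog.std() == 0:
        logger.warning("zero-variance EOG: correction skipped")
        return out, EmcpModel(*zeros, np.zeros((n_trials, n_samp), dtype=bool))

    names = [out.channel_names[i] for i in eog_idx]
    veog = eog[:, names.index("VEOGU")] - eog[:, names.index("VEOGL")] \
        if {"VEOGU", "VEOGL"} <= set(names) else eog[:, 0]
    blink = detect_blinks(veog, out.fs)

    eeg_res = eeg.copy()
    eog_res = eog.copy()
    for condition in np.unique(out.condition):
        mask = out.condition == condition
        eeg_res[mask] -= eeg[mask].mean(axis=0)
        eog_res[mask] -= eog[mask].mean(axis=0)

    def _fit(sample_mask: np.ndarray) -> np.ndarray:
        if sample_mask.sum() < 10 * n_eog:
            return np.zeros((n_eog, n_eeg))
        x = eog_res.transpose(0, 2, 1)[sample_mask]   # (m, n_eog)
        y = eeg_res.transpose(0, 2, 1)[sample_mask]   # (m, n_eeg)
        if np.linalg.matrix_rank(x.T @ x) < n_eog:
            logger.warning("rank-deficient EOG residuals: coefficients zeroed")
            return np.zeros((n_eog, n_eeg))
        coeff, *_ = np.linalg.lstsq(x, y, rcond=None)
        return coeff

    b_blink = _fit(blink)
    b_sacc = _fit(~blink)

    propagated = np.einsum("tes,ec->tcs", eog, b_sacc)
    propagated_blink = np.einsum("tes,ec->tcs", eog, b_blink)
    sel = np.broadcast_to(blink[:, None, :], propagated.shape)
    out.data[:, eeg_idx] = eeg - np.where(sel, propagated_blink, propagated)
    return out, EmcpModel(b_blink, b_sacc, blink)


def _spherical_g(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    n = np.arange(1, n_terms + 1)
    coeff = np.zeros(n_terms + 1)
    coeff[1:] = (2 * n + 1) / (n ** m * (n + 1.0) ** m)
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coeff) / (4.0 * np.pi)


def interpolation_weights(good_pos: np.ndarray, bad_pos: np.ndarray,
                          m: int = 4, reg: float = 1e-5) -> np.ndarray:
    """Spherical-spline weights W (n_bad x n_good) with v_bad = W v_good."""
    g = _spherical_g(good_pos @ good_pos.T, m) + reg * np.eye(len(good_pos))
    g_bad = _spherical_g(bad_pos @ good_pos.T, m)
    n = len(good_pos)
    lhs = np.zeros((n + 1, n + 1))
    lhs[:n, :n] = g
    lhs[:n, n] = 1.0
    lhs[n, :n] = 1.0
    inv = np.linalg.inv(lhs)
    # [c; c0] = inv @ [v; 0] -> v_bad = [g_bad, 1] @ inv[:, :n] @ v
    return np.hstack([g_bad, np.ones((len(bad_pos), 1))]) @ inv[:, :n]


def interpolate_channels(epochs: EpochSet, bad_channels: list[str]) -> EpochSet:
    """Replace up to three bad EEG channels by Perrin-style spherical-spline
    estimates from the remaining scalp channels."""
    if not bad_channels:
        return epochs.copy()
    if len(bad_channels) > MAX_INTERPOLATED:
        raise InvalidInputError(
            f"at most {MAX_INTERPOLATED} channels may be interpolated, "
            f"got {len(bad_channels)}")
    eeg_names = [epochs.channel_names[i] for i in epochs.eeg_index]
    unknown = [c for c in bad_channels if c not in eeg_names]
    if unknown:
        raise InvalidInputError(f"not EEG channels: {unknown}")
    good = [c for c in eeg_names if c not in bad_channels]
    w = interpolation_weights(montage.positions(good), montage.positions(bad_channels))
    out = epochs.copy()
    good_idx = out.channel_index(good)
    bad_idx = out.channel_index(bad_channels)
    out.data[:, bad_idx] = np.einsum("bg,tgs->tbs", w, out.data[:, good_idx])
    return out


def baseline_correct(epochs: EpochSet, window_ms=BASELINE_MS) -> EpochSet:
    """Subtract the per-trial/channel mean over the half-open baseline
    window [window_ms[0], window_ms[1]) from every sample."""
    times = epochs.times_ms
    mask = (times >= window_ms[0]) & (times < window_ms[1])
    if not mask.any():
        raise InvalidConfigError(f"baseline window {window_ms} outside epoch")
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def artifact_reject_auto(epochs: EpochSet,
                         thresholds: RejectionThresholds = RejectionThresholds()
                         ) -> EpochSet:
    """Three-step automatic rejection on the EEG channels.

    A trial is rejected when any channel violates any criterion; the flag
    carries the first violated criterion in the order extreme -> jump ->
    flat.  Inequalities are strict, as printed.
    """
    out = epochs.copy()
    eeg = out.data[:, out.eeg_index]
    extreme = (np.abs(eeg) > thresholds.extreme_abs).any(axis=(1, 2))
    jump = (np.abs(np.diff(eeg, axis=2)) > thresholds.jump).any(axis=(1, 2))
    window = max(2, int(round(thresholds.flat_window_ms * out.fs / 1000.0)))
    flat = (_window_ptp_min(eeg, window) < thresholds.flat_delta).any(axis=1)
    for t in range(out.n_trials):
        if not out.accepted[t]:
            continue
        for violated, reason in ((extreme[t], "extreme"), (jump[t], "jump"),
                                 (flat[t], "flat")):
            if violated:
                out.reject(t, reason)
                logger.info("trial %d rejected: %s", t, reason)
                break
    return out


def reject_prestim_response(epochs: EpochSet, responses: pd.DataFrame) -> EpochSet:
    """Reject trials whose half-open prestimulus window [-t0, 0) samples
    contains a button press.  A press exactly at stimulus onset is kept."""
    out = epochs.copy()
    onsets = getattr(out, "onset_sample", None)
    if onsets is None:
        raise InvalidInputError("epochs lack onset_sample provenance")
    presses = responses["press_sample"].to_numpy() if len(responses) else np.array([])
    for t, onset in enumerate(onsets):
        if ((presses >= onset - out.t0_index) & (presses < onset)).any():
            out.reject(t, "prestim_press")
            logger.info("trial %d rejected: prestim_press", t)
    return out


def match_trial_counts(epochs: EpochSet, seed: int) -> EpochSet:
    """Equalise accepted Go/NoGo counts by seeded random subsampling of the
    surplus condition (deselected trials are flagged match_surplus)."""
    out = epochs.copy()
    n_go = int(out.accepted_mask("Go").sum())
    n_nogo = int(out.accepted_mask("NoGo").sum())
    if n_go == 0 or n_nogo == 0:
        raise InvalidInputError(
            f"cannot match: {n_go} accepted Go, {n_nogo} accepted NoGo")
    if n_go == n_nogo:
        return out
    surplus = "Go" if n_go > n_nogo else "NoGo"
    keep = min(n_go, n_nogo)
    candidates = np.flatnonzero(out.accepted_mask(surplus))
    rng = np.random.default_rng(seed)
    kept = rng.choice(candidates, size=keep, replace=False)
    for t in np.setdiff1d(candidates, kept):
        out.reject(t, "match_surplus")
        logger.info("trial %d deselected: match_surplus", t)
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_preprocess(recording: Recording, seed: int,
                   thresholds: RejectionThresholds = RejectionThresholds(),
                   bad_channels: list[str] | None = None,
                   ear_channels: list[str] | None = None,
                   soa_ms: float = 1100.0,
                   window_ms=DEFAULT_WINDOW_MS,
                   ) -> tuple[EpochSet, EmcpModel, dict]:
    """Run the fixed preprocessing chain; returns the final EpochSet, the
    fitted ocular model and a per-stage count manifest."""
    manifest: dict[str, object] = {"stages": []}

    def note(stage: str, epochs: EpochSet | None = None) -> None:
        entry: dict[str, object] = {"stage": stage}
        if epochs is not None:
            entry["accepted_go"] = int(epochs.accepted_mask("Go").sum())
            entry["accepted_nogo"] = int(epochs.accepted_mask("NoGo").sum())
        manifest["stages"].append(entry)
        logger.info("stage %s done", stage)

    rec = bandpass_zero_phase(recording)
    note("bandpass")
    if ear_channels:
        rec = reref_linked_ears(rec, ear_channels)
        note("reref")
    if rec.fs != TARGET_FS:
        rec = resample(rec, TARGET_FS)
        note("resample")

    epochs = extract_epochs(rec, window_ms=window_ms, soa_ms=soa_ms)
    note("extract_epochs", epochs)
    epochs = screen_eog_dropout(epochs, thresholds)
    note("eog_dropout_screen", epochs)
    epochs, model = emcp_correct(epochs)
    note("emcp", epochs)
    if bad_channels:
        epochs = interpolate_channels(epochs, bad_channels)
        note("interpolate", epochs)
    epochs = baseline_correct(epochs)
    note("baseline", epochs)
    epochs = artifact_reject_auto(epochs, thresholds)
    note("artifact_reject", epochs)
    epochs = reject_prestim_response(epochs, rec.responses)
    note("prestim_reject", epochs)
    epochs = match_trial_counts(epochs, seed)
    note("match", epochs)
    manifest["seed"] = seed
    return epochs, model, manifest
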