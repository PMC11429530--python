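"""Synthetic task EEG with a fully known ground truth.

Generates continuous multichannel recordings (19 scalp + 4 periocular
channels) containing:

* a 1/f background (amplitude exponent 1.0, configurable scale),
* narrowband oscillators realised as bandpass-filtered Gaussian noise with
  per-trial and per-subject amplitude modulation (pure tones would make the
  downstream component recovery degenerate),
* stimulus-locked Gaussian ERP templates with per-condition gains,
* blink/saccade ocular artifacts propagated into the scalp channels with
  known coefficients, and
* button-press behaviour whose subject-level measures carry planted
  Spearman correlations with driver amplitudes (via a Gaussian copula:
  latent correlation r = 2 sin(pi * rho / 6) yields Spearman rho, and all
  downstream maps are rank-preserving monotone transforms).

Everything is reproducible bit-for-bit under a fixed seed; per-stage child
seeds are spawned from one ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import expit, logit
from scipy.stats import norm, rankdata

from . import montage, spectra
from .errors import InvalidConfigError
from .io_core.containers import Recording
from .io_core.edf import write_edf

BEHAVIOUR_TARGETS = ("mean_rt", "rt_variability", "omission", "fast_rt",
                     "slow_rt", "commission")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class OscillatorSpec:
    """Narrowband spectral component: peak frequency (integer Hz),
    spectral amplitude at the peak (uV), half-power bandwidth (Hz),
    unit-max per-channel topography and between-trial amplitude SD."""

    peak_frequency: int
    amplitude: float
    bandwidth: float = 2.0
    topography: np.ndarray = field(default_factory=lambda: np.ones(19))
    trial_sd: float = 0.0

    def __post_init__(self) -> None:
        self.topography = np.asarray(self.topography, dtype=float)
        if not (1 <= self.peak_frequency <= 30) or self.peak_frequency != int(self.peak_frequency):
            raise InvalidConfigError("peak_frequency must be an integer in 1..30")
        if self.amplitude <= 0 or self.bandwidth <= 0 or self.trial_sd < 0:
            raise InvalidConfigError("amplitude/bandwidth must be > 0, trial_sd >= 0")
        if len(self.topography) != 19 or not np.isclose(self.topography.max(), 1.0):
            raise InvalidConfigError("topography must be length 19 with max weight 1")

    @property
    def name(self) -> str:
        return f"osc_{self.peak_frequency}Hz"


@dataclass
class ErpTemplateSpec:
    """Gaussian ERP template: peak latency and SD in ms, signed amplitude
    in uV, unit-max topography and per-condition gain factors."""

    latency: float
    width: float
    amplitude: float
    topography: np.ndarray = field(default_factory=lambda: np.ones(19))
    condition_gain: dict = field(default_factory=lambda: {"Go": 1.0, "NoGo": 1.0})

    def __post_init__(self) -> None:
        self.topography = np.asarray(self.topography, dtype=float)
        if not 0 < self.latency < 600:
            raise InvalidConfigError("latency must lie in (0, 600) ms")
        if self.width <= 0:
            raise InvalidConfigError("width must be positive")
        if any(g < 0 for g in self.condition_gain.values()):
            raise InvalidConfigError("condition gains must be >= 0")
        if len(self.topography) != 19 or not np.isclose(self.topography.max(), 1.0):
            raise InvalidConfigError("topography must be length 19 with max weight 1")

    @property
    def name(self) -> str:
        return f"erp_{self.latency:g}ms"


@dataclass
class BehaviourLinkSpec:
    """Planted subject-level Spearman correlation between a driver
    (oscillator or ERP template, by name) and a behavioural target."""

    driver: str
    target: str
    strength: float

    def __post_init__(self) -> None:
        if self.target not in BEHAVIOUR_TARGETS:
            raise InvalidConfigError(f"unknown behaviour target {self.target!r}")
        if not -1.0 <= self.strength <= 1.0:
            raise InvalidConfigError("|strength| must be <= 1")


@dataclass
class SimTruth:
    """Ground-truth record for one simulated group."""

    oscillators: list
    erps: list
    links: list
    eog_propagation: np.ndarray
    seed: int
    subject_amplitudes: pd.DataFrame | None = None   # subject x driver
    per_trial_amplitudes: dict = field(default_factory=dict)  # subject -> DataFrame
    behaviour_params: dict = field(default_factory=dict)
    blink_intervals: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {
            "seed": self.seed,
            "oscillators": [
                {"peak_frequency": o.peak_frequency, "amplitude": o.amplitude,
                 "bandwidth": o.bandwidth, "trial_sd": o.trial_sd,
                 "topography": o.topography.tolist()} for o in self.oscillators],
            "erps": [
                {"latency": e.latency, "width": e.width, "amplitude": e.amplitude,
                 "condition_gain": e.condition_gain,
                 "topography": e.topography.tolist()} for e in self.erps],
            "links": [l.__dict__ for l in self.links],
            "eog_propagation": self.eog_propagation.tolist(),
            "subject_amplitudes": (None if self.subject_amplitudes is None
                                   else self.subject_amplitudes.to_dict()),
            "behaviour_params": self.behaviour_params,
            "blink_intervals": {k: [list(map(int, iv)) for iv in v]
                                for k, v in self.blink_intervals.items()},
        }
        path.write_text(json.dumps(doc, indent=1))
        return path


# ---------------------------------------------------------------------------
# event schedule
# ---------------------------------------------------------------------------

def schedule_events(n_blocks: int, per_condition: int, soa_ms: float,
                    seed: int, lead_in_ms: float = 2000.0) -> pd.DataFrame:
    """Seeded random Go/NoGo order at a fixed SOA.

    Each block contains exactly ``per_condition`` Go and ``per_condition``
    NoGo onsets; consecutive onsets differ by exactly ``soa_ms``.
    Returns columns onset_ms, condition, block.
    """
    if n_blocks < 1 or per_condition < 1 or soa_ms <= 0:
        raise InvalidConfigError("blocks/counts must be >= 1 and soa > 0")
    rng = np.random.default_rng(seed)
    conditions, blocks = [], []
    for b in range(n_blocks):
        block = ["Go"] * per_condition + ["NoGo"] * per_condition
        rng.shuffle(block)
        conditions += block
        blocks += [b] * (2 * per_condition)
    onsets = lead_in_ms + np.arange(len(conditions)) * soa_ms
    return pd.DataFrame({"onset_ms": onsets, "condition": conditions, "block": blocks})


# ---------------------------------------------------------------------------
# continuous signal
# ---------------------------------------------------------------------------

def _one_over_f(n_samples: int, fs: float, scale: float,
                rng: np.random.Generator) -> np.ndarray:
    """Random-phase 1/f series whose estimated amplitude spectrum is about
    ``scale``/f uV (per 1 Hz bin) at the estimator's resolution."""
    if scale == 0:
        return np.zeros(n_samples)
    freqs_full = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    duration = n_samples / fs
    amp = np.zeros_like(freqs_full)
    nz = freqs_full >= 0.5
    amp[nz] = scale / (np.sqrt(duration) * freqs_full[nz])
    phase = rng.uniform(0, 2 * np.pi, size=len(freqs_full))
    spectrum = (n_samples * amp / 2.0) * np.exp(1j * phase)
    spectrum[0] = 0.0
    return np.fft.irfft(spectrum, n=n_samples)


def _narrowband(n_samples: int, fs: float, spec: OscillatorSpec,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-calibrated narrowband noise: its mean estimated amplitude
    spectrum reads 1.0 uV at the peak bin."""
    low = max(0.25, spec.peak_frequency - spec.bandwidth / 2.0)
    high = min(fs / 2.0 - 1.0, spec.peak_frequency + spec.bandwidth / 2.0)
    sos = sps.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n_samples + int(4 * fs)))[int(4 * fs):]
    seg_len = spectra.SEGMENT_LEN
    n_seg = len(x) // seg_len
    segs = x[: n_seg * seg_len].reshape(n_seg, seg_len)
    est = spectra.amplitude_spectrum(segs, fs=512.0)[:, spec.peak_frequency].mean()
    return x / est if est > 0 else x


def _trial_gain_series(n_samples: int, fs: float, events_samples: np.ndarray,
                       gains: np.ndarray, prestim_samples: int) -> np.ndarray:
    """Piecewise-constant gain tiling: gain of trial t applies from
    (onset_t - prestim) up to (onset_{t+1} - prestim)."""
    series = np.ones(n_samples)
    starts = events_samples - prestim_samples
    bounds = np.append(starts, n_samples)
    for t, g in enumerate(gains):
        a, b = max(0, bounds[t]), max(0, bounds[t + 1])
        series[a:b] = g
    return series


def synth_background(duration_s: float, fs: float,
                     oscillators: list[OscillatorSpec],
                     one_over_f_scale: float, seed: int,
                     events_samples: np.ndarray | None = None,
                     trial_gains: np.ndarray | None = None,
                     n_channels: int = 19,
                     sensor_noise_sd: float | np.ndarray = 0.0) -> np.ndarray:
    """Continuous background EEG, shape (n_channels, n_samples).

    Each oscillator contributes bandpass-filtered noise calibrated so the
    prestimulus amplitude-spectrum estimator reads its stated amplitude at
    its peak bin on the max-weight channel.  ``trial_gains``
    (n_trials x n_oscillators) modulate oscillator amplitude per trial.
    """
    if fs not in (512, 1000, 512.0, 1000.0):
        raise InvalidConfigError("fs must be 512 or 1000 Hz")
    n_samples = int(round(duration_s * fs))
    if events_samples is not None and len(events_samples) and \
            events_samples.max() >= n_samples:
        raise InvalidConfigError("duration does not cover the event schedule")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_channels + len(oscillators) + 1)
    out = np.zeros((n_channels, n_samples))
    for c in range(n_channels):
        out[c] = _one_over_f(n_samples, fs, one_over_f_scale,
                             np.random.default_rng(child[c]))
    noise_sd = np.broadcast_to(np.asarray(sensor_noise_sd, dtype=float),
                               (n_channels,))
    if noise_sd.any():  # broadband noise floor, per-channel level
        out += noise_sd[:, None] * np.random.default_rng(child[-1]).standard_normal(out.shape)
    prestim = int(round(0.5 * fs))
    for o, spec in enumerate(oscillators):
        wave = _narrowband(n_samples, fs, spec, np.random.default_rng(child[n_channels + o]))
        gain = np.full(n_samples, spec.amplitude)
        if trial_gains is not None and events_samples is not None:
            gain *= _trial_gain_series(n_samples, fs, events_samples,
                                       trial_gains[:, o], prestim)
        out += spec.topography[:n_channels, None] * (wave * gain)[None, :]
    return out


def inject_erp(sig: np.ndarray, events: pd.DataFrame, erps: list[ErpTemplateSpec],
               fs: float, soa_ms: float = 1100.0,
               template_gains: np.ndarray | None = None) -> np.ndarray:
    """Add stimulus-locked Gaussian templates (additive superposition).

    ``events`` needs onset_sample and condition columns; ``template_gains``
    optionally scales each template globally (e.g. a per-subject gain).
    """
    for spec in erps:
        if spec.latency + 2 * spec.width > soa_ms:
            raise InvalidConfigError(
                f"template at {spec.latency} ms extends beyond the SOA")
    out = sig.copy()
    n_samples = out.shape[1]
    for k, spec in enumerate(erps):
        g0 = 1.0 if template_gains is None else float(template_gains[k])
        span = int(round((spec.latency + 4 * spec.width) * fs / 1000.0))
        t = np.arange(span) * 1000.0 / fs
        wave = spec.amplitude * np.exp(-0.5 * ((t - spec.latency) / spec.width) ** 2)
        for onset, condition in zip(events["onset_sample"], events["condition"]):
            gain = g0 * spec.condition_gain.get(condition, 0.0)
            if gain == 0.0:
                continue
            stop = min(int(onset) + span, n_samples)
            if stop <= onset:
                continue
            out[:, int(onset):stop] += gain * np.outer(
                spec.topography[: out.shape[0]], wave[: stop - int(onset)])
    return out


def _blink_wave(fs: float, duration_ms: float = 250.0) -> np.ndarray:
    n = int(round(duration_ms * fs / 1000.0))
    return np.hanning(n)


def inject_eog(sig: np.ndarray, fs: float, blink_rate_per_min: float,
               propagation: np.ndarray, seed: int,
               blink_amp: float = 150.0, saccade_rate_per_min: float = 4.0,
               eog_noise_sd: float = 3.0,
               ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Add ocular activity.

    Returns (contaminated EEG, EOG channels (4 x n), blink intervals).
    EOG order follows :data:`montage.EOG_CHANNELS`; the contamination added
    to EEG channel c is sum_e propagation[e, c] * eog[e].
    """
    propagation = np.asarray(propagation, dtype=float)
    if propagation.shape != (4, sig.shape[0]):
        raise InvalidConfigError(
            f"propagation must be (4, {sig.shape[0]}), got {propagation.shape}")
    n = sig.shape[1]
    rng = np.random.default_rng(seed)
    eog = eog_noise_sd * rng.standard_normal((4, n))

    wave = _blink_wave(fs)
    intervals: list[tuple[int, int]] = []
    n_blinks = int(round(blink_rate_per_min * n / fs / 60.0))
    if n_blinks:
        starts = np.sort(rng.integers(0, n - len(wave), size=n_blinks))
        for s in starts:
            amp = blink_amp * rng.uniform(0.7, 1.3)
            eog[0, s: s + len(wave)] += amp * wave          # VEOGU
            eog[1, s: s + len(wave)] += 0.6 * amp * wave     # VEOGL
            intervals.append((int(s), int(s + len(wave))))

    n_sacc = int(round(saccade_rate_per_min * n / fs / 60.0))
    if n_sacc:
        sw = int(round(0.2 * fs))
        ramp = np.linspace(0, 1, int(0.02 * fs))
        step = np.concatenate([ramp, np.ones(sw - 2 * len(ramp)), ramp[::-1]])
        for s in np.sort(rng.integers(0, n - sw, size=n_sacc)):
            amp = 40.0 * rng.uniform(0.5, 1.5) * rng.choice([-1, 1])
            eog[2, s: s + sw] += amp * step                  # HEOGL
            eog[3, s: s + sw] -= amp * step                  # HEOGR

    contaminated = sig + propagation.T @ eog
    return contaminated, eog, intervals


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

@dataclass
class BehaviourParams:
    """Per-subject generative behaviour parameters (all rank-preserving
    monotone functions of the copula latents)."""

    mean_rt: float = 350.0
    rt_sd: float = 0.0
    p_omission: float = 0.0
    p_fast: float = 0.0
    p_slow: float = 0.0
    p_commission: float = 0.0


def _latent_from_driver(values: np.ndarray, strength: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Gaussian-copula latent correlated with the ranks of ``values`` such
    that the induced Spearman correlation approaches ``strength``."""
    r = 2.0 * np.sin(np.pi * strength / 6.0)
    u = (rankdata(values) - 0.5) / len(values)
    z = norm.ppf(u)
    eps = rng.standard_normal(len(values))
    return r * z + np.sqrt(max(0.0, 1.0 - r * r)) * eps


def synth_behaviour(events: pd.DataFrame,
                    per_trial_amplitudes: pd.DataFrame | None,
                    links: list[BehaviourLinkSpec], base_rt_ms: float,
                    seed: int, params: BehaviourParams | None = None,
                    soa_ms: float = 1100.0) -> pd.DataFrame:
    """Per-trial responses (press_ms, NaN when withheld).

    ``params`` carries the subject-level generative values; trial-level
    links modulate RT and error propensities monotonically with the named
    driver's per-trial amplitude.
    """
    for link in links:
        if not -1.0 <= link.strength <= 1.0:
            raise InvalidConfigError("|strength| must be <= 1")
    params = params or BehaviourParams(mean_rt=base_rt_ms)
    rng = np.random.default_rng(seed)
    n = len(events)

    rt_shift = np.zeros(n)
    p_om = np.full(n, params.p_omission)
    p_fast = np.full(n, params.p_fast)
    p_slow = np.full(n, params.p_slow)
    p_comm = np.full(n, params.p_commission)
    for link in links:
        if link.strength == 0.0 or per_trial_amplitudes is None:
            continue
        if link.driver not in per_trial_amplitudes.columns:
            raise InvalidConfigError(f"unknown driver {link.driver!r}")
        y = _latent_from_driver(per_trial_amplitudes[link.driver].to_numpy(),
                                link.strength, rng)
        if link.target == "mean_rt":
            rt_shift += 50.0 * y
        elif link.target == "rt_variability":
            rt_shift += (20.0 + 15.0 * expit(y)) * rng.standard_normal(n)
        else:
            base = {"omission": p_om, "fast_rt": p_fast, "slow_rt": p_slow,
                    "commission": p_comm}[link.target]
            floor = np.maximum(base, 0.05)
            base[:] = expit(logit(floor) + 1.2 * y)

    press_ms = np.full(n, np.nan)
    for t, (onset, condition) in enumerate(zip(events["onset_ms"],
                                               events["condition"])):
        if condition == "Go":
            u = rng.uniform()
            if u < p_om[t]:
                continue
            if u < p_om[t] + p_fast[t]:
                rt = rng.uniform(20.0, 95.0)
            elif u < p_om[t] + p_fast[t] + p_slow[t]:
                rt = rng.uniform(605.0, min(soa_ms - 5.0, 1000.0))
            else:
                rt = params.mean_rt + rt_shift[t] + params.rt_sd * rng.standard_normal()
                rt = float(np.clip(rt, 105.0, 595.0))
            press_ms[t] = onset + rt
        else:
            if rng.uniform() < p_comm[t]:
                press_ms[t] = onset + rng.uniform(150.0, soa_ms - 10.0)
    return pd.DataFrame({"trial": np.arange(n), "press_ms": press_ms})


# ---------------------------------------------------------------------------
# group-level simulation
# ---------------------------------------------------------------------------

def default_propagation(n_eeg: int = 19) -> np.ndarray:
    """Plausible blink/saccade propagation: strong frontal, decaying back."""
    pos = montage.positions()
    frontality = (pos[:, 1] + 1.0) / 2.0  # 0 at back, 1 at front
    prop = np.zeros((4, n_eeg))
    prop[0] = 0.40 * frontality ** 2       # VEOGU
    prop[1] = 0.25 * frontality ** 2       # VEOGL
    lateral = pos[:, 0]
    prop[2] = 0.10 * frontality * np.clip(-lateral, 0, None)
    prop[3] = 0.10 * frontality * np.clip(lateral, 0, None)
    return prop


@dataclass
class SimConfig:
    """Group simulation configuration (JSON-serialisable via from/to dict)."""

    n_subjects: int = 20
    n_blocks: int = 2
    per_condition: int = 75
    soa_ms: float = 1100.0
    fs: float = 512.0
    oscillators: list = field(default_factory=list)
    erps: list = field(default_factory=list)
    links: list = field(default_factory=list)
    one_over_f_scale: float = 3.0
    one_over_f_subject_sd: float = 0.0   # log-scale between-subject SD
    sensor_noise_sd: float = 4.0   # white broadband noise, uV RMS
    sensor_noise_subject_sd: float = 0.4  # log-scale SD per subject x channel
    blink_rate_per_min: float = 4.0
    subject_amp_sd: float = 0.35   # log-scale SD of subject oscillator gain
    erp_subject_sd: float = 0.30   # log-scale SD of subject ERP gain
    base_rt_ms: float = 350.0
    rt_sd_ms: float = 45.0
    p_omission: float = 0.04
    p_fast: float = 0.01
    p_slow: float = 0.06
    p_commission: float = 0.05
    lead_in_ms: float = 2000.0

    @classmethod
    def from_dict(cls, doc: dict) -> "SimConfig":
        doc = dict(doc)
        doc["oscillators"] = [OscillatorSpec(**o) for o in doc.get("oscillators", [])]
        doc["erps"] = [ErpTemplateSpec(**e) for e in doc.get("erps", [])]
        doc["links"] = [BehaviourLinkSpec(**l) for l in doc.get("links", [])]
        return cls(**doc)


def default_config(**overrides) -> SimConfig:
    """Three oscillators (parietal delta, parietal alpha, frontal beta),
    three ERP templates, and no planted links."""
    parietal = montage.gaussian_topography("Pz", 0.9)
    frontal = montage.gaussian_topography("Fz", 0.9)
    central = montage.gaussian_topography("Cz", 0.9)
    cfg = SimConfig(
        oscillators=[
            OscillatorSpec(2, 7.0, 3.0, parietal, trial_sd=1.5),
            OscillatorSpec(9, 6.0, 2.5, central, trial_sd=1.5),
            OscillatorSpec(18, 3.0, 4.0, frontal, trial_sd=0.8),
        ],
        erps=[
            ErpTemplateSpec(100.0, 18.0, 4.0, central, {"Go": 1.0, "NoGo": 1.0}),
            ErpTemplateSpec(170.0, 25.0, -6.0, frontal, {"Go": 1.0, "NoGo": 1.2}),
            ErpTemplateSpec(360.0, 55.0, 8.0, parietal, {"Go": 1.2, "NoGo": 0.8}),
        ],
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def _subject_latents(cfg: SimConfig, rng: np.random.Generator,
                     n: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-level copula draw: one latent per driver, one per behaviour
    target, with corr(driver, target) = 2 sin(pi rho / 6) for each link."""
    drivers = [o.name for o in cfg.oscillators] + [e.name for e in cfg.erps]
    targets = list(BEHAVIOUR_TARGETS)
    names = drivers + targets
    cov = np.eye(len(names))
    seen: dict[str, str] = {}
    for link in cfg.links:
        if link.driver not in drivers:
            raise InvalidConfigError(f"unknown link driver {link.driver!r}")
        if link.target in seen:
            raise InvalidConfigError(
                f"target {link.target!r} linked twice (to {seen[link.target]!r} "
                f"and {link.driver!r}); one driver per target is supported")
        seen[link.target] = link.driver
        i = names.index(link.driver)
        j = names.index(link.target)
        cov[i, j] = cov[j, i] = 2.0 * np.sin(np.pi * link.strength / 6.0)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise InvalidConfigError("link structure is not jointly satisfiable") from None
    z = rng.standard_normal((n, len(names))) @ chol.T
    frame = pd.DataFrame(z, columns=names)
    return frame[drivers], frame[targets]


def simulate_group(cfg: SimConfig, seed: int, with_signal: bool = True,
                   ) -> tuple[dict[str, Recording], SimTruth]:
    """Simulate every subject of a group; returns ({subject: Recording},
    truth).  Subject ids are s01, s02, ...  With ``with_signal=False`` the
    recordings carry a single silent channel (events/responses and the
    truth record are unchanged), which is enough for behaviour-only
    studies at a fraction of the cost."""
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    zd, zt = _subject_latents(cfg, master, cfg.n_subjects)
    propagation = default_propagation()

    subjects = [f"s{i + 1:02d}" for i in range(cfg.n_subjects)]
    drivers = list(zd.columns)
    amp_rows = []
    recordings: dict[str, Recording] = {}
    truth = SimTruth(cfg.oscillators, cfg.erps, cfg.links, propagation, seed)

    subject_seeds = ss.spawn(cfg.n_subjects)
    for i, subject in enumerate(subjects):
        sub_ss = subject_seeds[i]
        s_events, s_bg, s_eog, s_beh, s_trial = sub_ss.spawn(5)

        # monotone subject-level driver amplitudes
        osc_gain = np.exp(cfg.subject_amp_sd * zd.iloc[i][[o.name for o in cfg.oscillators]].to_numpy())
        erp_gain = np.exp(cfg.erp_subject_sd * zd.iloc[i][[e.name for e in cfg.erps]].to_numpy())
        amp_rows.append(np.concatenate([
            [o.amplitude * g for o, g in zip(cfg.oscillators, osc_gain)],
            [abs(e.amplitude) * g for e, g in zip(cfg.erps, erp_gain)]]))

        events = schedule_events(cfg.n_blocks, cfg.per_condition, cfg.soa_ms,
                                 int(s_events.generate_state(1)[0]),
                                 lead_in_ms=cfg.lead_in_ms)
        n_trials = len(events)
        duration_s = (events["onset_ms"].iloc[-1] + cfg.soa_ms + 1000.0) / 1000.0
        onset_samples = np.round(events["onset_ms"].to_numpy() * cfg.fs / 1000.0).astype(int)

        trial_rng = np.random.default_rng(s_trial)
        trial_gains = np.empty((n_trials, len(cfg.oscillators)))
        per_trial = {}
        for o, (spec, g) in enumerate(zip(cfg.oscillators, osc_gain)):
            rel_sd = spec.trial_sd / spec.amplitude
            tg = np.exp(rel_sd * trial_rng.standard_normal(n_trials) - rel_sd ** 2 / 2)
            trial_gains[:, o] = g * tg
            per_trial[spec.name] = spec.amplitude * trial_gains[:, o]
        truth.per_trial_amplitudes[subject] = pd.DataFrame(per_trial)

        # broadband between-subject/channel variation (not drivers, realism:
        # subjects and electrodes differ in baseline noise level)
        onef_gain = float(np.exp(cfg.one_over_f_subject_sd * master.standard_normal()))
        noise_gain = np.exp(cfg.sensor_noise_subject_sd * master.standard_normal(19))
        if with_signal:
            sig = synth_background(duration_s, cfg.fs, cfg.oscillators,
                                   cfg.one_over_f_scale * onef_gain,
                                   int(s_bg.generate_state(1)[0]),
                                   events_samples=onset_samples,
                                   trial_gains=trial_gains,
                                   sensor_noise_sd=cfg.sensor_noise_sd * noise_gain)
            events_sam = events.assign(onset_sample=onset_samples)
            sig = inject_erp(sig, events_sam, cfg.erps, cfg.fs, cfg.soa_ms,
                             template_gains=erp_gain)
            sig, eog, blinks = inject_eog(sig, cfg.fs, cfg.blink_rate_per_min,
                                          propagation,
                                          int(s_eog.generate_state(1)[0]))
            truth.blink_intervals[subject] = blinks

        # monotone maps from target latents to generative parameters
        z = zt.iloc[i]
        params = BehaviourParams(
            mean_rt=cfg.base_rt_ms + 60.0 * z["mean_rt"],
            rt_sd=cfg.rt_sd_ms * np.exp(0.4 * z["rt_variability"]),
            p_omission=float(expit(logit(max(cfg.p_omission, 1e-3)) + 0.8 * z["omission"])),
            p_fast=float(expit(logit(max(cfg.p_fast, 1e-3)) + 0.8 * z["fast_rt"])),
            p_slow=float(expit(logit(max(cfg.p_slow, 1e-3)) + 0.8 * z["slow_rt"])),
            p_commission=float(expit(logit(max(cfg.p_commission, 1e-3)) + 0.8 * z["commission"])),
        )
        truth.behaviour_params[subject] = params.__dict__.copy()

        responses = synth_behaviour(events, truth.per_trial_amplitudes[subject],
                                    [], cfg.base_rt_ms,
                                    int(s_beh.generate_state(1)[0]),
                                    params=params, soa_ms=cfg.soa_ms)
        press = responses["press_ms"].to_numpy()
        press_samples = np.round(press[~np.isnan(press)] * cfg.fs / 1000.0).astype(int)

        events_frame = pd.DataFrame({"onset_sample": onset_samples,
                                     "condition": events["condition"],
                                     "block": events["block"]})
        responses_frame = pd.DataFrame({"press_sample": np.sort(press_samples)})
        n_samples = int(round(duration_s * cfg.fs))
        recordings[subject] = Recording(
            data=(np.vstack([sig, eog]) if with_signal
                  else np.zeros((1, n_samples))),
            fs=cfg.fs,
            channel_names=(montage.EEG_CHANNELS + montage.EOG_CHANNELS
                           if with_signal else ["dummy"]),
            events=events_frame,
            responses=responses_frame,
        )

    truth.subject_amplitudes = pd.DataFrame(np.array(amp_rows), columns=drivers,
                                            index=subjects)
    return recordings, truth


def write_dataset(recordings: dict[str, Recording], truth: SimTruth,
                  out_dir: str | Path) -> list[Path]:
    """Write one EDF per subject plus the JSON truth record."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for subject, rec in recordings.items():
        paths.append(write_edf(rec, out_dir / f"{subject}.edf"))
    paths.append(truth.to_json(out_dir / "truth.json"))
    return paths
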