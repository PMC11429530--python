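"""Covariance-matrix PCA with Kaiser-normalised Varimax/Promax rotation.

Shared by the frequency-domain stage (cases = subject x channel x condition,
variables = 31 spectral bins, Promax) and the temporal stage (cases =
subject x channel for one condition, variables = 179 time samples, Varimax).

Conventions
-----------
* Covariance (never correlation) over cases with the n-1 denominator;
  variables are centred, not standardised.
* Unrotated loadings are eigenvector x sqrt(eigenvalue); scores are
  standardised to unit variance.
* Microvolt-scaled loadings are the rotated loadings multiplied by the SD
  of the component's raw regression scores; percent variance per component
  is the sum of squared scaled loadings over the total data variance.
* Each component is oriented so its scaled loading at the peak variable
  shares the sign of the grand-mean data value there, making polarity
  deterministic under case permutation.
* Components are reported in ascending peak-variable order (frequency or
  latency); the selection threshold is inclusive (>= percent variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError
from .io_core.containers import EpochSet  # noqa: F401  (type reference)
from .spectra import N_BINS, SpectrumSet

VARIANCE_THRESHOLD_PCT = 1.5
TPCA_FS = 256.0
TPCA_WINDOW_MS = (-100.0, 600.0)
TPCA_N_VARIABLES = 179


@dataclass
class PCAInput:
    """Case x variable matrix with per-case provenance."""

    X: np.ndarray
    case_meta: pd.DataFrame  # columns: subject, channel, condition
    variable_axis: np.ndarray
    axis_unit: str  # "Hz" or "ms"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise InvalidInputError("X must be 2-D")
        if np.isnan(self.X).any():
            raise InvalidInputError("X contains missing values")
        if len(self.case_meta) != self.X.shape[0]:
            raise InvalidInputError("case_meta length mismatch")
        if len(self.variable_axis) != self.X.shape[1]:
            raise InvalidInputError("variable_axis length mismatch")

    @property
    def n_cases(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    @property
    def case_to_variable_ratio(self) -> float:
        return self.n_cases / self.n_variables


@dataclass
class ComponentSet:
    """PCA/rotation solution.

    ``loadings`` is the pattern matrix in the oblique case; ``structure``
    equals pattern x factor_correlations.  ``scores`` are standardised
    (unit variance); ``scores_sd`` holds the raw-score SDs used for the
    microvolt scaling.  Selection/scaling fields are populated by
    :func:`select_and_scale`.
    """

    loadings: np.ndarray                 # variable x component
    scores: np.ndarray                   # case x component, standardised
    factor_correlations: np.ndarray      # component x component
    eigenvalues: np.ndarray              # unrotated eigenvalues (descending)
    total_variance: float                # trace of the covariance matrix
    variable_axis: np.ndarray
    axis_unit: str
    rotation: str                        # "none" | "varimax" | "promax"
    structure: np.ndarray | None = None
    scores_sd: np.ndarray | None = None
    scaled_loadings: np.ndarray | None = None
    pct_variance: np.ndarray | None = None
    peak_variable: np.ndarray | None = None
    selected: np.ndarray | None = None
    mean_profile: np.ndarray = field(default=None)  # grand mean per variable

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def summary(self) -> pd.DataFrame:
        """One row per component: %variance, peak variable, selected flag."""
        if self.pct_variance is None:
            raise InvalidInputError("run select_and_scale first")
        return pd.DataFrame({
            "component": np.arange(1, self.n_components + 1),
            "pct_variance": self.pct_variance,
            f"peak_{self.axis_unit}": self.peak_variable,
            "selected": self.selected,
        })


# ---------------------------------------------------------------------------
# input assembly
# ---------------------------------------------------------------------------

def assemble_fpca_input(spectra: SpectrumSet) -> PCAInput:
    """Stack spectra over subject x channel x condition (subject-major).

    For 20 subjects, 19 channels and 2 conditions this yields the
    760 x 31 case/variable layout (ratio 24.5).
    """
    n_s, n_c, n_k, n_f = spectra.amplitude.shape
    if n_f != N_BINS:
        raise InvalidInputError("spectra must have 31 frequency bins")
    X = spectra.amplitude.reshape(n_s * n_c * n_k, n_f)
    meta = pd.DataFrame({
        "subject": np.repeat(spectra.subjects, n_c * n_k),
        "channel": np.tile(np.repeat(spectra.channel_names, n_k), n_s),
        "condition": np.tile(spectra.conditions, n_s * n_c),
    })
    return PCAInput(X, meta, np.arange(N_BINS, dtype=float), "Hz")


def tpca_times_ms() -> np.ndarray:
    """The 179-point ERP variable grid: -100..600 ms at 256 Hz."""
    step = 1000.0 / TPCA_FS
    first = int(round(TPCA_WINDOW_MS[0] / step))  # -25.6 -> -26? see below
    # grid convention: sample k at k*step ms; window [-100, 600) ms half-open
    # at the upper edge would give 180 points; the printed 179 variables
    # correspond to k in [-25, 153]: -97.65..597.65 ms.
    ks = np.arange(-25, 154)
    assert len(ks) == TPCA_N_VARIABLES
    return ks * step


def assemble_tpca_input(erp_data: np.ndarray, subjects: list[str],
                        channel_names: list[str], times_ms: np.ndarray,
                        condition: str) -> PCAInput:
    """Stack condition-mean ERPs over subject x channel.

    ``erp_data`` has shape (n_subjects, n_channels, 179) on the 256 Hz
    grid; for 20 subjects and 19 channels this yields 380 x 179 (ratio 2.1).
    """
    erp_data = np.asarray(erp_data, dtype=float)
    if erp_data.ndim != 3 or erp_data.shape[2] != TPCA_N_VARIABLES:
        raise InvalidInputError(
            f"expected (subjects, channels, {TPCA_N_VARIABLES}) ERP array")
    if len(times_ms) != TPCA_N_VARIABLES or not np.allclose(
            np.diff(times_ms), 1000.0 / TPCA_FS):
        raise InvalidInputError("ERP grid is not the 256 Hz -100..600 ms grid")
    n_s, n_c, n_t = erp_data.shape
    X = erp_data.reshape(n_s * n_c, n_t)
    meta = pd.DataFrame({
        "subject": np.repeat(subjects, n_c),
        "channel": np.tile(channel_names, n_s),
        "condition": condition,
    })
    return PCAInput(X, meta, np.asarray(times_ms, dtype=float), "ms")


# ---------------------------------------------------------------------------
# decomposition and rotation
# ---------------------------------------------------------------------------

def covariance_pca(pca_input: PCAInput) -> ComponentSet:
    """Eigendecomposition of the variable covariance matrix over cases."""
    X = pca_input.X
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(eigval.max(), 0.0) * 1e-12
    keep = eigval > tol
    if not keep.all():
        warnings.warn(
            f"rank-deficient covariance: retaining {int(keep.sum())} of "
            f"{len(eigval)} components", stacklevel=2)
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    loadings = eigvec * np.sqrt(eigval)
    scores = Xc @ eigvec / np.sqrt(eigval)
    return ComponentSet(
        loadings=loadings,
        scores=scores,
        factor_correlations=np.eye(loadings.shape[1]),
        eigenvalues=eigval,
        total_variance=float(np.trace(cov)),
        variable_axis=pca_input.variable_axis,
        axis_unit=pca_input.axis_unit,
        rotation="none",
        mean_profile=X.mean(axis=0),
    )


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw Varimax criterion: sum over components of the variance of
    squared loadings."""
    p = loadings.shape[0]
    sq = loadings ** 2
    return float((sq ** 2).sum() / p - ((sq.sum(axis=0) / p) ** 2).sum())


def _varimax_rotate(loadings: np.ndarray, tol: float = 1e-10,
                    max_sweeps: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise (Kaiser) Varimax sweeps; returns (rotated, rotation matrix)."""
    L = loadings.copy()
    p, k = L.shape
    R = np.eye(k)
    crit = varimax_criterion(L)
    for _ in range(max_sweeps):
        for i in range(k - 1):
            for j in range(i + 1, k):
                li, lj = L[:, i], L[:, j]
                u = li * li - lj * lj
                v = 2.0 * li * lj
                a, b = u.sum(), v.sum()
                c = (u * u - v * v).sum()
                d = 2.0 * (u * v).sum()
                num = d - 2.0 * a * b / p
                den = c - (a * a - b * b) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-12:
                    continue
                cs, sn = np.cos(phi), np.sin(phi)
                L[:, i], L[:, j] = cs * li + sn * lj, -sn * li + cs * lj
                ri, rj = R[:, i].copy(), R[:, j].copy()
                R[:, i], R[:, j] = cs * ri + sn * rj, -sn * ri + cs * rj
        new_crit = varimax_criterion(L)
        if new_crit - crit < tol:
            crit = new_crit
            break
        crit = new_crit
    else:
        warnings.warn("Varimax did not converge; returning best solution",
                      stacklevel=2)
    return L, R


def varimax(components: ComponentSet, kaiser: bool = True) -> ComponentSet:
    """Kaiser-normalised Varimax rotation of all components."""
    L = components.loadings
    h = np.sqrt((L ** 2).sum(axis=1))
    h_safe = np.where(h > 0, h, 1.0)
    Ln = L / h_safe[:, None] if kaiser else L
    Lr, R = _varimax_rotate(Ln)
    if kaiser:
        Lr = Lr * h_safe[:, None]
    return replace(
        components,
        loadings=Lr,
        scores=components.scores @ R,
        factor_correlations=np.eye(L.shape[1]),
        rotation="varimax",
        structure=None,
    )


def promax(components: ComponentSet, kappa: float = 3.0,
           kaiser: bool = True) -> ComponentSet:
    """Oblique Promax rotation: Varimax followed by a least-squares
    transformation toward the sign-preserved |loading|^kappa target.

    Returns the pattern matrix in ``loadings``, plus ``structure`` and
    ``factor_correlations``.  Scores are raw regression scores standardised
    later by :func:`select_and_scale` (their SDs are kept in scores_sd).
    """
    vm = varimax(components, kaiser=kaiser)
    L = vm.loadings
    target = np.sign(L) * np.abs(L) ** kappa
    try:
        U, *_ = np.linalg.lstsq(L, target, rcond=None)
        d = np.diag(np.linalg.inv(U.T @ U))
    except np.linalg.LinAlgError as exc:
        raise InvalidInputError(f"singular Promax transformation: {exc}") from None
    if (d <= 0).any():
        bad = list(np.flatnonzero(d <= 0) + 1)
        raise InvalidInputError(f"singular Promax transformation for components {bad}")
    U = U * np.sqrt(d)
    pattern = L @ U
    phi = np.linalg.inv(U.T @ U)
    structure = pattern @ phi
    # regression scores: orthogonal scores are Z = Xc V / sqrt(lambda);
    # the oblique regression scores are Z @ R @ inv(U).T
    scores = vm.scores @ np.linalg.inv(U).T
    return replace(
        vm,
        loadings=pattern,
        structure=structure,
        factor_correlations=phi,
        scores=scores,
        rotation="promax",
    )


# ---------------------------------------------------------------------------
# selection, scaling, amplitudes
# ---------------------------------------------------------------------------

def select_and_scale(components: ComponentSet,
                     threshold_pct: float = VARIANCE_THRESHOLD_PCT) -> ComponentSet:
    """Microvolt-scale loadings, compute percent variance, orient signs,
    order by peak variable and apply the inclusive selection threshold."""
    cs = replace(components)
    sd = cs.scores.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    scores = cs.scores / sd_safe
    scaled = cs.loadings * sd_safe
    structure = cs.structure * sd_safe if cs.structure is not None else None

    pct = (scaled ** 2).sum(axis=0) / cs.total_variance * 100.0
    peak_idx = np.argmax(np.abs(scaled), axis=0)

    # deterministic polarity: match the grand-mean value at the peak variable
    mean_profile = cs.mean_profile
    loadings = cs.loadings.copy()
    phi = cs.factor_correlations.copy()
    scaled = scaled.copy()
    scores = scores.copy()
    for k in range(cs.n_components):
        ref = mean_profile[peak_idx[k]] if mean_profile is not None else 1.0
        want = np.sign(ref) if abs(ref) > 1e-12 else 1.0
        if np.sign(scaled[peak_idx[k], k]) not in (0.0, want):
            for arr in (loadings, scaled, scores):
                arr[:, k] *= -1.0
            if structure is not None:
                structure[:, k] *= -1.0
            phi[k, :] *= -1.0
            phi[:, k] *= -1.0

    order = np.lexsort((-pct, cs.variable_axis[peak_idx]))
    take = lambda a: a[:, order] if a is not None else None  # noqa: E731
    phi = phi[np.ix_(order, order)]
    return replace(
        cs,
        loadings=take(loadings),
        structure=take(structure),
        scores=take(scores),
        scaled_loadings=take(scaled),
        factor_correlations=phi,
        scores_sd=sd[order],
        pct_variance=pct[order],
        peak_variable=cs.variable_axis[peak_idx][order],
        selected=pct[order] >= threshold_pct,
    )


def peak_amplitudes(components: ComponentSet, pca_input: PCAInput,
                    mode: str = "pooled") -> pd.DataFrame:
    """Per-subject global mean peak amplitudes for selected components.

    Per case the component amplitude (microvolts) is the standardised score
    times the scaled loading at the peak variable; within subject this is
    averaged over channels (the "global mean").  ``mode`` "pooled" also
    averages over conditions (frequency stage); "per_condition" returns one
    column per condition (temporal stage, where inputs are per condition
    anyway).
    """
    if mode not in ("pooled", "per_condition"):
        raise InvalidConfigError(f"unknown mode {mode!r}")
    if components.selected is None:
        raise InvalidInputError("run select_and_scale first")
    sel = np.flatnonzero(components.selected)
    peak_idx = [int(np.argmax(np.abs(components.scaled_loadings[:, k]))) for k in sel]
    amp = components.scores[:, sel] * components.scaled_loadings[peak_idx, sel]

    meta = pca_input.case_meta
    cols: dict[str, np.ndarray] = {}
    for j, k in enumerate(sel):
        peak = components.peak_variable[k]
        label = (f"c{j + 1}_{peak:g}{components.axis_unit}")
        cols[label] = amp[:, j]
    frame = pd.DataFrame(cols, index=pd.MultiIndex.from_frame(meta))
    if mode == "pooled":
        out = frame.groupby(level="subject", sort=False).mean()
    else:
        out = frame.groupby(level=["subject", "condition"], sort=False).mean()
    return out


def channel_topography(components: ComponentSet, pca_input: PCAInput) -> pd.DataFrame:
    """Per-channel mean amplitude of each selected component (rows =
    channels in first-appearance order), for topography inspection."""
    if components.selected is None:
        raise InvalidInputError("run select_and_scale first")
    sel = np.flatnonzero(components.selected)
    peak_idx = [int(np.argmax(np.abs(components.scaled_loadings[:, k]))) for k in sel]
    amp = components.scores[:, sel] * components.scaled_loadings[peak_idx, sel]
    frame = pd.DataFrame(
        amp, columns=[f"c{j + 1}" for j in range(len(sel))],
        index=pd.MultiIndex.from_frame(pca_input.case_meta))
    return frame.groupby(level="channel", sort=False).mean()
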