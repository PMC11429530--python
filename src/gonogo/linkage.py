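"""Pairwise Spearman associations with p values, 95% CIs and banding.

The p value refers rho to the t distribution with n-2 degrees of freedom
(two-tailed).  The confidence interval Fisher-z-transforms rho with the
Bonett-Wright standard error sqrt((1 + rho^2/2)/(n - 3)) and
back-transforms the bounds; the alternative Fieller variance
sqrt(1.06/(n - 3)) is available but is not the default because it does not
reproduce the reference intervals.  Banding: significant when p <= 0.05,
near when 0.05 < p <= 0.10.  No multiple-comparison correction is applied
to the banding; Benjamini-Hochberg adjusted p values are emitted as a
supplementary column only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError, InvalidInputError
from .io_core.containers import MeasureTable

ALPHA = 0.05
NEAR_ALPHA = 0.10
DOMAINS = ("EEG", "ERP-Go", "ERP-NoGo", "behaviour")


def spearman_rho(x, y) -> float:
    """Spearman correlation: Pearson correlation of mid-ranks.

    Returns NaN when either variable has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D and equal length")
    if len(x) < 4:
        raise InvalidInputError("need at least 4 paired observations")
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_p(rho: float, n: int) -> float:
    """Two-tailed p from the t approximation with n-2 df."""
    if np.isnan(rho):
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0  # exact monotone pair, by convention
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_ci(rho: float, n: int, level: float = 0.95,
                method: str = "bonett-wright") -> tuple[float, float]:
    """Fisher-z confidence interval for a Spearman correlation."""
    if n <= 3:
        raise InvalidInputError("CI undefined for n <= 3")
    if np.isnan(rho):
        return (float("nan"), float("nan"))
    if abs(rho) >= 1.0:  # Fisher z diverges; the interval collapses
        return (float(np.sign(rho)), float(np.sign(rho)))
    if method == "bonett-wright":
        se = np.sqrt((1.0 + rho * rho / 2.0) / (n - 3))
    elif method == "fieller":
        se = np.sqrt(1.06 / (n - 3))
    else:
        raise InvalidConfigError(f"unknown CI method {method!r}")
    z = np.arctanh(rho)
    z_crit = stats.norm.ppf(0.5 + level / 2.0)
    return (float(np.tanh(z - z_crit * se)), float(np.tanh(z + z_crit * se)))


def band(p: float) -> str:
    if np.isnan(p):
        return "undefined"
    if p <= ALPHA:
        return "significant"
    if p <= NEAR_ALPHA:
        return "near"
    return "null"


@dataclass(frozen=True)
class LinkRecord:
    x_domain: str
    x_name: str
    y_domain: str
    y_name: str
    n: int
    df: int
    rho: float
    p: float
    ci_low: float
    ci_high: float
    band: str


def build_link_table(measures: MeasureTable,
                     ci_method: str = "bonett-wright") -> pd.DataFrame:
    """All cross-domain Spearman associations as a tidy DataFrame.

    Within-domain pairs are excluded.  Columns: x_domain, x_name, y_domain,
    y_name, n, df, rho, p, ci_low, ci_high, band, p_bh (supplementary
    Benjamini-Hochberg adjusted p, never used for banding).
    """
    n = measures.n_subjects
    if n < 4:
        raise InvalidInputError("need at least 4 subjects")
    records: list[LinkRecord] = []
    for dx, dy in itertools.combinations(DOMAINS, 2):
        for x_name in measures.columns_in(dx):
            for y_name in measures.columns_in(dy):
                x = measures.frame[x_name].to_numpy()
                y = measures.frame[y_name].to_numpy()
                rho = spearman_rho(x, y)
                p = spearman_p(rho, n)
                if np.isnan(rho):
                    lo = hi = float("nan")
                else:
                    lo, hi = spearman_ci(rho, n, method=ci_method)
                records.append(LinkRecord(dx, x_name, dy, y_name, n, n - 2,
                                          rho, p, lo, hi, band(p)))
    frame = pd.DataFrame([r.__dict__ for r in records])
    frame["p_bh"] = _benjamini_hochberg(frame["p"].to_numpy())
    return frame


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p values; NaNs pass through."""
    out = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return out
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(adjusted, 1.0)
    out[ok] = vals
    return out
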