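"""Statistical primitives: Pearson test, biweight midcorrelation,
Kruskal-Wallis, Benjamini-Hochberg, and two-way consistency ICC.

All operations are pure functions.  Pearson, Kruskal-Wallis and the BH
step-up wrap scipy.stats; the biweight midcorrelation and the ICC
(two-way, single-rater, consistency model, with asymmetric F-inversion
confidence bounds) are implemented here from their standard definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def _as_vector(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-test p-value (n - 2 df)."""
    x, y = _as_vector(x, "x"), _as_vector(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bicor(x, y) -> float:
    """Biweight midcorrelation, a median/MAD-weighted robust correlation.

    Deviations are scaled as u_i = (x_i - median(x)) / (9 * MAD(x)) with
    the raw (unscaled) median absolute deviation; Tukey biweights
    w_i = (1 - u_i^2)^2 * 1{|u_i| < 1} downweight points far from the
    median, so single gross outliers barely move the estimate.  If either
    MAD is zero the function falls back to Pearson with a warning.
    """
    x, y = _as_vector(x, "x"), _as_vector(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    mad_x = np.median(np.abs(x - np.median(x)))
    mad_y = np.median(np.abs(y - np.median(y)))
    if mad_x == 0 or mad_y == 0:
        warnings.warn("zero MAD: falling back to Pearson correlation")
        return float(sps.pearsonr(x, y).statistic)

    def _weighted(v: np.ndarray, mad: float) -> np.ndarray | None:
        u = (v - np.median(v)) / (9.0 * mad)
        w = np.zeros_like(v)
        inside = np.abs(u) < 1.0        # mask first: u can overflow when MAD ~ 0
        w[inside] = (1.0 - u[inside] ** 2) ** 2
        d = (v - np.median(v)) * w
        norm = np.sqrt(np.sum(d**2))
        return None if norm == 0 else d / norm

    wx, wy = _weighted(x, mad_x), _weighted(y, mad_y)
    if wx is None or wy is None:
        # every point beyond the weight cutoff: degenerate spread, as with zero MAD
        warnings.warn("degenerate biweights: falling back to Pearson correlation")
        return float(sps.pearsonr(x, y).statistic)
    return float(np.dot(wx, wy))


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum test across the levels of ``groups``.

    Mid-ranks for ties, the standard tie correction, and a chi-square
    p-value with (g - 1) degrees of freedom.  If every value is identical
    the degenerate convention H = 0, p = 1 applies.
    """
    values = _as_vector(values, "values")
    groups = np.asarray(groups)
    if len(groups) != len(values):
        raise ValueError("values and groups must align")
    levels = [values[groups == g] for g in np.unique(groups)]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in levels):
        raise ValueError("each group needs at least one observation")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    res = sps.kruskal(*levels)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")


@dataclass
class ICCResult:
    """Two-way consistency single-rater ICC with its F-inversion CI."""

    estimate: float
    lower: float
    upper: float
    confidence: float
    n_subjects: int
    k_raters: int
    ms_between_subjects: float
    ms_error: float


def icc_consistency(pairs, confidence: float = 0.95) -> ICCResult:
    """ICC(C,1): two-way model without interaction, consistency definition.

    For an n x k table of repeated measurements (subjects x raters)::

        ICC = (MS_BS - MS_E) / (MS_BS + (k - 1) MS_E)

    where MS_BS is the between-subject and MS_E the residual mean square of
    the two-way ANOVA.  Consistency (not agreement): adding a constant to
    one rater leaves the estimate unchanged.  The asymmetric confidence
    bounds invert the F statistic MS_BS / MS_E with (n-1, (n-1)(k-1))
    degrees of freedom.
    """
    X = np.asarray(pairs, dtype=float)
    if X.ndim != 2:
        raise ValueError("pairs must be an n x k matrix")
    n, k = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if k < 2:
        raise ValueError("need at least 2 raters")
    if np.isnan(X).any():
        raise ValueError("missing cells are not allowed")
    grand = X.mean()
    ss_bs = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_rater = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_bs - ss_rater
    df_bs = n - 1
    df_err = (n - 1) * (k - 1)
    ms_bs = ss_bs / df_bs
    ms_err = ss_err / df_err
    if ms_err <= 0:
        # perfectly consistent raters
        return ICCResult(1.0, 1.0, 1.0, confidence, n, k, ms_bs, ms_err)
    icc = (ms_bs - ms_err) / (ms_bs + (k - 1) * ms_err)
    f_obs = ms_bs / ms_err
    alpha = 1.0 - confidence
    f_l = f_obs / sps.f.ppf(1 - alpha / 2, df_bs, df_err)
    f_u = f_obs * sps.f.ppf(1 - alpha / 2, df_err, df_bs)
    lower = (f_l - 1) / (f_l + k - 1)
    upper = (f_u - 1) / (f_u + k - 1)
    return ICCResult(float(icc), float(lower), float(upper), confidence,
                     n, k, float(ms_bs), float(ms_err))
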