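"""Age acceleration: OLS and random-intercept residualization, group tests.

Acceleration is the residual of predicted age after regressing out
chronological age and, by default, the proportion of neurons (cell
composition tracks age and would otherwise confound the residual).  For
multi-region designs the regression carries a per-region random intercept,

    y_ij = b0 + b1 * age_ij + b2 * neuron_ij + u_region(j) + e_ij,
    u ~ N(0, sigma_b^2),  e ~ N(0, sigma_e^2),

and acceleration is the conditional residual y - X beta - u_hat.  The
variance ratio theta = sigma_b^2 / sigma_e^2 is profiled out of the (RE)ML
deviance and optimized by Nelder-Mead; the remaining parameters have
closed forms given theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .stats import bh_adjust, kruskal_wallis

DEFAULT_COVARIATES = ("age", "neuron_proportion")


@dataclass
class AccelerationResult:
    """Per-sample age-acceleration residuals and the model behind them."""

    sample_ids: list[str]
    residuals: np.ndarray
    model_type: str                       # "ols" or "lme"
    covariates: list[str]
    coefficients: pd.Series
    dropped_ids: list[str] = field(default_factory=list)

    def to_series(self) -> pd.Series:
        return pd.Series(self.residuals, index=self.sample_ids, name="acceleration")


def _aligned_design(
    predictions: np.ndarray,
    sheet: pd.DataFrame,
    covariates: Sequence[str],
    extra: Sequence[str] = (),
):
    """Assemble y and the covariate frame, dropping rows with missing values."""
    predictions = np.asarray(predictions, dtype=float)
    if len(predictions) != len(sheet):
        raise ValueError("predictions and sheet must have equal length")
    cols = list(covariates) + list(extra)
    for c in cols:
        if c not in sheet.columns:
            raise ValueError(f"covariate {c!r} absent from sample sheet")
    sub = sheet[["sample_id", *cols]].copy()
    sub["__y"] = predictions
    complete = sub[cols].notna().all(axis=1) & np.isfinite(predictions)
    dropped = list(sub.loc[~complete, "sample_id"])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} samples with missing covariates: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
    sub = sub[complete]
    return sub, dropped


def ols_acceleration(
    predictions,
    sheet: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> AccelerationResult:
    """OLS residuals of clock predictions on the covariates (with intercept).

    Residuals are orthogonal to every design column; samples with missing
    covariates are dropped listwise with an explicit report.
    """
    covariates = list(covariates)
    sub, dropped = _aligned_design(predictions, sheet, covariates)
    y = sub["__y"].to_numpy()
    X = np.column_stack([np.ones(len(sub))] +
                        [pd.to_numeric(sub[c]).to_numpy(dtype=float) for c in covariates])
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} samples, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design (constant or collinear covariates)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    coef = pd.Series(beta, index=["intercept", *covariates])
    return AccelerationResult(
        sample_ids=list(sub["sample_id"]),
        residuals=resid,
        model_type="ols",
        covariates=covariates,
        coefficients=coef,
        dropped_ids=dropped,
    )


# ---------------------------------------------------------------------------
# random-intercept mixed model


@dataclass
class LMEFit:
    """Fitted random-intercept model with BLUPs and conditional residuals."""

    coefficients: pd.Series               # fixed effects
    sigma_b2: float                       # random-intercept variance (years^2)
    sigma_e2: float                       # residual variance (years^2)
    blups: pd.Series                      # per-group intercepts u_hat
    sample_ids: list[str]
    conditional_residuals: np.ndarray
    marginal_r2: float
    conditional_r2: float
    criterion: str                        # "REML" or "ML"
    theta: float                          # sigma_b2 / sigma_e2
    converged: bool
    n_groups: int
    dropped_ids: list[str] = field(default_factory=list)
    profiled_deviance: Callable[[float], float] | None = field(default=None, repr=False)

    def acceleration(self) -> AccelerationResult:
        return AccelerationResult(
            sample_ids=self.sample_ids,
            residuals=self.conditional_residuals,
            model_type="lme",
            covariates=[c for c in self.coefficients.index if c != "intercept"],
            coefficients=self.coefficients,
            dropped_ids=self.dropped_ids,
        )


def _profiled_quantities(theta: float, X, y, group_idx, group_sizes, criterion: str):
    """GLS at a fixed variance ratio; V = I + theta * Z Z' is block compound-symmetric."""
    n, p = X.shape
    shrink = theta / (1.0 + theta * group_sizes)          # per group
    # V^{-1} A = A - shrink_g * J A within each group
    def vinv(A):
        out = A.copy()
        sums = np.zeros((len(group_sizes),) + A.shape[1:])
        np.add.at(sums, group_idx, A)
        out -= (shrink[group_idx].reshape(-1, *([1] * (A.ndim - 1)))) * sums[group_idx]
        return out

    XtVX = X.T @ vinv(X)
    XtVy = X.T @ vinv(y[:, None]).ravel()
    beta = np.linalg.solve(XtVX, XtVy)
    r = y - X @ beta
    quad = float(r @ vinv(r[:, None]).ravel())
    logdet_v = float(np.sum(np.log1p(theta * group_sizes)))
    if criterion == "REML":
        sigma_e2 = quad / (n - p)
        dev = ((n - p) * (np.log(2 * np.pi * sigma_e2) + 1.0)
               + logdet_v + float(np.linalg.slogdet(XtVX)[1]))
    else:
        sigma_e2 = quad / n
        dev = n * (np.log(2 * np.pi * sigma_e2) + 1.0) + logdet_v
    return beta, sigma_e2, dev


def fit_random_intercept(
    predictions,
    sheet: pd.DataFrame,
    grouping: str = "region",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    criterion: str = "REML",
    n_restarts: int = 4,
) -> LMEFit:
    """Fit predicted age on covariates with a per-group random intercept.

    The deviance is profiled down to the single variance ratio
    ``theta = sigma_b^2 / sigma_e^2`` and minimized by Nelder-Mead on
    ``log(theta)`` from several start points (plus the ``theta = 0``
    boundary), so the fit is robust to flat likelihoods.  With a single
    group the model degenerates to OLS (warned).
    """
    if criterion not in ("REML", "ML"):
        raise ValueError("criterion must be 'REML' or 'ML'")
    covariates = list(covariates)
    sub, dropped = _aligned_design(predictions, sheet, covariates, extra=[grouping])
    y = sub["__y"].to_numpy()
    X = np.column_stack([np.ones(len(sub))] +
                        [pd.to_numeric(sub[c]).to_numpy(dtype=float) for c in covariates])
    groups = sub[grouping].astype(str).to_numpy()
    labels, group_idx = np.unique(groups, return_inverse=True)
    group_sizes = np.bincount(group_idx).astype(float)
    n, p = X.shape
    if len(labels) < 2:
        warnings.warn("single group: falling back to OLS")
        ols = ols_acceleration(predictions, sheet, covariates)
        return LMEFit(
            coefficients=ols.coefficients, sigma_b2=0.0,
            sigma_e2=float(ols.residuals @ ols.residuals / (len(ols.residuals) - p)),
            blups=pd.Series(0.0, index=labels), sample_ids=ols.sample_ids,
            conditional_residuals=ols.residuals, marginal_r2=np.nan,
            conditional_r2=np.nan, criterion=criterion, theta=0.0, converged=True,
            n_groups=1, dropped_ids=ols.dropped_ids,
        )
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient fixed-effect design")

    def deviance(theta: float) -> float:
        theta = max(float(theta), 0.0)
        return _profiled_quantities(theta, X, y, group_idx, group_sizes, criterion)[2]

    best_phi, best_dev, converged = None, np.inf, False
    for start in np.linspace(-4.0, 4.0, n_restarts):
        res = minimize(lambda phi: deviance(np.exp(phi[0])), x0=[start],
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 500})
        if res.fun < best_dev:
            best_dev, best_phi, converged = res.fun, res.x[0], bool(res.success)
    theta = float(np.exp(best_phi))
    if deviance(0.0) <= best_dev:        # boundary: no group variance
        theta, best_dev, converged = 0.0, deviance(0.0), True
    if not converged:
        raise RuntimeError("random-intercept fit failed to converge after restarts")

    beta, sigma_e2, _ = _profiled_quantities(theta, X, y, group_idx, group_sizes, criterion)
    sigma_b2 = theta * sigma_e2
    marg_resid = y - X @ beta
    group_means = np.bincount(group_idx, weights=marg_resid) / group_sizes
    blup = (theta * group_sizes / (1.0 + theta * group_sizes)) * group_means
    cond_resid = marg_resid - blup[group_idx]
    fitted_fixed = X @ beta
    var_f = float(np.var(fitted_fixed))
    total = var_f + sigma_b2 + sigma_e2
    return LMEFit(
        coefficients=pd.Series(beta, index=["intercept", *covariates]),
        sigma_b2=float(sigma_b2),
        sigma_e2=float(sigma_e2),
        blups=pd.Series(blup, index=labels),
        sample_ids=list(sub["sample_id"]),
        conditional_residuals=cond_resid,
        marginal_r2=var_f / total,
        conditional_r2=(var_f + sigma_b2) / total,
        criterion=criterion,
        theta=theta,
        converged=True,
        n_groups=len(labels),
        dropped_ids=dropped,
        profiled_deviance=deviance,
    )


class RandomInterceptModel:
    """Thin estimator-style wrapper around :func:`fit_random_intercept`.

    ``fit`` stores an :class:`LMEFit` in ``fit_`` and the conditional
    residuals in ``residuals_``.
    """

    def __init__(self, grouping: str = "region",
                 covariates: Sequence[str] = DEFAULT_COVARIATES,
                 criterion: str = "REML"):
        self.grouping = grouping
        self.covariates = covariates
        self.criterion = criterion

    def fit(self, predictions, sheet: pd.DataFrame):
        self.fit_ = fit_random_intercept(
            predictions, sheet, grouping=self.grouping,
            covariates=self.covariates, criterion=self.criterion,
        )
        self.residuals_ = self.fit_.conditional_residuals
        return self

    def get_params(self, deep: bool = True):
        return {"grouping": self.grouping, "covariates": self.covariates,
                "criterion": self.criterion}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


# ---------------------------------------------------------------------------
# group comparisons


def group_comparison(
    acceleration: AccelerationResult,
    sheet: pd.DataFrame,
    groupings: Sequence[str],
    strata: str | None = None,
    adjust: str = "grid",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group acceleration means with Kruskal-Wallis and BH-adjusted p.

    One Kruskal-Wallis omnibus test per (stratum, grouping) cell; BH
    adjustment is applied across the full stratum x grouping grid by
    default (``adjust="grid"``) or within each stratum
    (``adjust="per_stratum"``).  Output columns: stratum, grouping, level,
    n, mean, se, kw_p, bh_p, significant.
    """
    if adjust not in ("grid", "per_stratum"):
        raise ValueError("adjust must be 'grid' or 'per_stratum'")
    accel = acceleration.to_series()
    meta = sheet.set_index("sample_id").loc[accel.index]
    strata_levels = ["(all)"] if strata is None else list(pd.unique(meta[strata].dropna()))
    rows, tests = [], []
    for stratum in strata_levels:
        mask = np.ones(len(accel), dtype=bool) if strata is None \
            else (meta[strata] == stratum).to_numpy()
        for grouping in groupings:
            if grouping not in meta.columns:
                raise ValueError(f"grouping {grouping!r} absent from sheet")
            g = meta.loc[mask, grouping]
            v = accel[mask]
            ok = g.notna().to_numpy()
            g, v = g[ok].astype(str), v[ok]
            levels = pd.unique(g)
            if len(levels) < 2:
                warnings.warn(
                    f"grouping {grouping!r} in stratum {stratum!r} has a single "
                    "level; skipped"
                )
                continue
            _, p = kruskal_wallis(v.to_numpy(), g.to_numpy())
            tests.append({"stratum": stratum, "grouping": grouping, "kw_p": p})
            for level in sorted(levels):
                vals = v[(g == level).to_numpy()]
                rows.append({
                    "stratum": stratum, "grouping": grouping, "level": level,
                    "n": int(len(vals)), "mean": float(vals.mean()),
                    "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
                    "kw_p": p,
                })
    if not tests:
        raise ValueError("no grouping produced a valid comparison")
    tests = pd.DataFrame(tests)
    if adjust == "grid":
        tests["bh_p"] = bh_adjust(tests["kw_p"].to_numpy())
    else:
        tests["bh_p"] = np.nan
        for stratum in tests["stratum"].unique():
            m = tests["stratum"] == stratum
            tests.loc[m, "bh_p"] = bh_adjust(tests.loc[m, "kw_p"].to_numpy())
    table = pd.DataFrame(rows).merge(tests, on=["stratum", "grouping", "kw_p"])
    table["significant"] = table["bh_p"] < alpha
    return table
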