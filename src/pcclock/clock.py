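"""PC age clocks: training workflows, prediction, and serialization.

The full training recipe mirrors the sex-stratified consensus design used
for brain PC clocks: one shared SVD of the training betas, three
elastic-net age models (both sexes, males only, females only) on the same
PC scores, the "core PC" set as the intersection of the three selections,
and a final clock refit on both sexes with every non-core PC zeroed out.
The rank-deficient last PC of the centered decomposition is excluded from
every elastic-net design.
"""

from __future__ import annotations

import logging
import warnings
import zipfile
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .enet import ClockModel, fit_elastic_net
from .io import BetaMatrix
from .pc import PCModel, PCProjector, PCScores, fit_svd, project

logger = logging.getLogger(__name__)

FORMAT_VERSION = "pcclock-model-1"

_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "exp": np.exp,
    "expm1": np.expm1,
    "log": np.log,
    "log1p": np.log1p,
}


def consensus_core(selected_sets: Iterable[Iterable[int]]) -> list[int]:
    """Intersection of two or more PC-index selections, ascending.

    An empty intersection is valid (warned), signalling that the stratified
    models share no aging signal.
    """
    sets = [set(s) for s in selected_sets]
    if len(sets) < 2:
        raise ValueError("need at least two selections")
    if any(not s for s in sets):
        raise ValueError("each selection must be nonempty")
    core = set.intersection(*sets)
    if not core:
        warnings.warn("consensus core is empty: models share no selected PCs")
    return sorted(core)


def _design_without_last_pc(scores: PCScores | np.ndarray) -> np.ndarray:
    S = scores.scores if isinstance(scores, PCScores) else np.asarray(scores, dtype=float)
    if S.shape[1] < 2:
        raise ValueError("need at least two PCs to drop the last one")
    return S[:, :-1]


def fit_core_clock(
    training_scores: PCScores | np.ndarray,
    ages: np.ndarray,
    core_pcs: Sequence[int],
    alpha: float = 0.5,
    n_folds: int = 10,
    cv_seed: int = 0,
) -> ClockModel:
    """Refit the clock with every PC outside ``core_pcs`` zeroed out.

    ``core_pcs`` are 1-based PC numbers.  Zeroing a column is exactly
    equivalent to dropping it from the design — zeroed predictors receive
    zero coefficients — so the returned model keeps the original PC
    numbering.  The last PC is excluded regardless of ``core_pcs``.
    """
    S = _design_without_last_pc(training_scores)
    core = sorted(set(int(k) for k in core_pcs))
    if not core:
        raise ValueError("core_pcs must be nonempty")
    if min(core) < 1 or max(core) > S.shape[1]:
        raise ValueError(f"core_pcs must lie in 1..{S.shape[1]}")
    masked = np.zeros_like(S)
    idx = np.asarray(core, dtype=int) - 1
    masked[:, idx] = S[:, idx]
    return fit_elastic_net(masked, ages, alpha=alpha, n_folds=n_folds,
                           cv_seed=cv_seed, training_subset="both")


def train_degenerate_models(
    training: BetaMatrix,
    sheet: pd.DataFrame,
    alpha: float = 0.5,
    n_folds: int = 10,
    cv_seed: int = 0,
) -> tuple[PCModel, ClockModel, ClockModel, ClockModel, list[int]]:
    """One shared SVD, three sex-stratified elastic-net fits, and their core.

    Returns ``(pc_model, clock_both, clock_male, clock_female, core_pcs)``.
    The three clocks are fit on the corresponding sample subsets of the
    shared training PC scores (last PC excluded); ``core_pcs`` is the
    intersection of their selected PC sets.
    """
    if "sex" not in sheet.columns or "age" not in sheet.columns:
        raise ValueError("sample sheet must contain 'sex' and 'age' columns")
    meta = sheet.set_index("sample_id").loc[list(training.sample_ids)]
    sex = meta["sex"].to_numpy()
    ages = meta["age"].to_numpy(dtype=float)
    for label in ("female", "male"):
        if int((sex == label).sum()) < n_folds + 1:
            raise ValueError(
                f"sex stratum {label!r} has fewer than {n_folds + 1} samples"
            )
    pc_model, scores = fit_svd(training)
    S = _design_without_last_pc(scores)
    clocks = {}
    for subset, mask in (
        ("both", np.ones(len(sex), dtype=bool)),
        ("male", sex == "male"),
        ("female", sex == "female"),
    ):
        clocks[subset] = fit_elastic_net(
            S[mask], ages[mask], alpha=alpha, n_folds=n_folds,
            cv_seed=cv_seed, training_subset=subset,
        )
        logger.info("%s model selected %d PCs", subset, len(clocks[subset].pc_indices))
    core = consensus_core(
        [clocks["both"].pc_indices, clocks["male"].pc_indices, clocks["female"].pc_indices]
    )
    logger.info("core PC set has %d members", len(core))
    return pc_model, clocks["both"], clocks["male"], clocks["female"], core


def predict_age(
    clock: ClockModel,
    model: PCModel,
    cohort: BetaMatrix,
    missing_probe_policy: str = "error",
) -> np.ndarray:
    """Project a cohort and apply the clock: g0 + sum_k g_k S_k, per sample."""
    scores = project(model, cohort, missing_probe_policy)
    return clock.predict_from_scores(scores)


def apply_linear_cpg_clock(
    cohort: BetaMatrix,
    coefficients: Mapping[str, float] | pd.Series,
    intercept: float = 0.0,
    output_transform: str | Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Apply a user-supplied CpG-level linear clock: intercept + sum_j w_j beta_ij.

    Probes in the coefficient table but absent from the cohort contribute
    zero, with a warning reporting coverage.  ``output_transform`` may be a
    callable or one of {"identity", "exp", "expm1", "log", "log1p"} for
    clocks defined on a transformed age scale.
    """
    weights = pd.Series(coefficients, dtype=float)
    if weights.empty:
        raise ValueError("empty coefficient table")
    pos = {p: j for j, p in enumerate(cohort.probe_ids)}
    present = [p for p in weights.index if p in pos]
    if not present:
        raise ValueError("no overlap between cohort probes and coefficient table")
    if len(present) < len(weights):
        warnings.warn(
            f"{len(weights) - len(present)} of {len(weights)} clock probes absent "
            f"from cohort (coverage {len(present) / len(weights):.3f}); they contribute 0"
        )
    cols = [pos[p] for p in present]
    values = intercept + cohort.values[:, cols] @ weights.loc[present].to_numpy()
    if output_transform is None:
        return values
    fn = _TRANSFORMS[output_transform] if isinstance(output_transform, str) else output_transform
    return fn(values)


# ---------------------------------------------------------------------------
# serialization


def save_model(
    model: PCModel, clock: ClockModel, path, store_full_rotation: bool = True
) -> None:
    """Write model + clock to a single ``.npz`` container.

    With ``store_full_rotation=False`` only the rotation columns the clock
    uses are stored; predictions are unchanged, as unselected PCs never
    enter the predictor.
    """
    if store_full_rotation:
        pc_numbers = np.arange(1, model.n_components + 1)
    else:
        pc_numbers = np.asarray(clock.pc_indices, dtype=int)
    cols = pc_numbers - 1
    np.savez(
        path,
        format_version=np.array(FORMAT_VERSION),
        probe_ids=np.array(model.probe_ids),
        center=model.center,
        rotation=model.rotation[:, cols],
        rotation_pc_numbers=pc_numbers,
        singular_values=model.singular_values[cols],
        n_train=np.array(model.n_train),
        pc_indices=np.asarray(clock.pc_indices, dtype=int),
        coefficients=clock.coefficients,
        intercept=np.array(clock.intercept),
        alpha=np.array(clock.alpha),
        lambda_=np.array(clock.lambda_),
        cv_seed=np.array(clock.cv_seed),
        training_subset=np.array(clock.training_subset),
        n_pcs=np.array(clock.n_pcs),
    )


def load_model(path) -> tuple[PCModel, ClockModel]:
    """Load a saved container; predictions round-trip within 1e-10.

    When the container holds only the clock's rotation columns, the clock's
    PC indices are remapped to the stored column order, so prediction works
    identically.
    """
    try:
        with np.load(path, allow_pickle=False) as data:
            if "format_version" not in data or str(data["format_version"]) != FORMAT_VERSION:
                raise ValueError("model container version mismatch")
            arrays = {k: data[k] for k in data.files}
    except (OSError, ValueError, KeyError, zipfile.BadZipFile) as exc:
        if isinstance(exc, ValueError) and "version mismatch" in str(exc):
            raise
        raise ValueError(f"corrupted or truncated model container {path}") from exc
    pc_numbers = arrays["rotation_pc_numbers"].astype(int)
    model = PCModel(
        probe_ids=[str(p) for p in arrays["probe_ids"]],
        center=arrays["center"],
        rotation=arrays["rotation"],
        singular_values=arrays["singular_values"],
        n_train=int(arrays["n_train"]),
    )
    col_of = {int(num): j + 1 for j, num in enumerate(pc_numbers)}
    stored_indices = [col_of[int(k)] for k in arrays["pc_indices"]]
    clock = ClockModel(
        pc_indices=stored_indices,
        coefficients=arrays["coefficients"],
        intercept=float(arrays["intercept"]),
        alpha=float(arrays["alpha"]),
        lambda_=float(arrays["lambda_"]),
        cv_seed=int(arrays["cv_seed"]),
        training_subset=str(arrays["training_subset"]),
        n_pcs=model.n_components,
    )
    return model, clock


def export_coefficients(model: PCModel, clock: ClockModel, path) -> None:
    """Text audit export: per-PC coefficients plus intercept header."""
    with open(path, "w") as fh:
        fh.write(f"# intercept\t{clock.intercept!r}\n")
        fh.write("pc\tcoefficient\n")
        for k, c in zip(clock.pc_indices, clock.coefficients):
            fh.write(f"PC{k}\t{c!r}\n")


# ---------------------------------------------------------------------------
# scikit-learn estimators


class PCAgeClock(BaseEstimator, RegressorMixin):
    """PC age clock as a scikit-learn regressor.

    ``fit(X, y)`` centers and decomposes the training betas, drops the last
    PC, optionally zeroes non-core PCs, and fits the cross-validated
    elastic net of age on the remaining scores.  ``predict(X)`` projects
    new samples onto the training rotation and applies the clock.

    Parameters
    ----------
    alpha : float, default 0.5
        Elastic-net mixing (1 = lasso, 0 = ridge).
    n_folds : int, default 10
    cv_seed : int, default 0
        Seed for the CV fold shuffle.
    core_pcs : sequence of int, optional
        1-based PC numbers to restrict the fit to (others zeroed out).
    missing_probe_policy : {"error", "fill_with_center"}

    Attributes
    ----------
    pc_model_ : PCModel
    clock_model_ : ClockModel
    """

    def __init__(self, alpha: float = 0.5, n_folds: int = 10, cv_seed: int = 0,
                 core_pcs: Sequence[int] | None = None,
                 missing_probe_policy: str = "error"):
        self.alpha = alpha
        self.n_folds = n_folds
        self.cv_seed = cv_seed
        self.core_pcs = core_pcs
        self.missing_probe_policy = missing_probe_policy

    def fit(self, X, y):
        beta = PCProjector._as_beta(X)
        y = np.asarray(y, dtype=float)
        self.pc_model_, scores = fit_svd(beta)
        if self.core_pcs is not None:
            self.clock_model_ = fit_core_clock(
                scores, y, self.core_pcs, alpha=self.alpha,
                n_folds=self.n_folds, cv_seed=self.cv_seed,
            )
        else:
            S = _design_without_last_pc(scores)
            self.clock_model_ = fit_elastic_net(
                S, y, alpha=self.alpha, n_folds=self.n_folds, cv_seed=self.cv_seed,
            )
        self.n_features_in_ = beta.n_probes
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "clock_model_")
        beta = PCProjector._as_beta(X)
        return predict_age(self.clock_model_, self.pc_model_, beta,
                           self.missing_probe_policy)


class SexConsensusPCClock(BaseEstimator, RegressorMixin):
    """Sex-stratified consensus clock (the full training recipe).

    ``fit(X, y, sex=...)`` trains the three degenerate models (both sexes,
    male-only, female-only) on one shared decomposition, intersects their
    PC selections into the core set, and refits the final core clock on
    both sexes.  ``predict`` applies the core clock.

    Attributes
    ----------
    pc_model_ : PCModel
    clock_both_, clock_male_, clock_female_ : ClockModel
    core_pcs_ : list of int
    core_clock_ : ClockModel
    """

    def __init__(self, alpha: float = 0.5, n_folds: int = 10, cv_seed: int = 0,
                 missing_probe_policy: str = "error"):
        self.alpha = alpha
        self.n_folds = n_folds
        self.cv_seed = cv_seed
        self.missing_probe_policy = missing_probe_policy

    def fit(self, X, y, sex=None, sheet: pd.DataFrame | None = None):
        beta = PCProjector._as_beta(X)
        y = np.asarray(y, dtype=float)
        if sheet is None:
            if sex is None:
                raise ValueError("provide per-sample sex labels (or a sample sheet)")
            sheet = pd.DataFrame(
                {"sample_id": beta.sample_ids, "age": y, "sex": list(sex)}
            )
        (self.pc_model_, self.clock_both_, self.clock_male_, self.clock_female_,
         self.core_pcs_) = train_degenerate_models(
            beta, sheet, alpha=self.alpha, n_folds=self.n_folds, cv_seed=self.cv_seed,
        )
        if not self.core_pcs_:
            raise ValueError("consensus core is empty; cannot fit a core clock")
        scores = project(self.pc_model_, beta)
        self.core_clock_ = fit_core_clock(
            scores, y, self.core_pcs_, alpha=self.alpha,
            n_folds=self.n_folds, cv_seed=self.cv_seed,
        )
        self.n_features_in_ = beta.n_probes
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "core_clock_")
        beta = PCProjector._as_beta(X)
        return predict_age(self.core_clock_, self.pc_model_, beta,
                           self.missing_probe_policy)
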