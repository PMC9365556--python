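"""SVD training and PC-score projection on methylation beta matrices.

Training decomposes the per-probe-centered beta matrix X - mu as U D V^T;
scores of new cohorts are obtained by projecting the centered betas onto
the training right singular vectors: S = (X_new - mu) V.  Probes are
centered but not variance-scaled — betas already share the common [0, 1]
scale, and the conventional formulation of PC methylation clocks uses
centered scores only.

SVD signs are fixed by forcing the largest-magnitude entry of each right
singular vector to be positive, so decompositions are deterministic and
serializable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import BetaMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCModel:
    """Fitted decomposition: probe set, centers, rotation, singular values."""

    probe_ids: list[str]
    center: np.ndarray              # per-probe training means, length p
    rotation: np.ndarray            # p x K right singular vectors
    singular_values: np.ndarray     # length K, non-increasing
    n_train: int

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        p, K = self.rotation.shape
        if len(self.probe_ids) != p or len(self.center) != p:
            raise ValueError("probe_ids/center length must match rotation rows")
        if len(self.singular_values) != K:
            raise ValueError("singular_values length must match rotation columns")

    @property
    def n_components(self) -> int:
        return self.rotation.shape[1]

    def score_variances(self) -> np.ndarray:
        """Training-score variance of each PC: d_k^2 / (n_train - 1)."""
        return self.singular_values**2 / (self.n_train - 1)


@dataclass
class PCScores:
    """Per-sample coordinates on the training PCs."""

    sample_ids: list[str]
    scores: np.ndarray = field(repr=False)  # samples x K

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape[0] != len(self.sample_ids):
            raise ValueError("scores rows must match sample_ids")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _fix_signs(rotation: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(rotation), axis=0)
    signs = np.sign(rotation[idx, np.arange(rotation.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def fit_svd(training: BetaMatrix) -> tuple[PCModel, PCScores]:
    """Center per probe and decompose; returns the model and training scores.

    All K = min(n_train, n_probes) components are kept; with centering the
    trailing component is rank-deficient (near-zero singular value) and is
    flagged in the log.  Missing values must be imputed first.
    """
    X = training.values
    if np.isnan(X).any():
        raise ValueError("beta matrix contains missing values; impute first")
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 training samples")
    center = X.mean(axis=0)
    Xc = X - center
    if not np.any(np.abs(Xc) > 1e-12):
        raise ValueError("degenerate all-constant matrix")
    U, d, Vt = np.linalg.svd(Xc, full_matrices=False)
    signs = _fix_signs(Vt.T)
    V = Vt.T * signs[None, :]
    U = U * signs[None, :]
    near_zero = d < d[0] * 1e-10 if d[0] > 0 else d == 0
    if near_zero.any():
        logger.info("%d trailing components have near-zero variance", int(near_zero.sum()))
    model = PCModel(
        probe_ids=list(training.probe_ids),
        center=center,
        rotation=V,
        singular_values=d,
        n_train=n,
    )
    scores = PCScores(list(training.sample_ids), U * d[None, :])
    return model, scores


def project(
    model: PCModel,
    cohort: BetaMatrix,
    missing_probe_policy: str = "error",
) -> PCScores:
    """Project a cohort onto the training rotation: S = (X - mu_train) V.

    Probes are aligned by id to the training order.  Under the default
    strict policy any training probe absent from the cohort aborts; with
    ``fill_with_center`` absent probes are filled with the training mean
    (contributing exactly zero to every score) and the coverage fraction
    is logged.
    """
    if missing_probe_policy not in ("error", "fill_with_center"):
        raise ValueError(f"unknown missing_probe_policy {missing_probe_policy!r}")
    pos = {p: j for j, p in enumerate(cohort.probe_ids)}
    missing = [p for p in model.probe_ids if p not in pos]
    if missing:
        if missing_probe_policy == "error":
            raise ValueError(
                f"cohort lacks {len(missing)} of {len(model.probe_ids)} model probes "
                f"(e.g. {missing[:3]}); use fill_with_center to proceed"
            )
        coverage = 1.0 - len(missing) / len(model.probe_ids)
        logger.warning(
            "filling %d absent probes with training centers (coverage %.3f)",
            len(missing), coverage,
        )
    X = np.empty((cohort.n_samples, len(model.probe_ids)))
    for j, probe in enumerate(model.probe_ids):
        if probe in pos:
            X[:, j] = cohort.values[:, pos[probe]]
        else:
            X[:, j] = model.center[j]
    if np.isnan(X).any():
        raise ValueError("cohort contains missing values; impute first")
    scores = (X - model.center) @ model.rotation
    return PCScores(list(cohort.sample_ids), scores)


class PCProjector(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer wrapping SVD training and projection.

    ``fit`` learns per-probe centers and the rotation from a training beta
    matrix; ``transform`` returns PC scores for new cohorts.  Accepts
    :class:`~pcclock.io.BetaMatrix` or a plain samples x probes array
    (probe alignment by id requires a BetaMatrix).

    Attributes
    ----------
    model_ : PCModel
        Centers, rotation, singular values.
    training_scores_ : ndarray of shape (n_train, K)
    """

    def __init__(self, missing_probe_policy: str = "error"):
        self.missing_probe_policy = missing_probe_policy

    @staticmethod
    def _as_beta(X) -> BetaMatrix:
        if isinstance(X, BetaMatrix):
            return X
        X = np.asarray(X, dtype=float)
        return BetaMatrix(
            [f"s{i}" for i in range(X.shape[0])],
            [f"p{j}" for j in range(X.shape[1])],
            X,
        )

    def fit(self, X, y=None):
        beta = self._as_beta(X)
        self.model_, scores = fit_svd(beta)
        self.training_scores_ = scores.scores
        self.n_features_in_ = beta.n_probes
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        beta = self._as_beta(X)
        return project(self.model_, beta, self.missing_probe_policy).scores
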