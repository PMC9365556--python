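"""Synthetic methylation cohorts with known latent structure.

The generator emulates the dominant structure of brain methylation arrays:
a handful of latent factors tied to age, sex, cell composition, pathology
and brain region, with sparse probe loadings, a logistic link keeping beta
values inside (0, 1), and technical rescan noise for replicate designs.

Generative model (per sample ``i``, probe ``j``, factor ``k``)::

    z_ik    = a_k * age_i + s_k * sex_i + g_k * patho_i + o_k,region(i)
              + Normal(0, eta_k)
    logit_ij = mu_j + sum_k L_jk * z_ik + Normal(0, sigma_e)
    beta_ij  = 1 / (1 + exp(-logit_ij))

with sex coded -1/2 (female) and +1/2 (male).  Factor 0 is the designated
cell-composition factor: its score is a deterministic monotone map of the
sample's neuron proportion, which itself declines linearly with age plus
noise and is written to the sample sheet.  By default this factor has the
largest loading-density x variance product, so the first PC of the
simulated matrix aligns with cell composition rather than age — matching
what is seen on real brain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import BetaMatrix


def _default_tuple(*values):
    return field(default_factory=lambda: tuple(values))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Per-factor sequences all have length ``n_factors``; factor 0 is the
    cell-composition factor, whose ``age_slope`` / ``factor_noise_sd``
    entries are ignored (its score is driven by neuron proportion).

    Default condition: 300 samples, 2,000 probes, three age-linked factors
    (age slopes 0.10/0.07/0.05 per year on the latent scale) plus the
    cell-composition factor and one sex-linked factor, residual logit noise
    ``sigma_e`` = 0.5 and rescan noise ``sigma_t`` = 0.02 on the beta scale.
    """

    n_samples: int = 300
    n_probes: int = 2000
    age_range: tuple[float, float] = (20.0, 90.0)
    n_factors: int = 5
    age_slope: tuple[float, ...] = _default_tuple(0.0, 0.10, 0.07, 0.05, 0.0)
    sex_effect: tuple[float, ...] = _default_tuple(0.0, 0.0, 0.0, 0.0, 2.0)
    pathology_effect: tuple[float, ...] = _default_tuple(0.0, 0.0, 0.8, 0.0, 0.0)
    factor_noise_sd: tuple[float, ...] = _default_tuple(0.0, 0.8, 0.8, 0.8, 1.0)
    loading_density: tuple[float, ...] = _default_tuple(0.5, 0.2, 0.2, 0.2, 0.2)
    loading_scale: tuple[float, ...] = _default_tuple(2.0, 1.0, 1.0, 1.0, 1.0)
    baseline_logit_sd: float = 1.5
    sigma_e: float = 0.5
    sigma_t: float = 0.02
    pathology_prevalence: float = 0.3
    # neuron proportion ~ intercept + slope * age + Normal(0, sd), clipped
    neuron_intercept: float = 0.61
    neuron_age_slope: float = -0.002
    neuron_noise_sd: float = 0.05
    cell_factor_scale: float = 20.0
    region_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_probes < 1 or self.n_factors < 1:
            raise ValueError("counts must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min < max")
        for name in ("age_slope", "sex_effect", "pathology_effect",
                     "factor_noise_sd", "loading_density", "loading_scale"):
            vals = tuple(getattr(self, name))
            object.__setattr__(self, name, vals)
            if len(vals) != self.n_factors:
                raise ValueError(f"{name} must have length n_factors={self.n_factors}")
        if any(s < 0 for s in self.factor_noise_sd) or self.sigma_e < 0 or self.sigma_t < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if any(not (0 < d <= 1) for d in self.loading_density):
            raise ValueError("loading_density entries must lie in (0, 1]")
        if not (0 <= self.pathology_prevalence <= 1):
            raise ValueError("pathology_prevalence must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("age_range", "age_slope", "sex_effect", "pathology_effect",
                    "factor_noise_sd", "loading_density", "loading_scale"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        for key, val in raw.items():
            if isinstance(val, tuple):
                raw[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class SimulationTruth:
    """Ground truth retained for parameter-recovery tests."""

    factor_scores: np.ndarray       # samples x factors
    loadings: np.ndarray            # probes x factors
    baseline_logit: np.ndarray      # per-probe mu_j
    age: np.ndarray
    sex: np.ndarray                 # "female" / "male"
    pathology: np.ndarray           # 0/1 flags
    neuron_proportion: np.ndarray
    region: np.ndarray | None
    config: SimulationConfig

    def noiseless_logits(self) -> np.ndarray:
        """Reconstruct mu_j + sum_k L_jk z_ik exactly (no residual noise)."""
        return self.baseline_logit[None, :] + self.factor_scores @ self.loadings.T


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_subjects(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_samples
    age = rng.uniform(*config.age_range, size=n)
    sex_num = rng.integers(0, 2, size=n) - 0.5          # -0.5 female, +0.5 male
    patho = (rng.random(n) < config.pathology_prevalence).astype(float)
    neuron = config.neuron_intercept + config.neuron_age_slope * age \
        + rng.normal(0.0, config.neuron_noise_sd, size=n)
    neuron = np.clip(neuron, 0.02, 0.98)
    return age, sex_num, patho, neuron


def _factor_scores(
    config: SimulationConfig,
    rng: np.random.Generator,
    age, sex_num, patho, neuron,
    region_offsets: np.ndarray | None = None,
) -> np.ndarray:
    n, K = len(age), config.n_factors
    a = np.asarray(config.age_slope)
    s = np.asarray(config.sex_effect)
    g = np.asarray(config.pathology_effect)
    eta = np.asarray(config.factor_noise_sd)
    z = (age[:, None] * a[None, :] + sex_num[:, None] * s[None, :]
         + patho[:, None] * g[None, :])
    z += rng.normal(0.0, 1.0, size=(n, K)) * eta[None, :]
    # factor 0: deterministic monotone map of neuron proportion
    z[:, 0] = config.cell_factor_scale * (neuron - 0.5)
    if region_offsets is not None:
        z = z + region_offsets[None, :]
    return z


def _loadings(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    p, K = config.n_probes, config.n_factors
    L = np.zeros((p, K))
    for k in range(K):
        mask = rng.random(p) < config.loading_density[k]
        L[mask, k] = rng.normal(0.0, config.loading_scale[k], size=int(mask.sum()))
    return L


def _betas(config, rng, z, L, mu) -> np.ndarray:
    logits = mu[None, :] + z @ L.T
    if config.sigma_e > 0:
        logits = logits + rng.normal(0.0, config.sigma_e, size=logits.shape)
    return _sigmoid(logits)


def _sheet(sample_ids, age, sex_num, patho, neuron, rng,
           region=None) -> pd.DataFrame:
    n = len(sample_ids)
    # ordinal pathology scores loosely tracking the binary flag
    cerad_levels = np.where(
        patho > 0,
        rng.integers(2, 5, size=n),
        rng.integers(1, 3, size=n),
    )
    braak_group = np.where(patho > 0, "V-VI", "0-IV")
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": age,
            "sex": np.where(sex_num > 0, "male", "female"),
            "region": region if region is not None else "DLPFC",
            "neuron_proportion": neuron,
            "dx_clinical": np.where(patho > 0, "AD", "Control"),
            "cerad": cerad_levels,
            "braak": braak_group,
            "nia_reagan": np.where(patho > 0, "likely", "unlikely"),
            "apoe_e4": rng.integers(0, 2, size=n) * (rng.random(n) < 0.5),
        }
    )
    return sheet


def simulate_cohort(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[BetaMatrix, pd.DataFrame, SimulationTruth]:
    """Generate one synthetic cohort (beta matrix, sample sheet, truth).

    ``seed`` overrides ``config.seed`` when given; the same (config, seed)
    pair always yields byte-identical output.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    age, sex_num, patho, neuron = _draw_subjects(config, rng)
    L = _loadings(config, rng)
    mu = rng.normal(0.0, config.baseline_logit_sd, size=config.n_probes)
    z = _factor_scores(config, rng, age, sex_num, patho, neuron)
    betas = _betas(config, rng, z, L, mu)
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    probe_ids = [f"cg{j:06d}" for j in range(config.n_probes)]
    matrix = BetaMatrix(sample_ids, probe_ids, betas)
    sheet = _sheet(sample_ids, age, sex_num, patho, neuron, rng)
    truth = SimulationTruth(
        factor_scores=z, loadings=L, baseline_logit=mu, age=age,
        sex=sheet["sex"].to_numpy(), pathology=patho,
        neuron_proportion=neuron, region=None, config=config,
    )
    return matrix, sheet, truth


def simulate_replicate_pairs(
    matrix: BetaMatrix, sigma_t: float = 0.02, seed: int = 0
) -> BetaMatrix:
    """Technical rescans of a cohort: beta + Normal(0, sigma_t), clamped to [0, 1].

    Returned sample ids carry a ``_rep`` suffix; row order matches the
    originals, preserving the pairing.
    """
    if sigma_t < 0:
        raise ValueError("sigma_t must be >= 0")
    rng = np.random.default_rng(seed)
    rescans = matrix.values.copy()
    if sigma_t > 0:
        rescans = np.clip(rescans + rng.normal(0.0, sigma_t, size=rescans.shape), 0.0, 1.0)
    return BetaMatrix([f"{s}_rep" for s in matrix.sample_ids], matrix.probe_ids, rescans)


def simulate_multiregion(
    config: SimulationConfig | None = None,
    regions: Sequence[str] = ("PFC", "ST", "CBM"),
    region_offsets: dict[str, Sequence[float]] | None = None,
    seed: int | None = None,
    return_truth: bool = False,
):
    """Per-region cohorts sharing the same individuals.

    Each individual contributes one sample per region.  Subject-level factor
    structure (age, sex, pathology, subject noise) is shared across regions;
    region-specific offsets ``o_kr`` shift each factor, and a small
    idiosyncratic per-region noise (``config.region_noise_sd``) is added.
    ``region_offsets`` maps region label -> length-``n_factors`` offset
    vector; omitted regions get zero offsets.  With ``return_truth`` the
    per-region factor-score matrices are returned as a second value.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    region_offsets = region_offsets or {}
    age, sex_num, patho, neuron = _draw_subjects(config, rng)
    L = _loadings(config, rng)
    mu = rng.normal(0.0, config.baseline_logit_sd, size=config.n_probes)
    z_base = _factor_scores(config, rng, age, sex_num, patho, neuron)
    out: dict[str, tuple[BetaMatrix, pd.DataFrame]] = {}
    z_by_region: dict[str, np.ndarray] = {}
    probe_ids = [f"cg{j:06d}" for j in range(config.n_probes)]
    individual_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    # phenotypes belong to the individual, drawn once and reused per region
    base_sheet = _sheet(individual_ids, age, sex_num, patho, neuron, rng)
    for region in regions:
        offs = np.asarray(region_offsets.get(region, np.zeros(config.n_factors)), dtype=float)
        if offs.shape != (config.n_factors,):
            raise ValueError(f"offset vector for {region!r} must have length {config.n_factors}")
        z = z_base + offs[None, :]
        if config.region_noise_sd > 0:
            z = z + rng.normal(0.0, config.region_noise_sd, size=z.shape)
        betas = _betas(config, rng, z, L, mu)
        sample_ids = [f"{ind}_{region}" for ind in individual_ids]
        matrix = BetaMatrix(sample_ids, probe_ids, betas)
        sheet = base_sheet.copy()
        sheet["sample_id"] = sample_ids
        sheet["region"] = region
        sheet.insert(1, "individual_id", individual_ids)
        out[region] = (matrix, sheet)
        z_by_region[region] = z
    if return_truth:
        return out, z_by_region
    return out
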