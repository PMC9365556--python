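import numpy as np
import pandas as pd
import pytest

from pcclock.io import BetaMatrix
from pcclock.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_beta(rng):
    """10 samples x 50 probes random beta matrix, no missing values."""
    values = rng.uniform(0.05, 0.95, size=(10, 50))
    return BetaMatrix(
        [f"s{i}" for i in range(10)], [f"cg{j:03d}" for j in range(50)], values
    )


@pytest.fixture
def annotation():
    """Annotation for the small_beta probes: last 5 on sex chromosomes."""
    probes = [f"cg{j:03d}" for j in range(50)]
    chrom = [str(j % 22 + 1) for j in range(45)] + ["X", "X", "Y", "X", "Y"]
    genes = [f"G{j // 2}" if j % 3 else "" for j in range(50)]
    return pd.DataFrame({"probe_id": probes, "chromosome": chrom, "gene": genes})


@pytest.fixture(scope="session")
def small_cohort():
    """120-sample, 400-probe cohort: big enough to train, fast to fit."""
    cfg = SimulationConfig(n_samples=120, n_probes=400, seed=7)
    return simulate_cohort(cfg)
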