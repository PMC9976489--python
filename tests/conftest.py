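import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import methclock as mc

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CELLS = ("Bas", "Eos", "NK", "Mono", "CD4T", "CD8T")


@pytest.fixture(scope="session")
def small_cohort():
    """300 samples x 400 CpGs with every CpG class represented."""
    cfg = mc.SimulationConfig(n_samples=300, n_cpgs=400, seed=11)
    return mc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def survival_cohort():
    """Cohort with EpiScore-driven survival for bAge tests."""
    cfg = mc.SimulationConfig(
        n_samples=600, n_cpgs=300, seed=7,
        survival=mc.SurvivalConfig(
            episcore_log_hrs={"prot_001": 0.5, "prot_002": -0.4},
        ),
    )
    return mc.simulate_cohort(cfg)


def toy_matrix(values, sample_prefix="s", cpg_prefix="cg"):
    arr = np.asarray(values, dtype=float)
    return mc.MethylationMatrix(
        pd.DataFrame(
            arr,
            index=[f"{sample_prefix}{i}" for i in range(arr.shape[0])],
            columns=[f"{cpg_prefix}{j}" for j in range(arr.shape[1])],
        )
    )
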