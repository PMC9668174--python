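import numpy as np
import pytest

from ritss import Cohort, ScenarioConfig, simulate_null


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Hand-sized deterministic cohort (n=30, m=4, d=2, p=1)."""
    rng = np.random.default_rng(7)
    n, m = 30, 4
    X = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    E = rng.standard_normal((n, 2))
    Z = rng.standard_normal((n, 1))
    Y = 0.5 * E[:, 0] + X @ np.array([0.3, -0.2, 0.1, 0.0]) + rng.standard_normal(n)
    return Cohort(
        sample_ids=[f"S{i:02d}" for i in range(n)],
        Y=Y,
        X=X,
        E=E,
        Z=Z,
        variant_ids=[f"rs{j}" for j in range(m)],
        env_names=["E1", "E2"],
        covar_names=["Z1"],
    )


@pytest.fixture(scope="session")
def sim_cohort() -> Cohort:
    """Moderate simulated null cohort shared by module tests."""
    cfg = ScenarioConfig(scenario=1, n=1200, m=15, d=3, p=2, seed=11)
    return simulate_null(cfg)


def write_cohort_files(cohort: Cohort, tmp_path):
    """Write the four TSV inputs for CLI / loader tests; returns path dict."""
    from ritss import write_cohort

    return write_cohort(cohort, tmp_path)
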