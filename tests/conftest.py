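import pytest

from rmpa.synthetic_cohort import CohortConfig, generate


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample cohort with compact modules, reused by read-only tests."""
    return generate(
        CohortConfig(
            n_samples=60,
            module_sizes={"SPRY-M": 8, "NF1-M": 8, "PTEN-M": 8},
            n_background_genes=40,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the default study conditions (n=200, delta/sigma=1.5)."""
    return generate(CohortConfig(seed=11))
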