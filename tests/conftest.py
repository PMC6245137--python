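import pytest

import diabnet as dn


@pytest.fixture(scope="session")
def planted_config() -> dn.SyntheticCohortConfig:
    """Mid-sized cohort with five planted diagnosis features (0.8 vs 0.4)."""
    return dn.SyntheticCohortConfig(
        n_patients=600,
        complication="kidney",
        planted=dn.default_planted(5, 0.8, 0.4),
        seed=42,
    )


@pytest.fixture(scope="session")
def planted_cohort(planted_config):
    """(patients, diagnosis, clinical, truth) tables for planted_config."""
    return dn.generate_cohort(planted_config)
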