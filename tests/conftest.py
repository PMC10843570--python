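import pandas as pd
import pytest

from amychron import CohortConfig, estimate_cohort_chronicity, generate_cohort


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Full-size cohort with measurement noise switched off (latent values)."""
    cfg = CohortConfig(seed=0, noise_sd_abl=0.0, noise_sd_suvr=0.0)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort under the default (noisy) study conditions."""
    cfg = CohortConfig(seed=0)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def noise_free_fit(noise_free_cohort):
    cfg, df = noise_free_cohort
    estimates, curve = estimate_cohort_chronicity(df)
    return cfg, df, estimates, curve


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    cfg, df = default_cohort
    estimates, curve = estimate_cohort_chronicity(df)
    return cfg, df, estimates, curve


@pytest.fixture()
def two_scan_subject():
    """Minimal two-scan amyloid table for finite-difference checks."""
    return pd.DataFrame(
        {
            "subject_id": ["a", "a"],
            "age": [40.0, 42.0],
            "modality": ["amyloid", "amyloid"],
            "abl": [10.0, 14.0],
        }
    )
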