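import warnings

import numpy as np
import pytest

from pafreact import CohortDesign, RegionEffects, SpectralParams, generate_cohort, synth_psd
from pafreact.synthetic import default_frequency_grid


@pytest.fixture(scope="session")
def freq_grid():
    """0.2 Hz grid to 60 Hz, matching 5-s Welch epochs."""
    return default_frequency_grid()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort reused across tests (12 TD / 10 ASD)."""
    return generate_cohort(CohortDesign(n_td=12, n_asd=10), seed=42)


@pytest.fixture(scope="session")
def default_cohort_table():
    """PAF table from one default-design cohort (29 TD / 22 ASD)."""
    return generate_cohort(seed=2024).paf_table()


def zero_effect_design(**kw) -> CohortDesign:
    """Design with every injected effect and coupling set to zero."""
    regions = CohortDesign().region_effects
    return CohortDesign(
        region_effects={r: RegionEffects() for r in regions},
        baseline_coupling=0.0,
        srs_coupling=0.0,
        **kw,
    )


def clean_psd(mu=10.0, a=0.4, sigma=1.2, exponent=1.5, offset=1.0, noise=0.0, seed=None):
    return synth_psd(
        SpectralParams(
            offset=offset,
            exponent=exponent,
            peak_center=mu,
            peak_amplitude=a,
            peak_width=sigma,
            noise_sd=noise,
        ),
        seed=seed,
    )


@pytest.fixture(autouse=True)
def _quiet_model_warnings():
    """Mixed-model convergence chatter is asserted via result flags, not
    warnings; keep the test output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
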