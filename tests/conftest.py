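import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pyp_dynaquant as pq

settings.register_profile(
    "default", deadline=None, max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def geometry48():
    return pq.build_phantom_geometry((48, 48, 48), 4.92)


@pytest.fixture(scope="session")
def noiseless_attr_subject(geometry48):
    """One idealized ATTR subject: no blur, no noise, no inter-subject scale."""
    return pq.generate_subject(
        "ATTR", geometry48, pq.default_kinetics("ATTR"),
        pq.NOISELESS_ACQUISITION, pq.default_dose_params("ATTR"),
        seed=7, subject_id="ATTR-IDEAL", subject_cv_scale=0.0)


@pytest.fixture(scope="session")
def noiseless_non_attr_subject(geometry48):
    return pq.generate_subject(
        "non-ATTR", geometry48, pq.default_kinetics("non-ATTR"),
        pq.NOISELESS_ACQUISITION, pq.default_dose_params("non-ATTR"),
        seed=8, subject_id="NEG-IDEAL", subject_cv_scale=0.0)


@pytest.fixture(scope="session")
def noiseless_report():
    """Full-size noiseless pipeline run (19 subjects, 64^3 default grid)."""
    return pq.run_pipeline(pq.noiseless_run_config(seed=0))


@pytest.fixture(scope="session")
def noisy_report():
    """Default study conditions: Poisson noise on, blur off, printed group
    sizes and CVs, package default seed."""
    return pq.run_pipeline(pq.RunConfig(seed=0))


@pytest.fixture(scope="session")
def small_noisy_cohort(geometry48):
    """A small noisy cohort for per-subject property checks."""
    cfg = pq.CohortConfig(grid_shape=(48, 48, 48))
    return pq.generate_cohort(2, 3, cfg, seed=11)


def group_mean(quant, group, voi, window, metric="suv_mean"):
    sub = quant[(quant.group == group) & (quant.voi == voi)
                & (quant.window == window)]
    assert not sub.empty
    return float(sub[metric].mean())
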