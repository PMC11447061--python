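import numpy as np
import pytest

from oralmm.cohort import default_cf_config, generate_cohort
from oralmm.core import OgttSeries, Subject

OGTT_TIMES = np.array([-10., -1., 10., 20., 30., 45., 60., 90., 120., 150., 180.])


@pytest.fixture
def tiny_series() -> OgttSeries:
    """Hand-written, physiologically plausible 11-point record."""
    return OgttSeries(
        subject_id="T01",
        times=OGTT_TIMES.copy(),
        glucose=np.array([5.0, 5.2, 6.5, 8.0, 9.5, 10.0, 9.0, 7.5, 6.2, 5.6, 5.3]),
        insulin=np.array([40., 40., 120., 260., 380., 430., 400., 300., 220., 120., 60.]),
        cpeptide=np.array([300., 310., 520., 800., 1100., 1250., 1200., 1000.,
                           800., 560., 420.]),
    )


@pytest.fixture
def tiny_subject() -> Subject:
    return Subject(subject_id="T01", age=30.0, sex="female", height=165.0,
                   weight=60.0)


@pytest.fixture(scope="session")
def noisefree_cohort_small():
    """Eight noise-free synthetic subjects (two per tolerance group)."""
    cfg = default_cf_config()
    cfg.group_sizes = {"NGT": 2, "EGI": 2, "IGT": 2, "CFRD": 2}
    return generate_cohort(cfg, seed=42, noise=False)


@pytest.fixture(scope="session")
def noisy_cohort_small():
    cfg = default_cf_config()
    cfg.group_sizes = {"NGT": 2, "EGI": 2, "IGT": 2, "CFRD": 2}
    return generate_cohort(cfg, seed=42, noise=True)
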