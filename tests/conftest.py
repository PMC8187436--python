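import numpy as np
import pytest

from gammares.pipeline import fixture_config, make_fixture
from gammares.synth import CohortConfig, SubjectParams


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Miniature simulated cohort on disk (3 subjects x 2 visits, high snr)."""
    out = tmp_path_factory.mktemp("cohort")
    make_fixture(out, seed=7)
    return out


@pytest.fixture(scope="session")
def fixture_cfg():
    return fixture_config(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def small_config():
    """Cheap generation geometry for per-test simulation."""
    return CohortConfig(n_subjects=2, n_trials=12, n_vertices=6, n_visits=1, seed=5)


def make_params(**kw) -> SubjectParams:
    defaults = dict(
        subject_id="S000",
        alpha=1.1,
        beta=0.5,
        f0=55.0,
        gamma_slope=2.5,
        snr=0.6,
        pink_exponent=1.0,
        sens_score=37.7,
        age=28.0,
    )
    defaults.update(kw)
    return SubjectParams(**defaults)


@pytest.fixture()
def params():
    return make_params()
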