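import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rsmga import datasets

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ccd_experiment():
    """The bundled published 10-run CCD and its response table."""
    return datasets.load_ccd_experiment()


@pytest.fixture(scope="session")
def ccd_fit(ccd_experiment):
    from rsmga import fit_quadratic

    design, df = ccd_experiment
    return fit_quadratic(design, df["observed"])


@pytest.fixture(scope="session")
def screening_records():
    from rsmga.pipeline import ScreeningRecord

    df = datasets.load_screening()
    return [
        ScreeningRecord(r.source, r.role, r.cdw, r.pha) for r in df.itertuples()
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
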