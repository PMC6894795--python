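import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sumroc import SNPSummary, StudySummary

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_study(study_id="study1", n_case=2000, n_control=3000, snp_params=None):
    """snp_params: list of (odds_ratio, raf) tuples."""
    if snp_params is None:
        snp_params = [(1.5, 0.3), (2.0, 0.1)]
    snps = tuple(
        SNPSummary(snp_id=f"rs{i + 1}", odds_ratio=oratio, raf=raf)
        for i, (oratio, raf) in enumerate(snp_params)
    )
    return StudySummary(
        study_id=study_id, n_case=n_case, n_control=n_control,
        snps=snps, phenotype="test condition",
    )


@pytest.fixture
def two_snp_study():
    return make_study()


@pytest.fixture
def single_snp_study():
    return make_study(
        study_id="single", n_case=1000, n_control=1000, snp_params=[(2.0, 0.3)]
    )
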