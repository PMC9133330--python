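import pytest
from hypothesis import settings

import dorsalkit as dk

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_cohort():
    """Deterministic cohort reproducing the published marginal counts."""
    cohort, norms = dk.make_fixture_cohort()
    return cohort, norms


@pytest.fixture(scope="session")
def fixture_report(fixture_cohort):
    cohort, norms = fixture_cohort
    cfg = dk.RunConfig(cohort_dir="", n_sims=100_000, seed=7)
    return dk.analyze(cohort, norms, cfg=cfg)


@pytest.fixture(scope="session")
def default_model():
    return dk.default_reference_model(seed=11)
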