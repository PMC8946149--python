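import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_reference():
    """Small deterministic 4-contig reference shared across tests."""
    from ocstrat.synthetic_data import simulate_reference

    return simulate_reference(seed=3, n_chroms=4, length=50_000)


@pytest.fixture(scope="session")
def full_reference():
    """The default 22-autosome toy genome used by the cohort generator."""
    from ocstrat.synthetic_data import _reference_bundle

    ref, _ = _reference_bundle(0, 22, 1_000_000)
    return ref


@pytest.fixture(scope="session")
def default_cohort():
    """One default 120-sample synthetic cohort, simulated once per session."""
    from ocstrat.synthetic_data import CohortConfig, simulate_cohort

    return simulate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    """Context counts and ploidy profiles for the session cohort."""
    from ocstrat import genome_features as gf

    feats = {}
    for s in default_cohort.samples:
        cc = gf.count_contexts(s.variants, s.svs, default_cohort.reference)
        wgd = gf.call_wgd(s.segments)
        feats[s.meta.sample_id] = (cc, gf.ploidy_fractions(s.segments, wgd=wgd))
    return feats


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
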