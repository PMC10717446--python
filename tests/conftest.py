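import pytest
from hypothesis import HealthCheck, settings

from cannamr import (
    HarmonizedInstrument,
    SimulationConfig,
    SnpAssociation,
    harmonize_pair,
    simulate_two_sample,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_assoc(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.02, p=1e-6, n=100_000, eaf=0.3):
    return SnpAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pvalue=p, n=n, eaf=eaf,
    )


def make_instrument(
    rsid="rs1", bx=0.1, sx=0.02, by=0.05, sy=0.01, p=1e-6,
    eaf=0.3, bc=None, sc=None, ea="A", oa="G",
    n_exposure=100_000, n_outcome=100_000,
):
    return HarmonizedInstrument(
        rsid=rsid, effect_allele=ea, other_allele=oa,
        beta_exposure=bx, se_exposure=sx, pvalue_exposure=p,
        beta_outcome=by, se_outcome=sy,
        n_exposure=n_exposure, n_outcome=n_outcome, eaf=eaf,
        beta_covariate=bc, se_covariate=sc,
        is_palindromic=(ea, oa) in {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")},
    )


@pytest.fixture(scope="session")
def sim_pair():
    """One synthetic two-sample dataset at the study scale, true effect 0.2."""
    return simulate_two_sample(SimulationConfig(seed=7, theta=0.2))


@pytest.fixture(scope="session")
def sim_instruments(sim_pair):
    return harmonize_pair(sim_pair.exposure_stats, sim_pair.outcome_stats).instruments
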