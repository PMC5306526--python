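"""Shared fixtures: cohorts and fitted posterior draws reused across tests.

Session-scoped fits keep the suite fast: the default synthetic cohort is
fitted once per region at the reduced test schedule and shared by every
test that only reads the draws.
"""

import numpy as np
import pandas as pd
import pytest

from neuroblme.cohort import CohortDesign, generate_cohort
from neuroblme.model import MCMCConfig, PosteriorDraws, gibbs_sample

QUICK_CONFIG = MCMCConfig(
    n_chains=2, n_iterations=3000, n_burnin=1000, thin=4, seed=5
)

SMALL_DESIGN = CohortDesign(
    n_hc_stable=20,
    n_mci_stable=8,
    n_ad_stable=8,
    n_conv_hc_mci=2,
    n_conv_hc_ad=1,
    n_conv_hc_mci_ad=1,
    n_conv_mci_ad=2,
    retention_by_visit=(1.0, 38 / 42, 36 / 42, 34 / 42),
    n_single_visit=4,
)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return generate_cohort(SMALL_DESIGN, seed=2)


@pytest.fixture(scope="session")
def ventricle_draws(default_cohort) -> PosteriorDraws:
    return gibbs_sample(
        default_cohort, "ventricle", config=MCMCConfig.test_profile(seed=11)
    )


@pytest.fixture(scope="session")
def hippocampus_draws(default_cohort) -> PosteriorDraws:
    return gibbs_sample(
        default_cohort, "hippocampus", config=MCMCConfig.test_profile(seed=12)
    )


def make_draws(
    beta: np.ndarray,
    sigma2: np.ndarray | float = 1.0,
    Sigma: np.ndarray | None = None,
    random_effects: np.ndarray | None = None,
    participant_ids: np.ndarray | None = None,
    region: str = "ventricle",
    n_chains: int = 2,
    age_mean: float = 72.0,
    age_sd: float = 6.0,
) -> PosteriorDraws:
    """Assemble a PosteriorDraws object directly from arrays, for tests of
    the inference layers that do not need a real MCMC fit."""
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    M = beta.shape[0]
    if np.isscalar(sigma2):
        sigma2 = np.full(M, float(sigma2))
    if Sigma is None:
        Sigma = np.broadcast_to(np.eye(2), (M, 2, 2)).copy()
    elif np.asarray(Sigma).ndim == 2:
        Sigma = np.broadcast_to(np.asarray(Sigma, float), (M, 2, 2)).copy()
    if random_effects is None:
        random_effects = np.zeros((M, 1, 2))
    if participant_ids is None:
        participant_ids = np.arange(1, random_effects.shape[1] + 1)
    chain = np.arange(M) % n_chains
    return PosteriorDraws(
        beta=beta,
        sigma2=np.asarray(sigma2, float),
        Sigma=np.asarray(Sigma, float),
        random_effects=np.asarray(random_effects, float),
        chain=chain,
        participant_ids=np.asarray(participant_ids),
        age_mean=age_mean,
        age_sd=age_sd,
        region=region,
    )
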