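import numpy as np
import pytest

from mfindices import (
    ProfileTable,
    sample_vine_correlation,
    simulate_population,
)
from mfindices.data_model import _within_sex_residuals
from mfindices.error_correction import _inv_sqrt_pd


def make_profiles(
    p: int = 5,
    n: int = 600,
    d_sd: float = 0.7,
    seed: int = 0,
    beta: float = 4.0,
    prop_female: float = 0.5,
) -> ProfileTable:
    """Simulated two-sex sample with a vine correlation and random d vector."""
    rng = np.random.default_rng(seed)
    R = sample_vine_correlation(p, beta, rng)
    d = rng.normal(0.0, d_sd, p)
    return simulate_population(R, d, n, prop_female, rng)


def force_identity_correlation(profiles: ProfileTable) -> ProfileTable:
    """Whiten within-sex residuals so the pooled correlation is exactly I."""
    resid = _within_sex_residuals(profiles)
    cov = resid.T @ resid / (profiles.n - 2)
    white = resid @ _inv_sqrt_pd(cov)
    means = profiles.values - resid
    return ProfileTable(
        values=white + means,
        sex=profiles.sex.copy(),
        trait_names=list(profiles.trait_names),
    )


def pooled_variance(scores: np.ndarray, sex: np.ndarray) -> float:
    """Pooled within-sex variance with denominator n - 2."""
    parts = []
    for code in (1, 0):
        s = scores[sex == code]
        parts.append(np.sum((s - s.mean()) ** 2))
    return sum(parts) / (len(scores) - 2)


@pytest.fixture(scope="session")
def small_profiles() -> ProfileTable:
    return make_profiles(p=5, n=400, seed=11)


@pytest.fixture(scope="session")
def two_trait_profiles() -> ProfileTable:
    return make_profiles(p=2, n=400, seed=7)
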