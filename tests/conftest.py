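import numpy as np
import pytest

from survfuse import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_censored_outcome(rng, n, tie_prob=0.5, censor_frac=0.4):
    """Random survival outcome with time ties (integer grid) and censoring."""
    if rng.random() < tie_prob:
        time = rng.integers(1, 12, size=n).astype(float)
    else:
        time = rng.exponential(size=n)
    event = (rng.random(n) > censor_frac).astype(int)
    if event.sum() == 0:
        event[rng.integers(n)] = 1
    return time, event


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 80-sample cohort with moderate planted signal."""
    cfg = SimConfig(
        n_samples=80, p_gene=40, p_mirna=20, n_clusters=2, latent_dim=4,
        beta_additive=1.0, beta_cross=0.5, target_censoring=0.4, seed=7,
    )
    return simulate_cohort(cfg)


# small network dims that keep estimator tests fast
FAST_MODEL = dict(l=8, m=4, d=4, h1=6, h2=4, k=4, max_epochs=40)
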