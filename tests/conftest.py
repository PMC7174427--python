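import numpy as np
import pytest

from causalmr import HarmonizedInstrumentSet


def make_hset(beta_x, se_x, beta_y, se_y, eaf=None, n_x=400_000.0, n_y=180_000.0, ids=None):
    """Build a harmonized set directly from effect arrays (single exposure)."""
    beta_x = np.asarray(beta_x, dtype=float)
    k = len(beta_x)
    if ids is None:
        ids = [f"rs{i + 1}" for i in range(k)]
    if eaf is None:
        eaf = np.full(k, 0.3)
    return HarmonizedInstrumentSet(
        exposure_labels=["exposure"],
        outcome_label="outcome",
        variant_ids=list(ids),
        beta_x=np.asarray(beta_x, dtype=float).reshape(k, 1),
        se_x=np.asarray(se_x, dtype=float).reshape(k, 1),
        beta_y=np.asarray(beta_y, dtype=float),
        se_y=np.asarray(se_y, dtype=float),
        eaf=np.asarray(eaf, dtype=float),
        n_x=np.full((k, 1), float(n_x)),
        n_y=np.full(k, float(n_y)),
    )


@pytest.fixture
def fixture_a():
    """Three-instrument hand-checkable set: IVW beta = 112.8/308, Q tiny."""
    return make_hset(
        beta_x=[0.10, 0.08, 0.12],
        se_x=[0.01, 0.01, 0.01],
        beta_y=[0.036, 0.030, 0.044],
        se_y=[0.010, 0.010, 0.010],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_hset(rng, k=12, theta=0.4, alpha_mu=0.0, alpha_sd=0.0):
    """A generic well-behaved instrument set for algebraic identities."""
    bx = rng.uniform(0.05, 0.2, k) * rng.choice([-1, 1], k)
    sx = rng.uniform(0.004, 0.01, k)
    sy = rng.uniform(0.005, 0.02, k)
    alpha = rng.normal(alpha_mu, alpha_sd, k) if (alpha_mu or alpha_sd) else np.zeros(k)
    by = theta * bx + alpha + rng.normal(0, sy)
    return make_hset(bx, sx, by, sy)
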