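import numpy as np
import pytest
from scipy.stats import spearmanr

from seedgrad import io, gradient, synthetic


@pytest.fixture(scope="session")
def world():
    """Default synthetic world (seed 42): per-subject BOLD, grids, truth."""
    return synthetic.make_connectivity_world(seed=42)


@pytest.fixture(scope="session")
def group_series(world):
    seed_blocks, target_blocks, seed_grid, target_grid, _ = world
    with np.errstate(all="ignore"):
        seed_ts = io.standardize_and_concatenate(seed_blocks, seed_grid)
        target_ts = io.standardize_and_concatenate(target_blocks, target_grid)
    return seed_ts, target_ts


@pytest.fixture(scope="session")
def gradients(world, group_series):
    """Gradient pipeline output on the default world."""
    seed_ts, target_ts = group_series
    grads, fc_sparse, aff = gradient.run_gradient_pipeline(seed_ts, target_ts)
    return grads, fc_sparse, aff


@pytest.fixture(scope="session")
def oriented_gradient(world, gradients):
    """Dominant gradient flipped to correlate positively with the planted axis.

    The embedding sign is arbitrary; recovery checks that depend on the
    direction resolve it against the planted truth.
    """
    truth = world[4]
    g = gradients[0].dominant
    if spearmanr(g, truth.latent).statistic < 0:
        g = -g
    return g
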