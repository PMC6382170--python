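import numpy as np
import pytest

from radfeat.phantoms import make_grid, phantom_roi
from radfeat.preprocess import (
    ROI,
    DiscretizationMethod,
    DiscretizationRule,
    DiscretizedROI,
)


@pytest.fixture(scope="session")
def seeded_grids():
    """Small seeded discretized volumes covering full and irregular masks."""
    grids = [
        make_grid((4, 6, 6), ng=4, seed=11),
        make_grid((3, 5, 5), ng=3, seed=23),
        make_grid((2, 4, 6), ng=4, seed=7),
    ]
    # an irregular intensity mask carved out of a full grid
    g = make_grid((4, 5, 5), ng=4, seed=41)
    rng = np.random.default_rng(99)
    imask = rng.random(g.levels.shape) > 0.25
    imask[0, 0, 0] = True  # keep nonempty deterministically
    levels = np.where(imask, g.levels, 0)
    grids.append(
        DiscretizedROI(levels, g.ng, g.rule, imask, np.ones_like(imask, bool), g.spacing)
    )
    return grids


@pytest.fixture(scope="session")
def fixture_roi():
    """The in-repo digital phantom as an ROI."""
    return phantom_roi()


@pytest.fixture()
def simple_roi():
    """A tiny deterministic ROI with distinct intensities for hand checks."""
    img = np.arange(24, dtype=float).reshape(2, 3, 4)
    mask = np.ones((2, 3, 4), bool)
    return ROI(img, mask, mask, (1.0, 1.0, 1.0))


@pytest.fixture()
def fbn_rule():
    return DiscretizationRule(DiscretizationMethod.FBN, n_bins=4)
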