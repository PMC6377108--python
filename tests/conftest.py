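"""Shared fixtures: published parameter sets and small simulated datasets."""

import numpy as np
import pytest

from emergentdrf import (
    BackgroundSpec,
    CommonModeParams,
    DissimilarModeParams,
    FrechetModel,
    FrechetParams,
    ModelSpec,
    QuantalData,
    simulate_quantal,
)

# Reported chloroform (mild liver necrosis, mice) parameter rows
CHLOROFORM_DMB = dict(c=0.0496, xi=0.2719, eta=2.4126)
CHLOROFORM_CMB = dict(d_b=0.7886, xi=1.1711, eta=5.3731)
CHLOROFORM_MULTISTAGE = (0.0486, 2.2191, 0.0)
CHLOROFORM_LOGNORMAL_DMB = dict(c=0.0507, mu=-1.0434, sigma=0.6393)

# Benzene-toluene (medaka mortality) mixture rows; stressor order
# (benzene, toluene) — the published table does not state the assignment,
# this order matches the narrated slice behaviour.
BENZENE_TOLUENE_CM = CommonModeParams(
    xi=(3.0, 30.0), eta=1.0, d0=4.2, interactions={(0, 1): -0.095}
)
BENZENE_TOLUENE_DM = DissimilarModeParams(
    per_stressor=(
        dict(xi=6.0, eta=1.0, d0=10.0),
        dict(xi=30.0, eta=1.0, d0=125.0),
    ),
    interactions={(0, 1): 0.0},
    interaction_thresholds={(0, 1): 0.0},
)


@pytest.fixture(scope="session")
def frechet_true():
    """A ground-truth Frechet DRF used for simulation-based tests."""
    return FrechetModel(FrechetParams(xi=1.0, eta=2.0))


@pytest.fixture(scope="session")
def dose_grid_interior():
    """8 doses spanning response ~0.06 to ~0.95 for the ground truth."""
    return np.geomspace(0.6, 4.4, 8)


@pytest.fixture(scope="session")
def simulated_data(frechet_true, dose_grid_interior):
    return simulate_quantal(frechet_true, dose_grid_interior, 500, seed=42)


def union_inclusion_exclusion(probs):
    """Brute-force union probability over all non-empty subsets."""
    from itertools import combinations

    probs = list(probs)
    total = 0.0
    for r in range(1, len(probs) + 1):
        for subset in combinations(probs, r):
            total += (-1) ** (r + 1) * float(np.prod(subset))
    return total
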