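import warnings

import numpy as np
import pytest

import coexar as cx

# statsmodels emits optimization chatter on sparse species; irrelevant to assertions
warnings.filterwarnings("ignore", category=RuntimeWarning, module="statsmodels")
warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")


@pytest.fixture(scope="session")
def small_design() -> cx.StudyDesign:
    """A reduced design (2 years, 6 plots, 8 species) for fast end-to-end tests."""
    return cx.StudyDesign(
        n_years=2,
        n_plots=6,
        species_names=tuple(f"SP{i:02d}" for i in range(1, 9)),
    )


@pytest.fixture(scope="session")
def small_truth(small_design) -> cx.GroundTruth:
    return cx.generate_ground_truth(small_design, seed=42)


@pytest.fixture(scope="session")
def small_obs(small_design, small_truth):
    return cx.generate_observations(small_truth, small_design, 20, seed=43)


def random_community(rng: np.random.Generator, size: int) -> cx.LVCommunity:
    """A random community with competitive self-limitation and mixed signs."""
    A = rng.normal(0.3, 0.15, (size, size))
    np.fill_diagonal(A, rng.uniform(0.5, 1.5, size))
    r = rng.uniform(0.2, 1.5, size)
    return cx.LVCommunity(tuple(f"S{i}" for i in range(size)), r, A)
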