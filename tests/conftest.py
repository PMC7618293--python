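import numpy as np
import pytest

from sptpalm import dstar, sample_dstar_records
from sptpalm.simulate import sample_track_lengths

# three-species ground truth used across the suite: amplitudes and apparent
# diffusion coefficients of the very-slow / slow / fast populations
TRUTH_AMPLITUDES = np.array([0.41, 0.47, 0.12])
TRUTH_DSTARS = np.array([0.15, 0.33, 0.99])
FRAME_INTERVAL_S = 0.01064


@pytest.fixture(scope="session")
def three_species_records():
    """20k-track synthetic D* dataset from the three-species truth."""
    return sample_dstar_records(TRUTH_AMPLITUDES, TRUTH_DSTARS, 20_000, seed=101)


@pytest.fixture(scope="session")
def three_species_fit(three_species_records):
    return dstar.fit_mixture(three_species_records, 3)


@pytest.fixture(scope="session")
def literature_model():
    """Mixture model at the literature point estimate, with realistic
    track-length weights (geometric, mean ~10.6 steps, minimum 4)."""
    rng = np.random.default_rng(7)
    n = sample_track_lengths(100_000, rng)
    return dstar.MixtureModel(
        components=(
            dstar.MixtureComponent("very_slow", 0.41, 0.15),
            dstar.MixtureComponent("slow", 0.47, 0.33),
            dstar.MixtureComponent("fast", 0.12, 0.99),
        ),
        length_weights=dstar.empirical_length_weights(n),
    )
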