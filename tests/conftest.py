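import numpy as np
import pytest

from irbind import (
    NoiseModel,
    PromoterBindingModel,
    TitrationDesign,
    rv2827c_promoter_model,
    simulate_emsa,
)

PAPER_KDS_UM = (0.0205, 0.121, 0.862, 11.0)


@pytest.fixture
def four_site_model() -> PromoterBindingModel:
    """The four-operator promoter model with the measured per-repeat affinities."""
    return rv2827c_promoter_model()


@pytest.fixture
def noiseless_single_site_table():
    """Factory: noiseless 12-lane titration (plus zero lane) from one Kd."""

    def make(kd: float, n_lanes: int = 12, decades: float = 2.0):
        model = PromoterBindingModel.from_kds([kd])
        design = TitrationDesign.log_spaced(kd, decades=decades, n_lanes=n_lanes, replicates=1)
        return simulate_emsa(model, design, NoiseModel(multiplicative_sigma=0.0))

    return make


def poisson_binomial(ps) -> np.ndarray:
    """Independent oracle: distribution of the number of successes among
    independent Bernoulli trials, by polynomial convolution."""
    probs = np.array([1.0])
    for p in ps:
        nxt = np.zeros(len(probs) + 1)
        nxt[:-1] += probs * (1.0 - p)
        nxt[1:] += probs * p
        probs = nxt
    return probs
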