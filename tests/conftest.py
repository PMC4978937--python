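import numpy as np
import pytest

from footmix import (
    BinningScheme,
    BindingModeSpec,
    ModelParams,
    PriorCoefficients,
    StrandChromatinParams,
    clip_counts,
    make_binning,
    make_toy_model,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def tiny_model():
    """Fully enumerable toy: L=2, margin=2, window length 4, K=0.

    Bound spatial masses are deliberately non-uniform so the posterior is
    informative even at tiny totals.
    """
    binning_bound = make_binning(L=2, margin=2, bin_width=2, mode="bound")
    binning_unbound = make_binning(L=2, margin=2, bin_width=2, mode="unbound")
    modes = BindingModeSpec.monomer(n_features=1)
    prior = PriorCoefficients(beta0=np.array([0.5]), beta=np.array([[1.2]]))
    states = [
        {"+": StrandChromatinParams(p=0.4, r=1.5, lam=np.array([1.0])),
         "-": StrandChromatinParams(p=0.4, r=1.5, lam=np.array([1.0]))},
        {"+": StrandChromatinParams(p=0.7, r=2.0, lam=np.array([0.5, 0.1, 0.4])),
         "-": StrandChromatinParams(p=0.7, r=2.0, lam=np.array([0.3, 0.2, 0.5]))},
    ]
    return ModelParams(prior=prior, modes=modes, states=states,
                       binning=[binning_unbound, binning_bound], delta=0.5)


@pytest.fixture(scope="session")
def tiny_dimer_model():
    """Enumerable K=1 toy for the brute-force Bayes oracle."""
    binning_bound = make_binning(L=2, margin=2, bin_width=2, mode="bound")
    binning_unbound = make_binning(L=2, margin=2, bin_width=2, mode="unbound")
    gamma = np.array([[True, False], [True, True]])
    modes = BindingModeSpec(gamma=gamma,
                            partner_features=[None, "partner_score_2"],
                            feature_names=["motif_score", "partner_score_2"])
    prior = PriorCoefficients(beta0=np.array([0.3, -0.4]),
                              beta=np.array([[1.0, 0.0], [0.8, 1.1]]))
    states = [
        {"+": StrandChromatinParams(p=0.35, r=1.0, lam=np.array([1.0])),
         "-": StrandChromatinParams(p=0.35, r=1.0, lam=np.array([1.0]))},
        {"+": StrandChromatinParams(p=0.6, r=2.0, lam=np.array([0.5, 0.1, 0.4])),
         "-": StrandChromatinParams(p=0.6, r=2.0, lam=np.array([0.3, 0.2, 0.5]))},
        {"+": StrandChromatinParams(p=0.75, r=1.5, lam=np.array([0.2, 0.5, 0.3])),
         "-": StrandChromatinParams(p=0.75, r=1.5, lam=np.array([0.6, 0.1, 0.3]))},
    ]
    return ModelParams(prior=prior, modes=modes, states=states,
                       binning=[binning_unbound, binning_bound, binning_bound],
                       delta=0.5)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated dataset shared across tests (raw + clipped)."""
    model = make_toy_model(K=0, L=6, margin=60, seed=11)
    ds = simulate_dataset(model, 400, seed=11)
    return ds, clip_counts(ds.matrices)


def enumerate_compositions(total, length):
    """All non-negative integer vectors of given length summing to total."""
    if length == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in enumerate_compositions(total - first, length - 1):
            yield (first,) + rest
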