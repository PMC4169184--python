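import numpy as np
import pytest

from growthsde import EMConfig, GrowthParams

# true-parameter sets used throughout the synthetic studies (K, r, P, nu, sigma)
SET1 = GrowthParams(K=0.15, r=3.0, P=1e-4, nu=0.005, sigma=0.01)
SET2 = GrowthParams(K=0.11, r=4.0, P=5e-5, nu=0.001, sigma=0.05)
SET3 = GrowthParams(K=0.30, r=6.0, P=2e-4, nu=0.01, sigma=0.02)
# ensemble-comparison set (no measurement error)
FIG_ENSEMBLE = GrowthParams(K=0.11, r=4.0, P=5e-5, sigma=0.05)


@pytest.fixture(scope="session")
def set1():
    return SET1


@pytest.fixture(scope="session")
def set2():
    return SET2


@pytest.fixture(scope="session")
def set3():
    return SET3


@pytest.fixture(scope="session")
def fig_ensemble_params():
    return FIG_ENSEMBLE


@pytest.fixture(scope="session")
def lognormal_set1():
    """One lognormal-error synthetic dataset from parameter set 1."""
    from growthsde import make_synthetic_dataset

    return make_synthetic_dataset(SET1, "lognormal", EMConfig(seed=11))


@pytest.fixture(scope="session")
def normal_set1():
    """One normal-error synthetic dataset from parameter set 1."""
    from growthsde import make_synthetic_dataset

    return make_synthetic_dataset(SET1, "normal", EMConfig(seed=11))


@pytest.fixture(scope="session")
def lnaa_chain_set1(normal_set1):
    """LNAA posterior chain fitted to the normal-error set-1 dataset."""
    from growthsde import McmcConfig, PriorHyper, mwg_sample

    hyper = PriorHyper.default_for(normal_set1.timecourse)
    cfg = McmcConfig(n_burn=10_000, thin=40, n_keep=800, seed=5)
    return mwg_sample("lnaa", normal_set1.timecourse, hyper, cfg)


@pytest.fixture(scope="session")
def lnam_chain_set1(lognormal_set1):
    """LNAM posterior chain fitted to the lognormal-error set-1 dataset."""
    from growthsde import McmcConfig, PriorHyper, mwg_sample

    hyper = PriorHyper.default_for(lognormal_set1.timecourse)
    cfg = McmcConfig(n_burn=8000, thin=20, n_keep=500, seed=3)
    return mwg_sample("lnam", lognormal_set1.timecourse, hyper, cfg)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
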