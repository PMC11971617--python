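from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import regpcm as rp

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def aggression():
    return rp.load_aggression()


@pytest.fixture(scope="session")
def example_fit(aggression):
    """The v=6 example fit (with covariance), shared across the suite."""
    return rp.fit(aggression, rp.CGFSpec(v=6), y0=(0, 0, 0, 0, 0))


@pytest.fixture(scope="session")
def expected_eap():
    return pd.read_csv(DATA_DIR / "expected_eap.csv")


@pytest.fixture(scope="session")
def expected_estimates():
    df = pd.read_csv(DATA_DIR / "expected_estimates.csv")
    return df.set_index("param")


@pytest.fixture()
def toy_two_pattern():
    """k=1 dichotomous item, beta=0, alpha=1, normal CGF, B={(0),(1)}.

    Hand-computed: weights (1, e^0.5), probabilities (0.37754, 0.62246).
    """
    design = rp.TestDesign(m=(1,))
    spec = rp.CGFSpec(v=2)
    return rp.ModelParams(
        design=design,
        beta=np.zeros(1),
        alpha=np.ones(1),
        eps=spec.epsilons(),
        y0=(0,),
        support=np.array([[0], [1]]),
    )


@pytest.fixture(scope="session")
def small_sim_data():
    """Pattern data simulated from a known k=3 model (full support)."""
    design = rp.TestDesign(m=(2, 2, 2))
    spec = rp.CGFSpec(v=4, deg2=1)
    params = rp.ModelParams(
        design=design,
        beta=np.array([-1.5, -4.0, -1.2, -3.5, -1.8, -4.5]),
        alpha=np.array([0.7, 0.6, 0.8]),
        eps=spec.epsilons([0.08, -0.05]),
        y0=(0, 0, 0),
        support=rp.all_patterns(design),
    )
    data = rp.simulate_from_model(params, 20000, seed=20240901)
    return params, data
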