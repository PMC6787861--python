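"""Shared fixtures: one synthetic study-design dataset at the published truth
values, and the expensive session-scoped artefacts (final-model fit, stepwise
selection run, simulate-and-refit recovery experiment) reused across tests."""

import numpy as np
import pytest

import lfmcdyn as L

#: printed 95% confidence intervals of the reference fit for this design
#: (used to check that estimates on data generated at the same truth are
#: compatible with the reported uncertainty)
REFERENCE_CI = {
    "A0": (42.5, 66.0),
    "A[GE]": (13.5, 48.3),
    "A[SM]": (191.9, 254.6),
    "A[SS]": (207.1, 273.5),
    "w0": (25.7, 32.4),
    "w[GE]": (-25.8, -15.6),
    "w[SM]": (16.4, 47.0),
    "w[SS]": (11.1, 42.9),
    "m": (26.9, 35.0),
    "s": (-20.8, -11.5),
    "sigma": (6.0, 8.6),
    "delta(GE)": (0.7, 1.2),
    "delta(SM)": (2.4, 4.0),
    "delta(SS)": (2.4, 3.9),
    "sd(A)": (3.9, 15.8),
}


@pytest.fixture(scope="session")
def truth():
    return L.GeneratingParams()


@pytest.fixture(scope="session")
def dataset(truth):
    """One synthetic dataset with the full field design (n = 247)."""
    return L.simulate_dataset(L.DesignSpec(), truth, seed=1)


@pytest.fixture(scope="session")
def m1_fit(dataset):
    """The final drying-curve model fitted to the session dataset."""
    return L.LfmcModel(dataset, L.ModelSpec.final_lfmc()).fit(seed=0)


@pytest.fixture(scope="session")
def selection_run(dataset):
    """The full stepwise protocol on the session dataset."""
    return L.select_model(dataset, L.ProtocolConfig(seed=0))


@pytest.fixture(scope="session")
def recovery(truth):
    """Simulate-and-refit experiment: 50 replicates at design scale with the
    generating truth, keeping the per-replicate results objects."""
    table, info = L.recovery_experiment(truth, L.DesignSpec(), n_reps=50,
                                        seed=42, keep_fits=True)
    return table, info


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
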