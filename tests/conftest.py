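import warnings

import numpy as np
import pytest

from cerebropdm import (LaguerreVolterraModel, SimulationConfig,
                        discrete_laguerre_basis, make_ground_truth,
                        simulate_cohort, simulate_inputs, simulate_subject)
from cerebropdm.laguerre import IdentifiabilityWarning


@pytest.fixture(autouse=True)
def _quiet_identifiability():
    # the 6-min default cohort sits just below 5 samples per parameter, so
    # this warning fires on nearly every fit; it has its own dedicated test
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IdentifiabilityWarning)
        yield


@pytest.fixture(scope="session")
def basis():
    return discrete_laguerre_basis(0.5, 5)


@pytest.fixture()
def rng():
    # fresh, identically seeded generator per test: results do not depend
    # on test execution order
    return np.random.default_rng(20260922)


def make_subject(seed=0, snr_db=np.inf, group="placebo", condition="pre",
                 subject_index=0, **cfg_kwargs):
    """One synthetic recording plus its ground truth."""
    cfg = SimulationConfig(seed=seed, snr_db=snr_db, **cfg_kwargs)
    system = make_ground_truth(cfg, group, condition, subject_index)
    bp, co2 = simulate_inputs(cfg, subject_index=subject_index, group=group,
                              condition=condition)
    rec = simulate_subject(system, bp, co2, cfg)
    return rec, system


@pytest.fixture(scope="session")
def noisefree_subject():
    return make_subject(seed=11, snr_db=np.inf)


@pytest.fixture(scope="session")
def default_cohort():
    """The default two-arm cohort (seed 0), shared across tests."""
    return simulate_cohort(SimulationConfig(seed=0))


def fit_recording(rec, **kwargs):
    return LaguerreVolterraModel.from_recording(rec, **kwargs).fit()
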