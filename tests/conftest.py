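"""Shared fixtures: simulated cohorts and their (expensive) model fits.

The recovery/selection cohorts use the canonical well-separated regime
(A1 = 40, A2 = 10 spikes/s, p_attend_fix = 0.5, p_attend_in = 0.7,
a1 = 1.5, a2 = 0.8, gamma1 = -3) at three times the experiment's median
trial counts; fits are session-scoped so every test shares them.
"""

import numpy as np
import pytest

import spikemix as sm
from spikemix.fitting import FitOptions, fit_both_models

COHORT_TRIALS = {"fix1": 12, "fix2": 12, "attend-fix": 12, "attend-in": 36}
N_MIXING = 10
N_AVERAGING = 8

#: reduced optimizer budget for unit tests on small datasets
FAST_OPTIONS = FitOptions(direct_maxfun=500, nm_maxfev=1500, nm_restarts=2)


@pytest.fixture(scope="session")
def cohort_design():
    return sm.build_design(trials_per_cell=COHORT_TRIALS)

@pytest.fixture(scope="session")
def mixing_truth():
    return sm.default_ground_truth("mixing")


@pytest.fixture(scope="session")
def averaging_truth():
    return sm.default_ground_truth("averaging")


@pytest.fixture(scope="session")
def mixing_cohort(cohort_design, mixing_truth):
    """(records, latent labels) for the mixing-generated cohort."""
    return sm.simulate_dataset(cohort_design, mixing_truth, N_MIXING, seed=11)


@pytest.fixture(scope="session")
def averaging_cohort(cohort_design, averaging_truth):
    return sm.simulate_dataset(cohort_design, averaging_truth, N_AVERAGING, seed=12)


@pytest.fixture(scope="session")
def mixing_cohort_fits(mixing_cohort):
    """Both models fitted to every mixing-generated neuron."""
    records, _ = mixing_cohort
    return {
        nid: fit_both_models(recs)
        for nid, recs in sm.group_by_neuron(records).items()
    }


@pytest.fixture(scope="session")
def averaging_cohort_fits(averaging_cohort):
    records, _ = averaging_cohort
    return {
        nid: fit_both_models(recs)
        for nid, recs in sm.group_by_neuron(records).items()
    }


def make_train(times, T=500.0):
    return sm.SpikeTrain(times=np.asarray(times, dtype=float), T=T)


def evenly_spaced_train(n_spikes, T=500.0):
    """A train with n evenly spaced spikes (helper for rate-only tests)."""
    if n_spikes == 0:
        return sm.SpikeTrain(times=np.zeros(0), T=T)
    step = T / (n_spikes + 1)
    times = np.round(np.arange(1, n_spikes + 1) * step)
    return sm.SpikeTrain(times=times, T=T)
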