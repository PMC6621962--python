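"""Shared fixtures: small landscapes, a simulated study, known-truth HMM data."""

import numpy as np
import pandas as pd
import pytest

from bearmove import simulate
from bearmove.landscape import make_landscape


@pytest.fixture(scope="session")
def land():
    """Small landscape for extraction and home-range tests."""
    return make_landscape(shape=(120, 120), seed=3)


@pytest.fixture(scope="session")
def wide_land():
    """Landscape whose interior is much wider than the largest kernel,
    so large-sigma availability is not edge-biased."""
    return make_landscape(shape=(600, 600), seed=11, autocorr_range=200.0)


@pytest.fixture(scope="session")
def study():
    return simulate.default_study(n_bears=3, seed=1, shape=(200, 200))


@pytest.fixture(scope="session")
def tracks(study):
    return simulate.simulate_tracks(study, duration_days=20, seed=1)


def make_hmm_truth_series(n=3000, seed=7):
    """A state sequence plus gamma/von Mises emissions from the default truth."""
    truth = simulate.HMMTruth()
    rng = np.random.default_rng(seed)
    tpm = np.asarray(truth.tpm)
    means = np.asarray(truth.step_means)
    sds = np.asarray(truth.step_sds)
    mus = np.asarray(truth.angle_means)
    kappas = np.asarray(truth.angle_kappas)
    s = rng.choice(3, p=np.asarray(truth.initial))
    states = np.empty(n, int)
    for t in range(n):
        states[t] = s
        s = rng.choice(3, p=tpm[s])
    shape = means**2 / sds**2
    scale = sds**2 / means
    lengths = rng.gamma(shape[states], scale[states])
    angles = rng.vonmises(mus[states], kappas[states])
    angles[0] = np.nan
    return {
        "states": states,
        "lengths": lengths,
        "angles": angles,
        "truth": truth,
        "tpm": tpm,
        "means": means,
        "sds": sds,
        "mus": mus,
        "kappas": kappas,
    }


@pytest.fixture(scope="session")
def hmm_series():
    return make_hmm_truth_series()
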