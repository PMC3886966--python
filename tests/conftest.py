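import numpy as np
import pytest

import pparclock as pc


@pytest.fixture(scope="session")
def bmal1_forcing():
    """Analytic cosinor BMAL1 drive (mesor 1, amplitude 0.5, peak 10 AM)."""
    return pc.default_bmal1_forcing()


@pytest.fixture(scope="session")
def base_params():
    """Lean-control ground-truth kinetics of the stepwise scenario."""
    return pc.stepwise_degradation_params()[("lean", "control")]


@pytest.fixture(scope="session")
def cosinor_dataset():
    """One seeded draw of the null cosinor scenario (4 groups x 6 times x 4)."""
    return pc.synth_dataset(pc.cosinor_scenario("null", seed=7))


@pytest.fixture(scope="session")
def ppar_dataset(bmal1_forcing):
    """One seeded draw of the stepwise-degradation scenario plus its truth."""
    return pc.synth_ppar_groups(bmal1_forcing, seed=3)


def make_curve(times, means, sems=None, ns=None, gene="BMAL1",
               maternal="lean", diet="control"):
    times = np.asarray(times, dtype=float)
    means = np.asarray(means, dtype=float)
    sems = np.zeros_like(means) if sems is None else np.asarray(sems, float)
    ns = np.full(len(means), 4) if ns is None else np.asarray(ns)
    return pc.GroupMeanCurve(gene=gene, maternal=maternal, diet=diet,
                             times=times, means=means, sems=sems, ns=ns)
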