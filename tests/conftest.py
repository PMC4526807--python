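"""Shared fixtures.

The heavier simulated tables are session-scoped so that unit tests and the
acceptance suite reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from shepnet import NetworkParams, TonotopicGrid, simulate
from shepnet.experiments import (
    bias_trial_demo,
    buildup_experiment,
    frequency_shift_tuning,
    single_bias_sweep,
    step_response_curve,
    tuning_curves,
)
from shepnet.readout import decisions
from shepnet.stimuli import InputDrive, make_tritone_trial, mirror_sequence


@pytest.fixture(scope="session")
def ring() -> TonotopicGrid:
    return TonotopicGrid.ring()


@pytest.fixture(scope="session")
def params() -> NetworkParams:
    return NetworkParams()


@pytest.fixture(scope="session")
def step_table():
    """D vs step for all integer steps, three pauses, both synapse modes."""
    return step_response_curve()


@pytest.fixture(scope="session")
def tuning_table():
    """Context-free tuning curves of the units at PC = 6 st."""
    return tuning_curves()


@pytest.fixture(scope="session")
def bias_sweep_narrow():
    """Single-bias-tone sweep, narrow tuning, 0.25-st resolution."""
    return single_bias_sweep(tuning="narrow")


@pytest.fixture(scope="session")
def bias_sweep_broad():
    return single_bias_sweep(tuning="broad")


@pytest.fixture(scope="session")
def freq_shift_table():
    """Frequency-shift tuning for both chord spacings, inner components 2-5."""
    return frequency_shift_tuning()


@pytest.fixture(scope="session")
def buildup_result():
    """Psychometric buildup, broad tuning, 100 trials per N_bias point."""
    return buildup_experiment(trials_per_point=100, tuning="broad", seed=0)


@pytest.fixture(scope="session")
def updown_decisions(ring):
    """100 seeded 10-tone Up-bias trials and their exact Down-bias mirrors."""
    n_trials = 100
    root = np.random.SeedSequence(0)
    seqs_up = [
        make_tritone_trial(0.0, 10, "up", rng=np.random.default_rng(ss))
        for ss in root.spawn(n_trials)
    ]
    seqs_down = [mirror_sequence(s, axis_st=0.0) for s in seqs_up]
    window = seqs_up[0].window("T2")
    d = {}
    for name, seqs in (("up", seqs_up), ("down", seqs_down)):
        drive = InputDrive.from_sequences(seqs, ring)
        trace = simulate(drive, record="windows", windows=[window])
        d[name] = decisions(trace, window)["D"].to_numpy()
    return d


@pytest.fixture(scope="session")
def biased_trial(ring):
    """One fully recorded 10-tone Up-bias trial (trace, decisions, F snapshot)."""
    return bias_trial_demo(t1_pc=4.0, n_bias=10, direction="up", seed=0)
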