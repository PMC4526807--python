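"""Scripted, seeded simulation protocols (parameter sweeps with tabular output).

Each experiment mirrors one of the model's simulated paradigms:

* ``step_response_curve`` — D vs pitch-class step for a sequential tone
  pair, for several pauses, with facilitating or static inhibition.
* ``tuning_curves`` — E_up/E_down tuning curves of a unit, optionally after
  a biasing context; with a skewness summary.
* ``pair_response_map`` — per-unit peak response to T2 across (T1, T2)
  combinations, averaged over runs with a random-pitch pre-tone.
* ``bias_trial_demo`` — one full biased tritone trial with trace,
  facilitation snapshot and currents.
* ``single_bias_sweep`` — D for the tritone pair vs the pitch of a single
  bias tone, narrow vs broad inhibitory tuning.
* ``buildup_experiment`` — Monte-Carlo psychometric buildup P(up) vs N_bias.
* ``heterogeneous_aie_sweep`` — D vs T2 for tritone pairs when the
  inhibitory synaptic strength a_ie varies along the tonotopic axis.
* ``frequency_shift_tuning`` — D vs frequency shift of a test tone against
  a chord of pure tones on a non-periodic (line) tonotopy.

All experiments are deterministic given their seed; trials that share event
timing are integrated in lockstep as one batch.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dynamics import NetworkParams, simulate
from .grids import ST_PER_OCT, TonotopicGrid
from .readout import DEFAULT_THRESHOLD, decisions, psychometric
from .stimuli import (
    InputDrive,
    ToneEvent,
    ToneSequence,
    TrialTiming,
    line_grid_for_chord,
    make_chord_drive,
    make_tritone_trial,
    pitch_class,
)

__all__ = [
    "ExperimentSpec",
    "params_for",
    "step_response_curve",
    "tuning_curves",
    "tuning_skewness",
    "pair_response_map",
    "bias_trial_demo",
    "single_bias_sweep",
    "buildup_experiment",
    "default_aie_bump",
    "heterogeneous_aie_sweep",
    "frequency_shift_tuning",
]


@dataclass(frozen=True)
class ExperimentSpec:
    """Serializable description of one experiment run (name + knobs + seed)."""

    name: str
    seed: int = 0
    tuning: str = "narrow"
    trials: int = 100
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def params_for(tuning: str, **overrides) -> NetworkParams:
    """Narrow- or broad-inhibitory-tuning parameter set with overrides."""
    if tuning == "narrow":
        return NetworkParams.narrow(**overrides)
    if tuning == "broad":
        return NetworkParams.broad(**overrides)
    raise ValueError("tuning must be 'narrow' or 'broad'")


def _batch_decisions(
    seqs: list[ToneSequence],
    params: NetworkParams,
    grid: TonotopicGrid,
    role: str = "T2",
    threshold: float = DEFAULT_THRESHOLD,
    **sim_kw,
) -> pd.DataFrame:
    """Simulate same-timing sequences in one batch; decisions during `role`."""
    drive = InputDrive.from_sequences(seqs, grid)
    window = seqs[0].window(role)
    trace = simulate(drive, params, record="windows", windows=[window], **sim_kw)
    return decisions(trace, window, threshold=threshold)


def step_response_curve(
    steps: Sequence[float] = tuple(range(-6, 7)),
    pauses: Sequence[float] = (50.0, 100.0, 200.0),
    facilitation: Sequence[str] = ("on", "off"),
    t1_pc: float = 0.0,
    params: NetworkParams | None = None,
    grid: TonotopicGrid | None = None,
) -> pd.DataFrame:
    """D during T2 vs pitch-class step T2 - T1, per pause and synapse mode.

    "off" freezes facilitation (gamma_f = 0 — static inhibitory synapses);
    "on" keeps the slow facilitation dynamics.
    """
    params = params or NetworkParams()
    grid = grid or TonotopicGrid.ring()
    rows = []
    for pause in pauses:
        timing = TrialTiming(iti=pause)
        seqs = []
        for step in steps:
            t2_on = timing.dur + pause
            seqs.append(
                ToneSequence(
                    (
                        ToneEvent(pitch_class(t1_pc), 0.0, timing.dur, role="T1"),
                        ToneEvent(pitch_class(t1_pc + step), t2_on, timing.dur, role="T2"),
                    )
                )
            )
        for mode in facilitation:
            p = params if mode == "on" else replace(params, gamma_f=0.0)
            table = _batch_decisions(seqs, p, grid)
            for step, d in zip(steps, table["D"]):
                rows.append({"step": step, "pause": pause, "facilitation": mode, "D": d})
    return pd.DataFrame(rows)


def tuning_curves(
    unit_pc: float = 6.0,
    probe_pcs: Sequence[float] | None = None,
    context: ToneSequence | None = None,
    params: NetworkParams | None = None,
    grid: TonotopicGrid | None = None,
    timing: TrialTiming = TrialTiming(),
) -> pd.DataFrame:
    """Peak firing rate of the E_up and E_down units at ``unit_pc`` for
    probe Shepard tones of every pitch class (100-ms tones).

    With ``context``, the context sequence precedes each probe by the
    standard 500-ms gap (probing the post-bias tuning).
    """
    params = params or NetworkParams()
    grid = grid or TonotopicGrid.ring()
    if probe_pcs is None:
        probe_pcs = np.arange(0.0, 12.0, 0.25)
    idx = grid.index_near(unit_pc)
    seqs = []
    for pc in probe_pcs:
        events = []
        t = 0.0
        if context is not None:
            events.extend(context.events)
            t = context.t_end + timing.gap
        events.append(ToneEvent(pitch_class(pc), t, timing.dur, role="probe"))
        seqs.append(ToneSequence(tuple(events)))
    drive = InputDrive.from_sequences(seqs, grid)
    window = seqs[0].window("probe")
    trace = simulate(drive, params, record="windows", windows=[window])
    ws = trace.window_stats(window)
    return pd.DataFrame(
        {
            "probe_pc": np.asarray(probe_pcs, dtype=float),
            "r_up_peak": ws.peak_up[:, idx],
            "r_down_peak": ws.peak_down[:, idx],
        }
    )


def tuning_skewness(curve: pd.DataFrame, unit_pc: float, column: str = "r_up_peak") -> float:
    """Direction and degree of a tuning curve's lean about the unit's PC.

    Returns the normalized response-mass imbalance
    (sum below - sum above) / (sum below + sum above) over the signed
    circular distance of the probe from the unit: positive values mean the
    curve leans toward lower pitch classes (the E_up signature), negative
    toward higher (E_down).  The raw third-moment skewness is deliberately
    not used: for these curves it is dominated by the far tail and can
    contradict the visible lean of the peak.
    """
    d = np.array([((p - unit_pc + 6.0) % ST_PER_OCT) - 6.0 for p in curve["probe_pc"]])
    w = np.clip(np.asarray(curve[column], dtype=float), 0.0, None)
    below = w[d < 0].sum()
    above = w[d > 0].sum()
    if below + above <= 0:
        raise ValueError("tuning curve has no mass")
    return float((below - above) / (below + above))


def pair_response_map(
    unit_pc: float = 6.0,
    t1_grid: Sequence[float] | None = None,
    t2_grid: Sequence[float] | None = None,
    n_runs: int = 10,
    params: NetworkParams | None = None,
    grid: TonotopicGrid | None = None,
    timing: TrialTiming = TrialTiming(),
    seed: int = 0,
    pre_tone: bool = True,
) -> pd.DataFrame:
    """Peak rate of the units at ``unit_pc`` during T2, per (T1, T2) pair.

    A Shepard tone of random pitch class precedes T1 in every run
    (randomized initial conditions); results are averaged over ``n_runs``.
    ``pre_tone=False`` drops the random pre-tone (deterministic maps, used
    for symmetry checks).
    """
    params = params or NetworkParams()
    grid = grid or TonotopicGrid.ring()
    if t1_grid is None:
        t1_grid = np.arange(0.0, 12.0, 0.5)
    if t2_grid is None:
        t2_grid = np.arange(0.0, 12.0, 0.5)
    idx = grid.index_near(unit_pc)
    cells = [(float(a), float(b)) for a in t1_grid for b in t2_grid]
    rng = np.random.default_rng(seed)
    up = np.zeros(len(cells))
    down = np.zeros(len(cells))
    step = timing.dur + timing.iti
    for _ in range(n_runs):
        pre = rng.uniform(0.0, 12.0)
        seqs = [
            ToneSequence(
                (
                    *((ToneEvent(pre, 0.0, timing.dur, role="pre"),) if pre_tone else ()),
                    ToneEvent(a, step, timing.dur, role="T1"),
                    ToneEvent(b, 2 * step, timing.dur, role="T2"),
                )
            )
            for a, b in cells
        ]
        drive = InputDrive.from_sequences(seqs, grid)
        window = seqs[0].window("T2")
        trace = simulate(drive, params, record="windows", windows=[window])
        ws = trace.window_stats(window)
        up += ws.peak_up[:, idx]
        down += ws.peak_down[:, idx]
    out = pd.DataFrame(cells, columns=["T1", "T2"])
    out["r_up_peak"] = up / n_runs
    out["r_down_peak"] = down / n_runs
    return out


def bias_trial_demo(
    t1_pc: float = 4.0,
    n_bias: int = 10,
    direction: str = "up",
    seed: int = 0,
    params: NetworkParams | None = None,
    grid: TonotopicGrid | None = None,
    timing: TrialTiming = TrialTiming(),
):
    """One fully recorded biased tritone trial.

    Returns (trace, decision_table, F_at_T2_onset); the trace carries the
    complete fields so snapshots and synaptic currents can be inspected.
    """
    params = params or NetworkParams()
    grid = grid or TonotopicGrid.ring()
    seq = make_tritone_trial(t1_pc, n_bias, direction, timing, rng=seed)
    drive = InputDrive.from_sequence(seq, grid)
    window = seq.window("T2")
    trace = simulate(drive, params, record="full", windows=[window])
    table = decisions(trace, window)
    f_snapshot = trace.state_at(window[0]).F[0]
    return trace, table, f_snapshot


def single_bias_sweep(
    bias_pcs: Sequence[float] | None = None,
    tuning: str = "narrow",
    t1_pc: float = 0.0,
    params: NetworkParams | None = None,
    grid: TonotopicGrid | None = None,
    timing: TrialTiming = TrialTiming(),
) -> pd.DataFrame:
    """D for the tritone pair (T1, T1+6) vs the pitch of one bias tone.

    Default sweep: 0.25-st grid strictly between T1 and T2.  The narrow- vs
    broad-tuning regimes place the most effective bias tone differently
    (about 1 st below T2 vs near the midpoint).
    """
    if params is None:
        params = params_for(tuning)
    grid = grid or TonotopicGrid.ring()
    if bias_pcs is None:
        bias_pcs = np.arange(0.25, 6.0, 0.25) + t1_pc
    t1_on = timing.dur + timing.gap
    t2_on = t1_on + timing.dur + timing.iti
    seqs = [
        ToneSequence(
            (
                ToneEvent(pitch_class(pc), 0.0, timing.dur, role="bias"),
                ToneEvent(pitch_class(t1_pc), t1_on, timing.dur, role="T1"),
                ToneEvent(pitch_class(t1_pc + 6.0), t2_on, timing.dur, role="T2"),
            ),
            n_bias=1,
        )
        for pc in bias_pcs
    ]
    table = _batch_decisions(seqs, params, grid)
    return pd.DataFrame(
        {"bias_pc": np.asarray(bias_pcs, dtype=float), "D": table["D"], "tuning": tuning}
    )


def buildup_experiment(
    n_bias_values: Sequence[int] = (1, 2, 4, 6, 8, 10),
    trials_per_point: int = 100,
    tuning: str = "broad",
    tau_fd: float = 2000.0,
    t1_pc: float = 0.0,
    direction: str = "up",
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    grid: TonotopicGrid | None = None,
    timing: TrialTiming = TrialTiming(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Psychometric buildup: P(up) vs number of bias tones.

    Each trial draws a fresh random bias sequence; the default protocol is
    the tritone pair at (0, 6) st with Up bias and the ascending-choice
    threshold D > 0.1.  Per-trial sub-seeds are spawned deterministically
    from ``seed`` so earlier trials are unchanged when the count grows.
    Returns (trial_table, psychometric_table); the psychometric table has
    binomial SEM per point.

    The full printed protocol uses 400 trials per point; the default of 100
    keeps routine runs light.
    """
    if trials_per_point < 1:
        raise ValueError("need at least one trial per point")
    grid = grid or TonotopicGrid.ring()
    params = params_for(tuning, tau_fd=tau_fd)
    tables = []
    root = np.random.SeedSequence(seed)
    for n_bias, ss in zip(n_bias_values, root.spawn(len(n_bias_values))):
        child_seeds = ss.spawn(trials_per_point)
        seqs = [
            make_tritone_trial(t1_pc, int(n_bias), direction, timing,
                               rng=np.random.default_rng(cs))
            for cs in child_seeds
        ]
        table = _batch_decisions(seqs, params, grid, threshold=threshold)
        table["N_bias"] = int(n_bias)
        tables.append(table)
    trial_table = pd.concat(tables, ignore_index=True)
    return trial_table, psychometric(trial_table, by="N_bias")


def default_aie_bump(
    center_st: float = 6.0,
    amplitude: float = 0.5,
    width_st: float = 2.0,
    base: float = 1.5,
) -> Callable[[np.ndarray], np.ndarray]:
    """Gaussian bump profile for heterogeneous inhibitory strength a_ie(x).

    a_ie(x) = base + amplitude * exp(-d(x, center)^2 / width^2) with circular
    distance on the pitch-class ring.  Its slope is steepest at
    center +/- width/sqrt(2), which is where tritone-pair decisions are
    predicted to deviate most from zero.
    """

    def profile(st: np.ndarray) -> np.ndarray:
        d = ((np.asarray(st) - center_st + 6.0) % ST_PER_OCT) - 6.0
        return base + amplitude * np.exp(-(d**2) / width_st**2)

    return profile


def heterogeneous_aie_sweep(
    a_ie_profile: Callable | np.ndarray | float | None = None,
    t2_pcs: Sequence[float] | None = None,
    params: NetworkParams | None = None,
    grid: TonotopicGrid | None = None,
    timing: TrialTiming = TrialTiming(),
) -> pd.DataFrame:
    """D for context-free tritone pairs (T2 - 6, T2) at every T2.

    With homogeneous a_ie the pair is perfectly ambiguous everywhere
    (D = 0); a tonotopically varying a_ie produces a sinusoidal-like D
    pattern with extrema where |da_ie/dx| is largest.
    """
    params = params or NetworkParams()
    grid = grid or TonotopicGrid.ring()
    if a_ie_profile is None:
        a_ie_profile = default_aie_bump()
    params = replace(params, a_ie=a_ie_profile)
    if t2_pcs is None:
        t2_pcs = np.arange(0.0, 12.0, 0.5)
    t2_on = timing.dur + timing.iti
    seqs = [
        ToneSequence(
            (
                ToneEvent(pitch_class(pc - 6.0), 0.0, timing.dur, role="T1"),
                ToneEvent(pitch_class(pc), t2_on, timing.dur, role="T2"),
            )
        )
        for pc in t2_pcs
    ]
    table = _batch_decisions(seqs, params, grid)
    return pd.DataFrame({"T2": np.asarray(t2_pcs, dtype=float), "D": table["D"]})


def frequency_shift_tuning(
    spacings: Sequence[float] = (0.5, 1.0),
    shifts: Sequence[float] | None = None,
    inner_components: Sequence[int] = (1, 2, 3, 4),
    n_components: int = 6,
    params: NetworkParams | None = None,
    dx: float = 0.01,
    timing: TrialTiming = TrialTiming(),
) -> pd.DataFrame:
    """D vs test-tone frequency shift against a chord, on a line tonotopy.

    The first tone is a chord of ``n_components`` pure tones spaced by each
    ``spacing`` (octaves); the second is a single pure tone at one of the
    inner components (0-based indices, default components 2-5) displaced by
    ``shift`` octaves.  One row per (spacing, component, shift); the
    psychometric-like tuning curve is the mean D over inner components.
    """
    params = params or NetworkParams()
    if shifts is None:
        shifts = np.arange(0.02, 0.301, 0.02)
    rows = []
    for spacing in spacings:
        grid = line_grid_for_chord(n_components, spacing, margin=1.0, dx=dx)
        drives = []
        keys = []
        for comp in inner_components:
            for shift in shifts:
                drives.append(
                    make_chord_drive(n_components, spacing, float(shift), int(comp), grid, timing)
                )
                keys.append((comp, float(shift)))
        # All chord drives share timing; merge into one batch.
        batch = InputDrive(
            grid,
            [
                type(drives[0].events[0])(
                    np.concatenate([d.events[k].profiles for d in drives]),
                    drives[0].events[k].t1,
                    drives[0].events[k].t2,
                )
                for k in range(len(drives[0].events))
            ],
            tau_r=timing.tau_r,
        )
        window = (batch.events[1].t1, batch.events[1].t2)
        trace = simulate(batch, params, record="windows", windows=[window])
        table = decisions(trace, window)
        for (comp, shift), d in zip(keys, table["D"]):
            rows.append({"spacing": spacing, "component": comp, "shift": shift, "D": d})
    return pd.DataFrame(rows)
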