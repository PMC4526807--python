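"""Stimulus construction: Shepard tones, tritone-with-bias paradigms, chords.

A Shepard tone is a stack of synchronous octave-spaced pure tones with a
flat spectral envelope; it is fully described by its pitch class, a point on
a 12-semitone circle.  The model never sees audio: a tone of pitch class x0
drives the network with a Gaussian spatial profile exp(-(x-x0)^2 / sigma_in^2)
(note: no factor 2 in the exponent) gated in time by raised-cosine ramps.
Audio renderings are provided separately for demonstration (``render_wav``).

Default paradigm timing follows the tritone-with-bias protocol: 100 ms
tones, 50 ms inter-tone interval, 500 ms gap between the bias sequence and
the test pair, bias pitches drawn uniformly from the open half-octave above
(Up bias) or below (Down bias) the first test tone T1.
"""

from __future__ import annotations

import wave as _wave
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import ST_PER_OCT, TonotopicGrid

__all__ = [
    "DEFAULT_SIGMA_IN",
    "DEFAULT_TAU_R",
    "TrialTiming",
    "ToneEvent",
    "ToneSequence",
    "InputDrive",
    "ramp",
    "pitch_class",
    "circ_dist_st",
    "gaussian_profile",
    "make_shepard_drive",
    "make_tritone_trial",
    "mirror_sequence",
    "make_chord_drive",
    "line_grid_for_chord",
    "render_wav",
]

#: Spatial width of a single tone's drive profile (octaves).
DEFAULT_SIGMA_IN = 0.1
#: Onset/offset ramp time constant (ms).
DEFAULT_TAU_R = 5.0


def pitch_class(value: float) -> float:
    """Wrap a pitch to the [0, 12) st circle."""
    return float(np.mod(value, ST_PER_OCT))


def circ_dist_st(a: float, b: float) -> float:
    """Signed circular distance a - b in st, in (-6, 6]."""
    d = (a - b) % ST_PER_OCT
    return float(d if d <= 6.0 else d - ST_PER_OCT)


def ramp(t_rel, tau_r: float = DEFAULT_TAU_R):
    """Raised-cosine-squared onset ramp.

    0 for t_rel <= 0, 1 for t_rel >= tau_r, and
    ((cos(pi (t/tau_r + 1)) + 1)/2)^2 in between (monotone, C^1 at both ends).
    """
    if tau_r <= 0:
        raise ValueError("tau_r must be positive")
    u = np.clip(np.asarray(t_rel, dtype=float) / tau_r, 0.0, 1.0)
    out = ((np.cos(np.pi * (u + 1.0)) + 1.0) / 2.0) ** 2
    if np.ndim(t_rel) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class TrialTiming:
    """Paradigm timing in ms."""

    dur: float = 100.0  # tone duration
    iti: float = 50.0  # inter-tone interval (also the tritone pause)
    gap: float = 500.0  # silence between bias sequence and test pair
    tau_r: float = DEFAULT_TAU_R

    def __post_init__(self):
        if self.dur <= 0 or self.iti < 0 or self.gap < 0 or self.tau_r <= 0:
            raise ValueError("invalid trial timing")


@dataclass(frozen=True)
class ToneEvent:
    """A single tone: pitch (st on ring, octave position x 12 on line),
    onset and duration in ms, and a role tag."""

    pitch_st: float
    onset_ms: float
    duration_ms: float
    role: str = "tone"

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("tone duration must be positive")

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass(frozen=True)
class ToneSequence:
    """Ordered, non-overlapping tone events plus paradigm metadata."""

    events: tuple[ToneEvent, ...]
    n_bias: int = 0
    direction: str | None = None  # "up" | "down" | None
    seed: int | None = None

    def __post_init__(self):
        evs = tuple(self.events)
        for a, b in zip(evs, evs[1:]):
            if b.onset_ms < a.offset_ms - 1e-9:
                raise ValueError("tone events overlap or are out of order")
        object.__setattr__(self, "events", evs)

    def by_role(self, role: str) -> list[ToneEvent]:
        return [e for e in self.events if e.role == role]

    def window(self, role: str) -> tuple[float, float]:
        """(onset, offset) of the unique event with the given role."""
        matches = self.by_role(role)
        if len(matches) != 1:
            raise ValueError(f"expected exactly one {role!r} event, got {len(matches)}")
        return (matches[0].onset_ms, matches[0].offset_ms)

    @property
    def t_end(self) -> float:
        return self.events[-1].offset_ms if self.events else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(len(self.events)),
                "role": [e.role for e in self.events],
                "pitch_st": [e.pitch_st for e in self.events],
                "onset_ms": [e.onset_ms for e in self.events],
                "duration_ms": [e.duration_ms for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def gaussian_profile(grid: TonotopicGrid, pitch_st: float, sigma_in: float = DEFAULT_SIGMA_IN) -> np.ndarray:
    """Spatial drive profile of a single tone: exp(-d^2/sigma_in^2).

    d is the (circular, on a ring) distance in octaves between the grid point
    and the tone's position.  The tone is NOT snapped to the grid.
    """
    if sigma_in <= 0:
        raise ValueError("sigma_in must be positive")
    d = grid.distance(grid.x, pitch_st / ST_PER_OCT)
    return np.exp(-(np.asarray(d) ** 2) / sigma_in**2)


@dataclass
class DriveEvent:
    """One gated drive epoch: spatial profiles (B, n) and a time window."""

    profiles: np.ndarray  # (B, n)
    t1: float
    t2: float


class InputDrive:
    """The afferent drive field Input(x, t) for a batch of trials.

    All trials in a batch share event timing; only the spatial profiles
    differ per trial.  ``evaluate(t)`` returns the (B, n) field; Input is 0
    outside all tone windows and bounded by the number of simultaneously
    overlapping spectral components.
    """

    def __init__(self, grid: TonotopicGrid, events: list[DriveEvent], tau_r: float = DEFAULT_TAU_R):
        if tau_r <= 0:
            raise ValueError("tau_r must be positive")
        b = {e.profiles.shape[0] for e in events} or {1}
        if len(b) != 1:
            raise ValueError("all drive events must share the batch size")
        self.grid = grid
        self.events = list(events)
        self.tau_r = float(tau_r)
        self.batch = b.pop()

    @property
    def t_end(self) -> float:
        return max((e.t2 for e in self.events), default=0.0)

    @property
    def breakpoints(self) -> list[float]:
        out: set[float] = set()
        for e in self.events:
            out.update((e.t1, e.t2))
        return sorted(out)

    def evaluate(self, t: float) -> np.ndarray:
        """Input(x, t) on the grid, shape (B, n)."""
        out = np.zeros((self.batch, self.grid.n))
        for e in self.events:
            if e.t1 < t < e.t2:
                gain = ramp(t - e.t1, self.tau_r) * ramp(e.t2 - t, self.tau_r)
                if gain > 0.0:
                    out += gain * e.profiles
        return out

    def sample(self, times: np.ndarray) -> np.ndarray:
        """Dense field sampled at given times, shape (n_t, B, n)."""
        return np.stack([self.evaluate(float(t)) for t in np.asarray(times)])

    @classmethod
    def from_sequence(
        cls,
        seq: ToneSequence,
        grid: TonotopicGrid,
        sigma_in: float = DEFAULT_SIGMA_IN,
        tau_r: float = DEFAULT_TAU_R,
    ) -> "InputDrive":
        return cls.from_sequences([seq], grid, sigma_in=sigma_in, tau_r=tau_r)

    @classmethod
    def from_sequences(
        cls,
        seqs: list[ToneSequence],
        grid: TonotopicGrid,
        sigma_in: float = DEFAULT_SIGMA_IN,
        tau_r: float = DEFAULT_TAU_R,
    ) -> "InputDrive":
        """Batch drive from sequences with identical event timing."""
        if not seqs:
            raise ValueError("need at least one sequence")
        ref = [(e.onset_ms, e.duration_ms) for e in seqs[0].events]
        for s in seqs[1:]:
            if [(e.onset_ms, e.duration_ms) for e in s.events] != ref:
                raise ValueError("batched sequences must share event timing")
        events = []
        for k, (onset, dur) in enumerate(ref):
            profiles = np.stack(
                [gaussian_profile(grid, s.events[k].pitch_st, sigma_in) for s in seqs]
            )
            events.append(DriveEvent(profiles, onset, onset + dur))
        return cls(grid, events, tau_r=tau_r)


def make_shepard_drive(
    tone: ToneEvent,
    grid: TonotopicGrid,
    sigma_in: float = DEFAULT_SIGMA_IN,
    tau_r: float = DEFAULT_TAU_R,
) -> InputDrive:
    """Drive field of a single Shepard tone."""
    profile = gaussian_profile(grid, tone.pitch_st, sigma_in)[None, :]
    return InputDrive(grid, [DriveEvent(profile, tone.onset_ms, tone.offset_ms)], tau_r=tau_r)


def make_tritone_trial(
    t1_pc: float,
    n_bias: int,
    direction: str = "up",
    timing: TrialTiming = TrialTiming(),
    rng: np.random.Generator | int | None = None,
    discrete_st: float | None = None,
    pre_tone: bool = False,
) -> ToneSequence:
    """Bias sequence followed by the ambiguous tritone pair T1, T2 = T1 + 6 st.

    Up-bias pitches are uniform in the open interval (T1, T1+6) st; Down-bias
    in (T1-6, T1), wrapped to [0, 12).  ``discrete_st`` optionally snaps bias
    pitches to a semitone sub-grid.  ``pre_tone`` prepends one random-pitch
    Shepard tone (used for randomized initial conditions), placed like a bias
    tone before everything else.
    """
    if n_bias < 0:
        raise ValueError("n_bias must be >= 0")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seed = None

    def draw_bias() -> float:
        while True:
            u = rng.uniform(0.0, 6.0)
            if discrete_st is not None:
                u = np.round(u / discrete_st) * discrete_st
            if 0.0 < u < 6.0:
                break
        return pitch_class(t1_pc + u) if direction == "up" else pitch_class(t1_pc - u)

    events: list[ToneEvent] = []
    t = 0.0
    if pre_tone:
        events.append(ToneEvent(rng.uniform(0.0, 12.0), t, timing.dur, role="pre"))
        t += timing.dur + timing.iti
    for _ in range(n_bias):
        events.append(ToneEvent(draw_bias(), t, timing.dur, role="bias"))
        t += timing.dur + timing.iti
    if events:
        t = events[-1].offset_ms + timing.gap
    events.append(ToneEvent(pitch_class(t1_pc), t, timing.dur, role="T1"))
    t += timing.dur + timing.iti
    events.append(ToneEvent(pitch_class(t1_pc + 6.0), t, timing.dur, role="T2"))
    return ToneSequence(tuple(events), n_bias=n_bias, direction=direction, seed=seed)


def mirror_sequence(seq: ToneSequence, axis_st: float = 0.0) -> ToneSequence:
    """Reflect every pitch about an axis on the pitch-class circle.

    Reflection about T1 maps an Up-bias trial onto the matched Down-bias
    trial (T2 is its own image since -6 = +6 mod 12); by the model's
    up/down symmetry the decision variable flips sign.
    """
    direction = {"up": "down", "down": "up"}.get(seq.direction, seq.direction)
    events = tuple(
        replace(e, pitch_st=pitch_class(2.0 * axis_st - e.pitch_st)) for e in seq.events
    )
    return ToneSequence(events, n_bias=seq.n_bias, direction=direction, seed=seq.seed)


def line_grid_for_chord(
    n_components: int,
    spacing: float,
    margin: float = 1.0,
    dx: float = 0.01,
) -> TonotopicGrid:
    """Line grid wide enough for a chord plus a boundary margin (octaves).

    The margin defaults to 1.0 oct (> 3 sigma_ie for the default 0.3-oct
    inhibitory footprint) so absorbing edges do not touch the stimulus.
    The lowest chord component sits at x = margin.
    """
    span = (n_components - 1) * spacing + 2.0 * margin
    return TonotopicGrid.line(span_oct=span, dx=dx, x0=0.0)


def make_chord_drive(
    n_components: int,
    spacing: float,
    test_shift: float,
    test_component_index: int,
    grid: TonotopicGrid,
    timing: TrialTiming = TrialTiming(),
    sigma_in: float = DEFAULT_SIGMA_IN,
    base_oct: float | None = None,
) -> InputDrive:
    """Chord of equally spaced pure tones followed by a shifted test tone.

    The chord has ``n_components`` synchronous Gaussian profiles spaced by
    ``spacing`` octaves (component drives sum linearly).  The test tone sits
    at component ``test_component_index`` (0-based, from the lowest) plus
    ``test_shift`` octaves.  Requires a line grid with >= 3 sigma_ie margin.
    """
    if grid.topology != "line":
        raise ValueError("chord stimuli require a line grid")
    if not 0 <= test_component_index < n_components:
        raise ValueError("test_component_index out of range")
    if base_oct is None:
        center = (grid.x[0] + grid.x[-1]) / 2.0
        base_oct = center - (n_components - 1) * spacing / 2.0
    positions = base_oct + spacing * np.arange(n_components)
    test_pos = positions[test_component_index] + test_shift
    for p in list(positions) + [test_pos]:
        if not grid.contains(p):
            raise ValueError(f"chord component at {p:.3f} oct outside grid")
    chord = np.sum(
        [gaussian_profile(grid, p * ST_PER_OCT, sigma_in) for p in positions], axis=0
    )[None, :]
    test = gaussian_profile(grid, test_pos * ST_PER_OCT, sigma_in)[None, :]
    t1 = 0.0
    events = [
        DriveEvent(chord, t1, t1 + timing.dur),
        DriveEvent(test, t1 + timing.dur + timing.iti, t1 + 2 * timing.dur + timing.iti),
    ]
    return InputDrive(grid, events, tau_r=timing.tau_r)


def render_wav(
    seq: ToneSequence,
    path,
    sample_rate: int = 44100,
    component_range_octaves: int = 5,
    reference_hz: float = 32.70,
    tau_r: float = DEFAULT_TAU_R,
    peak: float = 0.9,
) -> None:
    """Render a tone sequence as 16-bit PCM WAV audio.

    Each Shepard tone is synthesized as equal-amplitude octave-spaced
    sinusoids (flat spectral envelope) spanning ``component_range_octaves``
    octaves above ``reference_hz`` (default C1), gated by the same
    raised-cosine ramps as the model drive, peak-normalized to avoid
    clipping.  Audio is a demonstration artifact only — the model consumes
    the idealized drive field, not sound.
    """
    n_samples = int(np.ceil(seq.t_end / 1000.0 * sample_rate)) if seq.events else 0
    n_samples = max(n_samples, 1)
    signal = np.zeros(n_samples)
    t_all = np.arange(n_samples) / sample_rate * 1000.0  # ms
    for ev in seq.events:
        sel = (t_all > ev.onset_ms) & (t_all < ev.offset_ms)
        if not np.any(sel):
            continue
        t = t_all[sel]
        env = ramp(t - ev.onset_ms, tau_r) * ramp(ev.offset_ms - t, tau_r)
        pc = pitch_class(ev.pitch_st)
        tone = np.zeros_like(t)
        for k in range(component_range_octaves):
            f = reference_hz * 2.0 ** (k + pc / ST_PER_OCT)
            if f < sample_rate / 2.0:
                tone += np.sin(2.0 * np.pi * f * t / 1000.0)
        signal[sel] += env * tone
    m = np.max(np.abs(signal))
    if m > 0:
        signal = signal * (peak / m)
    pcm = np.clip(np.round(signal * 32767.0), -32768, 32767).astype("<i2")
    with _wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(2)
        w.setframerate(sample_rate)
        w.writeframes(pcm.tobytes())
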