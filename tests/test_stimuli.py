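"""Stimulus construction: ramps, drive profiles, paradigms, chords, audio."""

import wave

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shepnet.grids import TonotopicGrid
from shepnet.stimuli import (
    InputDrive,
    ToneEvent,
    ToneSequence,
    TrialTiming,
    circ_dist_st,
    gaussian_profile,
    line_grid_for_chord,
    make_chord_drive,
    make_shepard_drive,
    make_tritone_trial,
    mirror_sequence,
    pitch_class,
    ramp,
    render_wav,
)


class TestRamp:
    @pytest.mark.parametrize(
        "t_rel,expected",
        [(10.0, 1.0), (5.0, 1.0), (0.0, 0.0), (-3.0, 0.0), (2.5, 0.25)],
    )
    def test_values(self, t_rel, expected):
        # midpoint of the raised-cosine-squared form: ((1 - cos(pi/2))/2)^2 = 1/4
        assert ramp(t_rel, 5.0) == pytest.approx(expected, abs=1e-12)

    def test_monotone_and_bounded(self):
        t = np.linspace(-2.0, 8.0, 400)
        v = ramp(t, 5.0)
        assert np.all(np.diff(v) >= -1e-15)
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            ramp(1.0, 0.0)


class TestShepardDrive:
    def test_peak_and_width(self, ring):
        # pitch 3 st = 0.25 oct lies on the grid; +/- sigma_in falls e^-1 down
        drive = make_shepard_drive(ToneEvent(3.0, 0.0, 100.0), ring, sigma_in=0.1)
        mid = drive.evaluate(50.0)[0]
        i0 = ring.index_near(3.0)
        assert mid[i0] == pytest.approx(1.0)
        for di in (-10, 10):  # 0.1 oct = 10 grid points
            assert mid[i0 + di] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_ring_wrap(self, ring):
        profile = gaussian_profile(ring, 11.9)
        # mass wraps across 12 -> 0: the point at 0 st is ~0.1 oct... 0.0083 oct away
        assert profile[ring.index_near(0.0)] > profile[ring.index_near(6.0)]
        assert profile[ring.index_near(0.5)] > 0.5

    def test_circular_shift_equivariance(self, ring):
        # 3 st = 25 grid points: profiles are exact circular shifts
        p0 = gaussian_profile(ring, 1.0)
        p1 = gaussian_profile(ring, 4.0)
        assert np.allclose(np.roll(p0, 25), p1, atol=1e-15)

    def test_zero_outside_windows(self, ring):
        drive = make_shepard_drive(ToneEvent(3.0, 10.0, 100.0), ring)
        for t in (0.0, 10.0, 110.0, 500.0):
            assert np.all(drive.evaluate(t) == 0.0)
        assert drive.evaluate(60.0).max() <= 1.0


class TestTritoneParadigm:
    def test_no_bias_is_bare_pair(self):
        seq = make_tritone_trial(4.0, 0, "up", rng=0)
        assert [e.role for e in seq.events] == ["T1", "T2"]
        assert seq.events[0].pitch_st == 4.0
        assert seq.events[1].pitch_st == 10.0
        assert seq.events[1].onset_ms - seq.events[0].offset_ms == 50.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n_bias=st.integers(0, 12),
        t1=st.floats(0.0, 12.0, exclude_max=True),
        direction=st.sampled_from(["up", "down"]),
    )
    def test_bias_pitches_strictly_inside_half_octave(self, seed, n_bias, t1, direction):
        seq = make_tritone_trial(t1, n_bias, direction, rng=seed)
        sign = 1.0 if direction == "up" else -1.0
        for e in seq.by_role("bias"):
            offset = sign * circ_dist_st(e.pitch_st, t1)
            assert 0.0 < offset < 6.0
        # gap between last bias tone and T1 equals the configured 500 ms
        if n_bias:
            last_bias = seq.by_role("bias")[-1]
            assert seq.window("T1")[0] - last_bias.offset_ms == pytest.approx(500.0)

    def test_deterministic_given_seed(self):
        a = make_tritone_trial(4.0, 10, "up", rng=123)
        b = make_tritone_trial(4.0, 10, "up", rng=123)
        assert a == b

    def test_invalid_direction(self):
        with pytest.raises(ValueError):
            make_tritone_trial(0.0, 1, "sideways")

    def test_mirror_sequence_reflects_pitches_and_swaps_direction(self):
        seq = make_tritone_trial(0.0, 5, "up", rng=7)
        mir = mirror_sequence(seq, axis_st=0.0)
        assert mir.direction == "down"
        for e, m in zip(seq.events, mir.events):
            assert m.pitch_st == pytest.approx(pitch_class(-e.pitch_st))
            assert m.onset_ms == e.onset_ms

    def test_manifest_roundtrip(self, tmp_path):
        seq = make_tritone_trial(2.0, 3, "down", rng=5)
        path = tmp_path / "manifest.csv"
        seq.to_csv(path)
        df = pd.read_csv(path)
        assert list(df["role"]) == ["bias"] * 3 + ["T1", "T2"]
        assert np.allclose(df["pitch_st"], [e.pitch_st for e in seq.events])

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError):
            ToneSequence((ToneEvent(0.0, 0.0, 100.0), ToneEvent(1.0, 50.0, 100.0)))


class TestChord:
    def test_layout(self):
        grid = line_grid_for_chord(6, 0.5)
        drive = make_chord_drive(6, 0.5, 0.1, 2, grid)
        chord, test = drive.events
        # six components summed: six local maxima of unit height
        prof = chord.profiles[0]
        peaks = [grid.x[i] for i in range(1, grid.n - 1)
                 if prof[i] > prof[i - 1] and prof[i] > prof[i + 1] and prof[i] > 0.5]
        assert len(peaks) == 6
        assert np.allclose(np.diff(peaks), 0.5, atol=0.02)
        # test tone centered 0.1 oct above the third-lowest component
        i_test = int(np.argmax(test.profiles[0]))
        assert grid.x[i_test] == pytest.approx(peaks[2] + 0.1, abs=0.01)
        assert prof.max() <= 6.0

    def test_zero_shift_matches_component(self):
        grid = line_grid_for_chord(3, 0.5)
        drive = make_chord_drive(3, 0.5, 0.0, 1, grid)
        single = gaussian_profile(grid, (1.0 + 0.5) * 12.0)
        assert np.allclose(drive.events[1].profiles[0], single, atol=1e-12)

    def test_single_component_reduces_to_pair(self):
        grid = line_grid_for_chord(1, 0.5)
        drive = make_chord_drive(1, 0.5, 0.1, 0, grid)
        assert drive.events[0].profiles[0].max() == pytest.approx(1.0)

    def test_out_of_grid_rejected(self):
        grid = TonotopicGrid.line(span_oct=1.0)
        with pytest.raises(ValueError):
            make_chord_drive(6, 0.5, 0.1, 2, grid)

    def test_ring_grid_rejected(self, ring):
        with pytest.raises(ValueError):
            make_chord_drive(6, 0.5, 0.1, 2, ring)


class TestAudio:
    def test_wav_length_and_format(self, tmp_path):
        seq = ToneSequence((ToneEvent(3.0, 0.0, 100.0),))
        path = tmp_path / "tone.wav"
        render_wav(seq, path, sample_rate=44100)
        with wave.open(str(path)) as w:
            assert w.getframerate() == 44100
            assert w.getnframes() >= 4410
            assert w.getsampwidth() == 2

    def test_octave_equivalence(self, tmp_path):
        # same pitch class an octave apart -> identical Shepard waveforms
        a, b = tmp_path / "a.wav", tmp_path / "b.wav"
        render_wav(ToneSequence((ToneEvent(3.0, 0.0, 80.0),)), a)
        render_wav(ToneSequence((ToneEvent(15.0, 0.0, 80.0),)), b)
        assert a.read_bytes() == b.read_bytes()

    def test_batched_drive_requires_common_timing(self, ring):
        s1 = make_tritone_trial(0.0, 0, "up")
        s2 = ToneSequence((ToneEvent(0.0, 0.0, 100.0),))
        with pytest.raises(ValueError):
            InputDrive.from_sequences([s1, s2], ring)
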