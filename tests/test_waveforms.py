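import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motiontol.waveforms import (
    BreathingModelParams,
    MotionWaveform,
    concatenate_segments,
    cycle_to_waveform,
    read_waveform_csv,
    resample_to_control_points,
    scale_amplitude,
    surrogate_rescale,
    synthesize_breathing,
    write_waveform_csv,
)


def si_wave(values, dt=0.5, source="SYNTHETIC"):
    v = np.asarray(values, dtype=float)
    return MotionWaveform(np.column_stack([v, np.zeros_like(v), np.zeros_like(v)]), dt=dt, source=source)


@st.composite
def waveforms(draw):
    n = draw(st.integers(min_value=4, max_value=60))
    vals = draw(
        st.lists(
            st.floats(min_value=-15, max_value=15, allow_nan=False),
            min_size=n, max_size=n,
        )
    )
    return si_wave(vals)


class TestMotionWaveform:
    def test_native_range_is_si_peak_to_peak(self):
        w = si_wave([0.0, -3.5, 1.5, 0.2])
        assert w.native_range_si == pytest.approx(5.0)

    @pytest.mark.parametrize(
        "samples,err",
        [
            (np.array([[0.0, 0, 0]]), "at least 2"),
            (np.full((5, 3), np.nan), "finite"),
            (np.zeros((3, 2)), "shape"),
        ],
    )
    def test_validation(self, samples, err):
        with pytest.raises(ValueError, match=err):
            MotionWaveform(samples, dt=0.5)


class TestCycleToWaveform:
    def test_ten_phase_cycle_replicated(self):
        # SI COM tracing +-4.25 mm about its mean, three replicates
        si = 4.25 * np.cos(2 * np.pi * np.arange(10) / 10)
        coms = np.column_stack([100.0 + si, np.zeros(10), np.zeros(10)])
        w = cycle_to_waveform(coms, n_repeats=3)
        assert len(w) == 30
        assert w.native_range_si == pytest.approx(8.5)
        np.testing.assert_allclose(w.samples[:10], w.samples[10:20])  # periodic

    def test_identical_phases_give_zero_motion(self):
        coms = np.tile([5.0, 1.0, -2.0], (10, 1))
        w = cycle_to_waveform(coms, n_repeats=5)
        assert len(w) == 50
        np.testing.assert_array_equal(w.samples, 0.0)
        assert w.native_range_si == 0.0

    def test_cos2_template_range_matches_extrema_scan(self):
        t = np.arange(10) / 10
        si = 6.0 * np.cos(np.pi * t) ** 2
        coms = np.column_stack([si, np.zeros(10), np.zeros(10)])
        w = cycle_to_waveform(coms, n_repeats=2)
        # independent brute-force extrema scan of the template
        expected = max(si) - min(si)
        assert w.native_range_si == pytest.approx(expected)

    def test_fewer_than_two_phases_rejected(self):
        with pytest.raises(ValueError, match="2 phases"):
            cycle_to_waveform(np.array([[1.0, 0, 0]]), n_repeats=1)


class TestConcatenate:
    def test_three_forty_second_scans(self):
        segs = [si_wave(np.sin(np.arange(80)), dt=0.5) for _ in range(3)]
        w = concatenate_segments(segs)
        assert len(w) == 240
        assert w.duration_s == pytest.approx(120.0)

    def test_single_segment_identity(self):
        w = si_wave([1.0, -1.0, 0.5])
        out = concatenate_segments([w])
        np.testing.assert_array_equal(out.samples, w.samples)

    def test_combined_range_is_global_extrema(self):
        segs = [si_wave([0, 4.0]), si_wave([0, 6.0]), si_wave([0, 5.0])]
        w = concatenate_segments(segs)
        allvals = np.concatenate([s.si for s in segs])
        assert w.native_range_si == pytest.approx(allvals.max() - allvals.min())
        assert w.native_range_si >= max(s.native_range_si for s in segs)

    def test_mismatched_dt_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            concatenate_segments([si_wave([0, 1], dt=0.5), si_wave([0, 1], dt=0.4)])


class TestScaleAmplitude:
    def test_adds_extra_range(self):
        si = 4.25 * np.cos(2 * np.pi * np.arange(20) / 10)
        w = si_wave(si)
        out = scale_amplitude(w, 5.0)
        assert out.peak_to_peak_si() == pytest.approx(13.5, abs=1e-9)

    def test_zero_extra_is_identity(self):
        w = si_wave([1.0, -2.0, 0.3])
        out = scale_amplitude(w, 0.0)
        np.testing.assert_array_equal(out.samples, w.samples)

    def test_sine_doubles_when_extra_equals_range(self):
        # symmetric sampling: full periods without the duplicated endpoint
        si = 5.0 * np.sin(np.linspace(0, 4 * np.pi, 40, endpoint=False))
        w = si_wave(si)
        out = scale_amplitude(w, 10.0, anchor="MIDRANGE")
        # closed form: (R + extra) / R = 2, midrange anchor = 0 for a sine
        np.testing.assert_allclose(out.si, 2.0 * si, atol=1e-12)

    def test_exhale_anchor_keeps_exhale_extreme(self):
        w = si_wave([3.0, -1.0, 2.0, -3.0])
        out = scale_amplitude(w, 4.0, anchor="EXHALE_EXTREME")
        assert out.si.max() == pytest.approx(3.0)  # exhale plateau fixed
        assert out.peak_to_peak_si() == pytest.approx(10.0)

    def test_zero_range_falls_back_to_template(self):
        w = si_wave(np.zeros(20))
        with pytest.warns(UserWarning, match="cos"):
            out = scale_amplitude(w, 10.0)
        assert out.peak_to_peak_si() == pytest.approx(10.0, abs=1e-12)
        assert len(out) == 20

    @given(w=waveforms(), extra=st.floats(min_value=0, max_value=30, allow_nan=False))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_property_range_and_shape_preserved(self, w, extra):
        r = w.peak_to_peak_si()
        if r <= 1e-6:
            return
        out = scale_amplitude(w, extra)
        assert out.peak_to_peak_si() == pytest.approx(r + extra, abs=1e-9)
        if np.std(w.si) > 1e-9 and extra > 0:
            corr = np.corrcoef(w.si, out.si)[0, 1]
            assert corr == pytest.approx(1.0, abs=1e-9)


class TestSurrogateRescale:
    def test_diaphragm_scaled_to_tumor_range(self):
        w = si_wave(20.0 * np.sin(np.linspace(0, 6, 40)) / 2)
        w = si_wave(w.si - w.si.min())  # range 20 exactly? normalise explicitly
        w = si_wave(20.0 * (w.si - w.si.min()) / (w.si.max() - w.si.min()))
        out = surrogate_rescale(w, 10.7)
        assert out.peak_to_peak_si() == pytest.approx(10.7, abs=1e-9)
        assert np.corrcoef(w.si, out.si)[0, 1] == pytest.approx(1.0)

    def test_identity_and_zero_target(self):
        w = si_wave([0.0, 4.0, 1.0])
        np.testing.assert_allclose(surrogate_rescale(w, 4.0).samples, w.samples)
        np.testing.assert_array_equal(surrogate_rescale(w, 0.0).samples, 0.0)

    def test_zero_surrogate_range_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            surrogate_rescale(si_wave([1.0, 1.0, 1.0]), 5.0)


class TestSynthesizeBreathing:
    def test_noise_free_range_equals_amplitude(self):
        p = BreathingModelParams(period_s=4, amplitude_mm=8.5, duration_s=40, sample_hz=2)
        w = synthesize_breathing(p)
        assert len(w) == 80
        assert w.peak_to_peak_si() == pytest.approx(8.5, abs=1e-9)

    def test_same_seed_is_deterministic(self):
        p = BreathingModelParams(jitter_sd=0.15, noise_sd_mm=0.3, seed=42)
        np.testing.assert_array_equal(
            synthesize_breathing(p).samples, synthesize_breathing(p).samples
        )

    def test_drift_range_matches_formula_evaluation(self):
        p = BreathingModelParams(
            period_s=4, amplitude_mm=5.0, drift_mm_per_min=2.0, duration_s=120, sample_hz=2
        )
        w = synthesize_breathing(p)
        # independent evaluation of the generating formula
        t = np.arange(240) / 2.0
        si = 2.0 * t / 60.0 - 5.0 * np.cos(np.pi * t / 4.0) ** 4
        assert w.peak_to_peak_si() == pytest.approx(si.max() - si.min(), abs=1e-9)


class TestResample:
    def test_length_and_coverage(self):
        w = si_wave(np.sin(np.arange(240)), dt=0.5)
        out = resample_to_control_points(w, 180, 0.33)
        assert out.shape == (180, 3)

    @pytest.mark.parametrize("n_cp,sec", [(1, 0.1), (37, 0.73), (500, 2.0)])
    def test_constant_waveform_stays_constant(self, n_cp, sec):
        w = si_wave(np.full(30, 2.5), dt=0.5)
        out = resample_to_control_points(w, n_cp, sec)
        np.testing.assert_allclose(out[:, 0], 2.5, atol=1e-12)

    def test_matching_rate_picks_samples_directly(self):
        si = np.sin(2 * np.pi * 0.25 * np.arange(40) * 0.5)
        w = si_wave(si, dt=0.5)
        out = resample_to_control_points(w, 40, 0.5)
        np.testing.assert_allclose(out[:, 0], si, atol=1e-12)

    def test_wraps_cyclically(self):
        w = si_wave([0.0, 1.0, 2.0, 3.0], dt=1.0)
        out = resample_to_control_points(w, 8, 1.0)
        np.testing.assert_allclose(out[4:, 0], out[:4, 0], atol=1e-12)


class TestWaveformCsv:
    def test_round_trip_bit_stable(self, tmp_path):
        w = si_wave(np.sin(np.arange(50)) * 7.123456, dt=0.5)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_waveform_csv(w, p1)
        w2 = read_waveform_csv(p1)
        write_waveform_csv(w2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        np.testing.assert_allclose(w2.samples, w.samples, atol=1e-6)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t_s,dx_mm\n0,1\n0.5,2\n")
        with pytest.raises(ValueError, match="dy_mm"):
            read_waveform_csv(p)
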