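import numpy as np
import pytest

from gazerec import (
    Apparatus,
    DetectorParams,
    GazeSequence,
    SimConfig,
    detect_events,
    duration_stats,
    fraction_in_bounds,
    main_sequence,
    make_image_models,
    simulate_encoding_trial,
    spatial_coverage,
)
from gazerec.events import EventSet, FixationEvent
from gazerec.io import px_to_deg


def _seq_from_xy(x, y, valid=None, t0=0, **kw):
    n = len(x)
    valid = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    return GazeSequence("s0", "i0", "encoding", np.arange(n) + t0,
                        np.asarray(x, float), np.asarray(y, float), valid, **kw)


def _ramp_signal(apparatus, deg_per_s, ramp_ms=40, hold_ms=400):
    """Two fixations joined by a constant-velocity horizontal ramp."""
    dx, _ = px_to_deg(apparatus)
    step_px = deg_per_s / 1000.0 / dx  # px per ms
    x = np.concatenate([
        np.full(hold_ms, 200.0),
        200.0 + step_px * np.arange(1, ramp_ms + 1),
        np.full(hold_ms, 200.0 + step_px * ramp_ms),
    ])
    return _seq_from_xy(x, np.full(len(x), 600.0))


class TestDetector:
    def test_constant_position_single_fixation(self):
        seq = _seq_from_xy(np.full(1000, 500.0), np.full(1000, 500.0))
        es = detect_events(seq)
        assert len(es.fixations) == 1
        assert len(es.saccades) == 0
        assert es.fixations[0].duration_ms == 999
        assert es.fixations[0].x_px == pytest.approx(500.0)

    def test_fast_ramp_detected_as_one_saccade(self, apparatus):
        seq = _ramp_signal(apparatus, 250.0, ramp_ms=40)
        es = detect_events(seq, apparatus=apparatus)
        assert len(es.fixations) == 2
        assert len(es.saccades) == 1
        assert es.saccades[0].amplitude_deg == pytest.approx(10.0, rel=0.05)

    def test_sub_threshold_ramp_is_not_a_saccade(self, apparatus):
        # 29 deg/s sits just below the 30 deg/s velocity threshold
        seq = _ramp_signal(apparatus, 29.0, ramp_ms=100)
        es = detect_events(seq, apparatus=apparatus)
        assert len(es.saccades) == 0

    def test_all_invalid_sequence_flagged(self):
        seq = _seq_from_xy(np.full(100, np.nan), np.full(100, np.nan),
                           valid=np.zeros(100))
        es = detect_events(seq)
        assert es.warning is not None
        assert not es.fixations and not es.saccades

    def test_blink_splits_fixation(self):
        x = np.full(1200, 400.0)
        valid = np.ones(1200, dtype=bool)
        valid[550:650] = False
        x = x.copy()
        x[~valid] = np.nan
        es = detect_events(_seq_from_xy(x, x, valid=valid))
        assert len(es.fixations) == 2
        assert len(es.blink_windows) == 1

    def test_time_shift_invariance(self, apparatus):
        seq0 = _ramp_signal(apparatus, 250.0)
        seq1 = GazeSequence("s0", "i0", "encoding", seq0.t_ms + 1234, seq0.x_px,
                            seq0.y_px, seq0.valid)
        e0 = detect_events(seq0, apparatus=apparatus)
        e1 = detect_events(seq1, apparatus=apparatus)
        assert [f.duration_ms for f in e0.fixations] == [f.duration_ms for f in e1.fixations]
        assert [f.onset_ms + 1234 for f in e0.fixations] == [f.onset_ms for f in e1.fixations]

    def test_noise_free_parameter_recovery(self):
        # planted fixation count recovered exactly on tremor- and blink-free trials
        cfg = SimConfig(tremor_sd_deg=0.0, blink_rate_per_trial=0.0)
        models = make_image_models(10, seed=2)
        ok = 0
        n = 100
        for i in range(n):
            seq, truth = simulate_encoding_trial(models[i % 10], cfg, 900 + i)
            ok += len(detect_events(seq).fixations) == truth.n_fixations
        assert ok >= 0.99 * n


class TestMainSequence:
    def test_empty_without_saccades(self):
        assert main_sequence([EventSet("s", "i", "encoding")]).empty

    def test_simulated_saccade_follows_main_sequence_law(self, apparatus):
        # one planted 10-degree saccade: peak velocity ~ 500 (1 - e^{-10/8})
        dx, _ = px_to_deg(apparatus)
        cfg = SimConfig(tremor_sd_deg=0.0, blink_rate_per_trial=0.0,
                        enc_fix_count=(2, 0))
        found = []
        models = make_image_models(30, seed=8)
        for i in range(30):
            seq, truth = simulate_encoding_trial(models[i], cfg, i)
            amp_px = np.linalg.norm(truth.fix_xy[1] - truth.fix_xy[0])
            if abs(amp_px * dx - 10.0) > 1.0:
                continue
            ms = main_sequence([detect_events(seq, apparatus=apparatus)])
            assert len(ms) == 1
            expected = 500.0 * (1 - np.exp(-ms["amplitude_deg"].iloc[0] / 8.0))
            found.append((ms["peak_velocity_deg_s"].iloc[0], expected))
        assert found, "no ~10 degree saccades sampled"
        for got, expected in found:
            assert got == pytest.approx(expected, rel=0.05)

    def test_peak_velocity_monotone_in_amplitude(self, small_study):
        _, trials, _ = small_study
        ms = main_sequence([detect_events(s) for s in trials.select("encoding")])
        big = ms[ms.amplitude_deg > 2.0].sort_values("amplitude_deg")
        # binned medians must be non-decreasing under the saturating law
        med = big.groupby(np.digitize(big.amplitude_deg, [2, 5, 10, 20]))[
            "peak_velocity_deg_s"].median()
        assert med.is_monotonic_increasing


class TestSpatialMeasures:
    @staticmethod
    def _events(points):
        return EventSet("s", "i", "encoding",
                        fixations=[FixationEvent(i * 100, i * 100 + 50, x, y)
                                   for i, (x, y) in enumerate(points)])

    def test_single_fixation_zero_coverage(self):
        assert spatial_coverage(self._events([(5, 5)])) == 0.0

    def test_corner_fixations_full_coverage(self):
        es = self._events([(0, 0), (1920, 0), (0, 1200), (1920, 1200)])
        assert spatial_coverage(es) == pytest.approx(100.0)

    def test_quarter_screen_box(self):
        es = self._events([(0, 0), (960, 600)])
        assert spatial_coverage(es) == pytest.approx(25.0)

    def test_fraction_in_bounds_counting(self):
        es = self._events([(10, 10), (20, 20), (30, 30), (500, 500)])
        assert fraction_in_bounds(es, (0, 0, 100, 100)) == pytest.approx(0.75)

    def test_zero_fixations_signalled(self):
        with pytest.raises(ValueError):
            spatial_coverage(EventSet("s", "i", "encoding"))


class TestDurationStats:
    @staticmethod
    def _sets(enc_durs, rec_durs):
        out = []
        for phase, durs in (("encoding", enc_durs), ("recall", rec_durs)):
            out.append(EventSet("s", "i", phase, fixations=[
                FixationEvent(0, int(d), 0.0, 0.0) for d in durs
            ]))
        return out

    def test_identical_samples_give_t0_p1(self):
        st = duration_stats(self._sets([100, 200, 300], [100, 200, 300]))
        assert st["duration_welch"]["t"] == pytest.approx(0.0)
        assert st["duration_welch"]["p"] == pytest.approx(1.0)

    def test_welch_t_hand_computed(self):
        # {1,2,3} vs {2,3,4}: t = -1 / sqrt(2/3) = -1.2247
        st = duration_stats(self._sets([1, 2, 3], [2, 3, 4]))
        assert st["duration_welch"]["t"] == pytest.approx(-1.2247, abs=1e-4)

    def test_recall_fixations_longer_on_simulated_data(self, small_study):
        _, trials, _ = small_study
        events = [detect_events(s) for s in trials]
        st = duration_stats(events)
        enc, rec = st["per_phase"]["encoding"], st["per_phase"]["recall"]
        assert rec["fix_dur_mean_ms"] > enc["fix_dur_mean_ms"]
        assert enc["fix_count_mean"] > rec["fix_count_mean"]
        assert st["duration_welch"]["p"] < 0.001
        assert st["duration_mannwhitney"]["p"] < 0.001
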