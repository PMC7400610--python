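import numpy as np
import pytest

from gazerec import (
    Apparatus,
    SimConfig,
    make_image_models,
    simulate_encoding_trial,
    simulate_recall_trial,
    simulate_study,
)
from gazerec.simulate import SimulationError


@pytest.fixture(scope="module")
def models():
    return make_image_models(5, seed=3)


class TestImageModels:
    def test_count_and_determinism(self):
        a = make_image_models(4, seed=9)
        b = make_image_models(4, seed=9)
        assert len(a) == len(make_image_models(1, seed=0)) * 4
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.means, mb.means)
            np.testing.assert_array_equal(ma.weights, mb.weights)

    def test_clone_pairs_are_near_duplicates(self):
        ms = make_image_models(20, seed=1, n_clone_pairs=5, clone_shift_px=10.0)
        assert len(ms) == 20
        n_close = 0
        for j in range(5):
            src, clone = ms[j], ms[15 + j]
            d = np.linalg.norm(src.means - clone.means, axis=1).mean()
            n_close += d < 50.0
        assert n_close == 5

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            make_image_models(0)


class TestEncodingTrial:
    def test_degenerate_two_fixation_config(self, models):
        cfg = SimConfig(enc_fix_count=(2, 0), tremor_sd_deg=0.0, blink_rate_per_trial=0.0)
        seq, truth = simulate_encoding_trial(models[0], cfg, 5)
        assert truth.n_fixations == 2
        assert len(truth.blink_windows) == 0
        assert seq.valid.all()

    def test_sample_count_bookkeeping(self, models):
        # total samples = trial_ms * rate / 1000; invalid ones are the blink union
        cfg = SimConfig(blink_rate_per_trial=2.0)
        seq, truth = simulate_encoding_trial(models[1], cfg, 7)
        assert len(seq) == cfg.trial_ms
        covered = np.zeros(cfg.trial_ms, dtype=bool)
        for b0, b1 in truth.blink_windows:
            covered[int(np.ceil(b0)): int(np.ceil(b1))] = True
        assert int((~seq.valid).sum()) == int(covered.sum())

    def test_mean_fixation_count_matches_encoding_law(self, models):
        cfg = SimConfig()
        counts = [
            simulate_encoding_trial(models[i % len(models)], cfg, 1000 + i)[1].n_fixations
            for i in range(300)
        ]
        assert np.mean(counts) == pytest.approx(16.0, abs=0.5)

    def test_infeasible_budget_raises(self, models):
        cfg = SimConfig(enc_fix_count=(200, 0))
        with pytest.raises(SimulationError):
            simulate_encoding_trial(models[0], cfg, 1)

    def test_valid_samples_inside_screen(self, models):
        seq, _ = simulate_encoding_trial(models[2], SimConfig(), 3)
        x, y = seq.valid_xy()
        assert (x >= 0).all() and (x <= 1919).all()
        assert (y >= 0).all() and (y <= 1199).all()


class TestRecallTrial:
    @staticmethod
    def _identity_cfg(**kw):
        kw.setdefault("rec_fix_count", (16.0, 2.8))
        return SimConfig(
            shrink_range=(1.0, 1.0), translate_sd_px=0.0, jitter_sd_px=0.0,
            tremor_sd_deg=0.0, blink_rate_per_trial=0.0, **kw
        )

    def test_identity_distortion_revisits_encoding_positions(self, models):
        cfg = self._identity_cfg(enc_fix_count=(10, 0), rec_fix_count=(10, 0))
        _, enc = simulate_encoding_trial(models[0], cfg, 21)
        _, rec = simulate_recall_trial(enc, cfg, 22)
        # same positions as a set (order is deliberately not reinstated)
        assert rec.scale == 1.0
        got = set(map(tuple, np.round(rec.fix_xy, 6)))
        want = set(map(tuple, np.round(enc.fix_xy, 6)))
        assert got == want

    def test_halving_scale_quarters_bbox_area(self, models):
        cfg = SimConfig(shrink_range=(0.5, 0.5), translate_sd_px=0.0, jitter_sd_px=0.0)
        _, enc = simulate_encoding_trial(models[1], cfg, 4)
        _, rec = simulate_recall_trial(enc, cfg, 5)
        src = enc.fix_xy[rec.source_indices]

        def area(p):
            return np.ptp(p[:, 0]) * np.ptp(p[:, 1])

        assert area(rec.fix_xy) == pytest.approx(0.25 * area(src), rel=1e-6)

    def test_mean_fixation_count_matches_recall_law(self, models):
        cfg = SimConfig()
        counts = []
        for i in range(300):
            _, enc = simulate_encoding_trial(models[i % len(models)], cfg, 2000 + i)
            counts.append(simulate_recall_trial(enc, cfg, 5000 + i)[1].n_fixations)
        assert np.mean(counts) == pytest.approx(11.0, abs=0.5)

    def test_shrink_factor_recovery(self):
        # sqrt of recall/encoding bbox-area ratio recovers the planted scale
        cfg = SimConfig(n_subjects=10, n_images=20, seed=5, jitter_sd_px=0.0,
                        subject_style_range=(1.0, 1.0), rate_hz=100)
        _, truths = simulate_study(cfg)
        errs = []
        for tr in truths.values():
            if tr.phase != "recall":
                continue
            enc = truths[(tr.subject_id, tr.image_id, "encoding")]
            src = enc.fix_xy[tr.source_indices]
            a_src = np.ptp(src[:, 0]) * np.ptp(src[:, 1])
            a_rec = np.ptp(tr.fix_xy[:, 0]) * np.ptp(tr.fix_xy[:, 1])
            if a_src > 0:
                errs.append(np.sqrt(a_rec / a_src) - tr.scale)
        assert len(errs) >= 200
        assert abs(np.mean(errs)) < 0.05


class TestStudy:
    def test_design_counts_small(self):
        trials, truths = simulate_study(SimConfig(n_subjects=1, n_images=1, seed=0))
        assert len(trials) == 2
        assert len(truths) == 2

    def test_per_subject_sequence_count(self):
        cfg = SimConfig(n_subjects=3, n_images=4, seed=2, rate_hz=100)
        trials, _ = simulate_study(cfg)
        for s in trials.subjects():
            assert len(trials.select(subject_id=s)) == 2 * cfg.n_images

    def test_determinism_byte_identical(self):
        cfg = SimConfig(n_subjects=2, n_images=2, seed=42)
        t1, _ = simulate_study(cfg)
        t2, _ = simulate_study(cfg)
        for a, b in zip(t1, t2):
            assert a.key == b.key
            np.testing.assert_array_equal(a.x_px, b.x_px)
            np.testing.assert_array_equal(a.valid, b.valid)

    def test_subject_style_scales_shrinkage(self):
        small = SimConfig(n_subjects=2, n_images=8, seed=3,
                          subject_style_range=(0.6, 0.6))
        big = SimConfig(n_subjects=2, n_images=8, seed=3,
                        subject_style_range=(1.0, 1.0))
        def mean_scale(cfg):
            _, truths = simulate_study(cfg)
            return np.mean([t.scale for t in truths.values() if t.phase == "recall"])
        assert mean_scale(small) < mean_scale(big)
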