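import numpy as np
import pytest

from gazerec import TripletDescriptorEmbedder, imagefold_evaluate, match_query, roc_auc
from gazerec.histograms import GazeHistogram

from conftest import make_blob_hists

FAST = dict(base_channels=8, epochs=150)


@pytest.fixture(scope="module")
def identity_pairs():
    # recall histograms identical to encoding ones: the easiest matching task
    X, y, subj = make_blob_hists(n_classes=8, per_class=3, n_subjects=3, seed=0)
    return X, y, subj


def _satisfaction(emb, Xe, Xr, imgs):
    E = emb.transform(Xe, "encoding")
    R = emb.transform(Xr, "recall")
    good = tot = 0
    for i in range(len(Xe)):
        for j in range(len(Xe)):
            if imgs[i] == imgs[j]:
                continue
            tot += 1
            good += np.linalg.norm(R[i] - E[i]) < np.linalg.norm(R[i] - E[j])
    return good / tot


class TestTraining:
    @pytest.mark.parametrize("loss", ["triplet", "hinge"])
    def test_identity_data_triplet_satisfaction(self, identity_pairs, loss):
        X, y, subj = identity_pairs
        emb = TripletDescriptorEmbedder(loss=loss, seed=0, **FAST).fit(X, X, y, subj)
        assert _satisfaction(emb, X, X, y) >= 0.95

    def test_loss_decreases(self, identity_pairs):
        X, y, subj = identity_pairs
        emb = TripletDescriptorEmbedder(seed=1, **FAST).fit(X, X, y, subj)
        assert emb.loss_trace_[-1] < emb.loss_trace_[0]

    def test_misaligned_pairs_rejected(self, identity_pairs):
        X, y, subj = identity_pairs
        with pytest.raises(ValueError):
            TripletDescriptorEmbedder(epochs=1).fit(X, X[:-1], y, subj)

    def test_lr_schedule_and_params_exposed(self):
        emb = TripletDescriptorEmbedder()
        p = emb.get_params()
        assert p["epochs"] == 1000 and p["base_lr"] == 1e-3
        assert p["lr_decay"] == 0.75 and p["lr_step"] == 100
        assert p["beta1"] == 0.95 and p["batch_size"] == 20


class TestEmbedding:
    def test_descriptor_dimension_is_16(self, identity_pairs):
        X, y, subj = identity_pairs
        emb = TripletDescriptorEmbedder(epochs=2, base_channels=8, seed=0).fit(X, X, y, subj)
        d = emb.embed(X[0], "encoding")
        assert d.shape == (16,)

    def test_deterministic_and_phase_specific(self, identity_pairs):
        X, y, subj = identity_pairs
        emb = TripletDescriptorEmbedder(epochs=2, base_channels=8, seed=0).fit(X, X, y, subj)
        d1 = emb.embed(X[0], "encoding")
        d2 = emb.embed(X[0], "encoding")
        np.testing.assert_array_equal(d1, d2)  # bitwise repeatable
        assert not np.array_equal(d1, emb.embed(X[0], "recall"))  # twin nets differ


class TestMatchQuery:
    def test_exact_candidate_ranks_first(self):
        cands = [(np.array([1.0, 0.0]), "a"), (np.array([0.0, 5.0]), "b")]
        assert match_query(np.array([0.0, 5.0]), cands)[0] == "b"

    def test_two_candidate_ordering(self):
        cands = [(np.array([2.0]), "far"), (np.array([1.0]), "near")]
        assert match_query(np.array([0.0]), cands) == ["near", "far"]

    def test_matches_brute_force_sort_oracle(self):
        rng = np.random.default_rng(4)
        q = rng.normal(size=16)
        cands = [(rng.normal(size=16), f"i{k:03d}") for k in range(100)]
        got = match_query(q, cands)
        want = [img for _, img in sorted(
            ((float(np.linalg.norm(d - q)), img) for d, img in cands))]
        assert got == want

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(5)
        q = rng.normal(size=3)
        descs = [rng.normal(size=3) for _ in range(10)]
        cands = [(d, f"i{k}") for k, d in enumerate(descs)]
        # random rotation + common translation preserve all distances
        R, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(size=3)
        moved = [(R @ d + t, f"i{k}") for k, d in enumerate(descs)]
        assert match_query(q, cands) == match_query(R @ q + t, moved)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            match_query(np.zeros(16), [])


class TestImageFold:
    @staticmethod
    def _hists(X, y, subj, Xr=None):
        out = []
        Xr = X if Xr is None else Xr
        for x, xr, c, s in zip(X, Xr, y, subj):
            for phase, grid in (("encoding", x), ("recall", xr)):
                out.append(GazeHistogram(grid=grid, subject_id=s, image_id=c, phase=phase,
                                         total_samples=int(grid.sum()), normalized=False))
        return out

    def test_identity_data_near_perfect_auc(self, identity_pairs):
        X, y, subj = identity_pairs
        hists = self._hists(X, y, subj)
        table = imagefold_evaluate(hists, n_folds=4, seed=0, **FAST)
        assert roc_auc(table).auc > 0.95

    def test_fold_divisibility_enforced(self, identity_pairs):
        X, y, subj = identity_pairs
        with pytest.raises(ValueError):
            imagefold_evaluate(self._hists(X, y, subj), n_folds=3, epochs=1)

    def test_label_shuffle_null_is_chance(self, identity_pairs):
        # breaking the encoding/recall pairing destroys retrieval signal
        X, y, subj = identity_pairs
        rng = np.random.default_rng(9)
        Xr = X[rng.permutation(len(X))]
        hists = self._hists(X, y, subj, Xr=Xr)
        table = imagefold_evaluate(hists, n_folds=4, seed=0, **FAST)
        assert roc_auc(table).auc == pytest.approx(0.5, abs=0.12)

    def test_held_out_images_absent_from_training(self, identity_pairs):
        # fold recomputation oracle as leakage probe: training ignores the
        # held-out images entirely, so retraining on the complement reproduces
        # the fold's descriptors bit for bit
        X, y, subj = identity_pairs
        hists = self._hists(X, y, subj)
        images = sorted({h.image_id for h in hists})
        folds = [images[i::4] for i in range(4)]
        held = set(folds[0])
        keys = [(s, i) for s in sorted(set(subj)) for i in images if i not in held]
        enc = {(h.subject_id, h.image_id): h for h in hists if h.phase == "encoding"}
        rec = {(h.subject_id, h.image_id): h for h in hists if h.phase == "recall"}
        emb = TripletDescriptorEmbedder(seed=0, epochs=3, base_channels=8)
        emb.fit(np.stack([enc[k].grid for k in keys]),
                np.stack([rec[k].grid for k in keys]),
                [k[1] for k in keys], [k[0] for k in keys])
        # poisoning the held-out images' histograms must not change training
        hists2 = [
            GazeHistogram(grid=h.grid + 11.0, subject_id=h.subject_id,
                          image_id=h.image_id, phase=h.phase,
                          total_samples=h.total_samples, normalized=False)
            if h.image_id in held else h
            for h in hists
        ]
        enc2 = {(h.subject_id, h.image_id): h for h in hists2 if h.phase == "encoding"}
        rec2 = {(h.subject_id, h.image_id): h for h in hists2 if h.phase == "recall"}
        emb2 = TripletDescriptorEmbedder(seed=0, epochs=3, base_channels=8)
        emb2.fit(np.stack([enc2[k].grid for k in keys]),
                 np.stack([rec2[k].grid for k in keys]),
                 [k[1] for k in keys], [k[0] for k in keys])
        probe = np.stack([h.grid for h in hists[:3]])
        np.testing.assert_array_equal(emb.transform(probe, "encoding"),
                                      emb2.transform(probe, "encoding"))
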