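"""Metric-learned descriptor matching of recall to encoding histograms.

Two twin networks (one for encoding histograms, one for recall histograms)
embed each histogram into a shared 16-dimensional descriptor space in which
matching encoding/recall pairs are close and non-matching pairs are far
apart.  Training uses two triplet losses in tandem — one anchored on the
recall descriptor against matching/non-matching encoding descriptors, one
anchored the other way round — with Euclidean distances and a fixed margin.

At test time a subject's recall descriptor is matched against that subject's
encoding descriptors by ascending distance.  Because the embedding is learned
on image-independent structure, it generalises to images never seen in
training: evaluation is 10-fold cross-validation over images, matching each
held-out recall trial within the held-out fold of the same subject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .cnn import build_conv_encoder, _prepare_X
from .evaluation import RANK_COLUMNS, rank_of_truth

__all__ = ["TripletDescriptorEmbedder", "match_query", "imagefold_evaluate"]


def _build_descriptor_net(rng, grid, base_channels, descriptor_dim):
    # classification encoder with a 16-output head; no batch norm, no dropout
    c = base_channels
    n_feat = 4 * c * (grid // 4) ** 2
    return nn.Sequential(
        *build_conv_encoder(rng, c).layers,
        nn.Flatten(),
        nn.Linear(n_feat, 256, rng),
        nn.ReLU(),
        nn.Linear(256, descriptor_dim, rng),
    )


class TripletDescriptorEmbedder(BaseEstimator, TransformerMixin):
    """Twin descriptor networks trained with two triplet losses.

    Defaults follow the published recipe: 1000 epochs, base learning rate
    0.001 scaled by 0.75 every 100 epochs, Adam with beta1 = beta2 = 0.95,
    batch size 20, L2 weight decay 1e-8, 16-dimensional descriptors.  The
    margin (unstated in the recipe) defaults to 0.2; ``loss="hinge"``
    switches to a contrastive pair loss.
    """

    def __init__(self, grid: int = 24, descriptor_dim: int = 16, epochs: int = 1000,
                 base_lr: float = 1e-3, lr_decay: float = 0.75, lr_step: int = 100,
                 beta1: float = 0.95, beta2: float = 0.95, batch_size: int = 20,
                 weight_decay: float = 1e-8, margin: float = 0.2,
                 loss: str = "triplet", base_channels: int = 16, seed: int = 0):
        self.grid = grid
        self.descriptor_dim = descriptor_dim
        self.epochs = epochs
        self.base_lr = base_lr
        self.lr_decay = lr_decay
        self.lr_step = lr_step
        self.beta1 = beta1
        self.beta2 = beta2
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.margin = margin
        self.loss = loss
        self.base_channels = base_channels
        self.seed = seed

    def _pick_negatives(self, image_ids, subject_ids, idx, rng):
        """Within-batch negative positions: a different image, same subject preferred."""
        neg = np.empty(len(idx), dtype=int)
        ok = np.ones(len(idx), dtype=bool)
        for pos, i in enumerate(idx):
            other = [p for p, j in enumerate(idx) if image_ids[j] != image_ids[i]]
            if not other:
                ok[pos] = False
                neg[pos] = pos
                continue
            same_subj = [p for p in other if subject_ids[idx[p]] == subject_ids[i]]
            cands = same_subj if same_subj else other
            neg[pos] = cands[rng.integers(len(cands))]
        return neg, ok

    def fit(self, X_enc, X_rec, image_ids, subject_ids):
        """Train both branches on matched (encoding, recall) histogram pairs."""
        if self.loss not in ("triplet", "hinge"):
            raise ValueError("loss must be 'triplet' or 'hinge'")
        image_ids = np.asarray(image_ids)
        subject_ids = np.asarray(subject_ids)
        if not (len(X_enc) == len(X_rec) == len(image_ids) == len(subject_ids)):
            raise ValueError("pairs must align: X_enc, X_rec, image_ids, subject_ids")
        Xe = _prepare_X(X_enc, self.grid)
        Xr = _prepare_X(X_rec, self.grid)
        ss = np.random.SeedSequence(self.seed)
        init_ss, train_ss = ss.spawn(2)
        init_rng = np.random.default_rng(init_ss)
        rng = np.random.default_rng(train_ss)
        self.encoder_net_ = _build_descriptor_net(init_rng, self.grid, self.base_channels,
                                                  self.descriptor_dim)
        self.recall_net_ = _build_descriptor_net(init_rng, self.grid, self.base_channels,
                                                 self.descriptor_dim)
        opt = nn.Adam(self.encoder_net_.params() + self.recall_net_.params(),
                      lr=self.base_lr, beta1=self.beta1, beta2=self.beta2,
                      weight_decay=self.weight_decay)
        loss_fn = nn.triplet_loss if self.loss == "triplet" else nn.hinge_pair_loss
        self.loss_trace_ = []
        self.skipped_batches_ = 0
        n = len(Xe)
        for epoch in range(self.epochs):
            lr = self.base_lr * self.lr_decay ** (epoch // self.lr_step)
            perm = rng.permutation(n)
            losses = []
            for i in range(0, n, self.batch_size):
                idx = perm[i:i + self.batch_size]
                if len(idx) < 2:
                    continue
                neg, ok = self._pick_negatives(image_ids, subject_ids, idx, rng)
                if not ok.all():
                    # no valid negative available in this batch
                    self.skipped_batches_ += 1
                    continue
                opt.zero_grad()
                E = self.encoder_net_.forward(Xe[idx], train=True)
                R = self.recall_net_.forward(Xr[idx], train=True)
                # negatives are other batch members' descriptors of the same branch
                E_neg = E[neg]
                R_neg = R[neg]
                l1, (dR1, dE_pos1, dE_neg1) = loss_fn(R, E, E_neg, self.margin)
                l2, (dE2, dR_pos2, dR_neg2) = loss_fn(E, R, R_neg, self.margin)
                dE = dE_pos1 + dE2
                dR = dR1 + dR_pos2
                # scatter negative gradients back to their batch positions
                np.add.at(dE, neg, dE_neg1)
                np.add.at(dR, neg, dR_neg2)
                self.encoder_net_.backward(dE)
                self.recall_net_.backward(dR)
                opt.step(lr)
                losses.append(l1 + l2)
            self.loss_trace_.append(float(np.mean(losses)) if losses else float("nan"))
        return self

    def transform(self, X, phase: str = "encoding") -> np.ndarray:
        """Embed histograms with the branch matching their phase."""
        check_is_fitted(self, "encoder_net_")
        net = self.encoder_net_ if phase == "encoding" else self.recall_net_
        return net.forward(_prepare_X(X, self.grid), train=False)

    def embed(self, hist, phase: str) -> np.ndarray:
        """16-d descriptor of a single histogram."""
        grid = hist.grid if hasattr(hist, "grid") else np.asarray(hist)
        return self.transform(grid[None], phase=phase)[0]


def match_query(recall_d: np.ndarray, candidates: list[tuple[np.ndarray, str]]) -> list[str]:
    """Rank candidate images by ascending Euclidean descriptor distance.

    Ties are broken by ascending image id.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    q = np.asarray(recall_d, dtype=float)
    items = sorted(
        (float(np.linalg.norm(np.asarray(d, dtype=float) - q)), img) for d, img in candidates
    )
    return [img for _, img in items]


def imagefold_evaluate(
    hists,
    n_folds: int = 10,
    candidate_set: str = "fold",
    **embedder_params,
) -> pd.DataFrame:
    """K-fold-over-images descriptor matching (generalisation to unseen images).

    Images are split into ``n_folds`` groups; each fold's embedder is trained
    on the complement (all subjects), then every subject's recall descriptor
    of a held-out image is matched against that subject's encoding
    descriptors of the held-out images (``candidate_set="fold"``) or of all
    images (``"all"``).  Returns the pooled rank table.
    """
    enc = {(h.subject_id, h.image_id): h for h in hists if h.phase == "encoding"}
    rec = {(h.subject_id, h.image_id): h for h in hists if h.phase == "recall"}
    images = sorted({h.image_id for h in hists})
    subjects = sorted({h.subject_id for h in hists})
    if len(images) % n_folds:
        raise ValueError(f"{len(images)} images not divisible into {n_folds} folds")
    folds = [images[i::n_folds] for i in range(n_folds)]

    rows = []
    for f, held_images in enumerate(folds):
        held = set(held_images)
        keys = [
            (s, i) for s in subjects for i in images
            if i not in held and (s, i) in enc and (s, i) in rec
        ]
        emb = TripletDescriptorEmbedder(**embedder_params)
        emb.set_params(seed=emb.seed + f)
        emb.fit(
            np.stack([enc[k].grid for k in keys]),
            np.stack([rec[k].grid for k in keys]),
            [k[1] for k in keys],
            [k[0] for k in keys],
        )
        for s in subjects:
            cand_images = held_images if candidate_set == "fold" else images
            cand_keys = [(s, i) for i in cand_images if (s, i) in enc]
            if not cand_keys:
                continue
            cand_d = emb.transform(np.stack([enc[k].grid for k in cand_keys]), "encoding")
            C = len(cand_keys)
            for img in held_images:
                if (s, img) not in rec or (s, img) not in enc:
                    continue  # subject missing a phase for this image: skip query
                q = emb.embed(rec[(s, img)], "recall")
                dists = np.linalg.norm(cand_d - q, axis=1)
                scores = pd.Series(-dists, index=[k[1] for k in cand_keys])
                rows.append((f"{s}:{img}", s, img, rank_of_truth(scores, img), C))
    return pd.DataFrame(rows, columns=RANK_COLUMNS)
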