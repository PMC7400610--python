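"""CNN retrieval over gaze histograms.

Two estimators:

* :class:`HistogramCNNClassifier` — a small convolutional classifier over
  normalised 24 x 24 gaze histograms (stacked 3 x 3 convolutions with two
  max-poolings, a 256-unit head, C logits), trained with cross-entropy.
* :class:`DualTaskCNNClassifier` — the same encoder plus a decoder branch
  that, given a recall histogram, reconstructs the matching encoding
  histogram; trained with ``L = L_cross + lambda * L_1`` (lambda = 1000).
  Dropout and batch normalisation are disabled everywhere in this variant,
  and the decoder inserts a convolution before each transposed convolution.

Defaults follow the published training recipe: Adam (lr 5e-4, weight decay
2e-5), batch size 100, 80 epochs, Xavier/orthogonal initialisation.
Evaluation is leave-one-subject-out: the network is retrained once per
subject with that subject's trials withheld, and tested only on them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .evaluation import RANK_COLUMNS, rank_of_truth
from .histograms import GazeHistogram

__all__ = [
    "HistogramCNNClassifier",
    "DualTaskCNNClassifier",
    "classify",
    "loso_cnn_evaluate",
]


def build_conv_encoder(rng, base_channels: int = 32) -> nn.Sequential:
    """Shared feature extractor: (1, G, G) -> (4c, G/4, G/4)."""
    c = base_channels
    return nn.Sequential(
        nn.Conv2d(1, c, rng), nn.ReLU(),
        nn.Conv2d(c, c, rng), nn.ReLU(),
        nn.MaxPool2d(),
        nn.Conv2d(c, 2 * c, rng), nn.ReLU(),
        nn.Conv2d(2 * c, 2 * c, rng), nn.ReLU(),
        nn.MaxPool2d(),
        nn.Conv2d(2 * c, 4 * c, rng), nn.ReLU(),
    )


def _build_head(rng, n_feat, hidden, n_classes, dropout, batch_norm, drop_rng):
    layers: list = [nn.Flatten(), nn.Linear(n_feat, hidden, rng)]
    if batch_norm:
        layers.append(nn.BatchNorm1d(hidden))
    layers.append(nn.ReLU())
    if dropout:
        layers.append(nn.Dropout(drop_rng, 0.5))
    layers.append(nn.Linear(hidden, n_classes, rng))
    return nn.Sequential(*layers)


def _build_decoder(rng, base_channels: int) -> nn.Sequential:
    c = base_channels
    return nn.Sequential(
        nn.Conv2d(4 * c, 2 * c, rng), nn.ReLU(),
        nn.ConvTranspose2d(2 * c, 2 * c, rng), nn.ReLU(),
        nn.Conv2d(2 * c, c, rng), nn.ReLU(),
        nn.ConvTranspose2d(c, c, rng), nn.ReLU(),
        nn.Conv2d(c, 1, rng), nn.Softplus(),
    )


def _prepare_X(X, grid):
    X = np.asarray(X, dtype=np.float32)
    X = X.reshape(len(X), grid, grid)
    sums = X.sum(axis=(1, 2), keepdims=True)
    sums[sums == 0] = 1.0
    return (X / sums)[:, None, :, :]  # normalise to unit mass, add channel axis


class HistogramCNNClassifier(BaseEstimator, ClassifierMixin):
    """Convolutional classifier over gaze-density histograms."""

    def __init__(self, grid: int = 24, epochs: int = 80, learning_rate: float = 5e-4,
                 weight_decay: float = 2e-5, batch_size: int = 100, dropout: bool = True,
                 batch_norm: bool = True, base_channels: int = 32, hidden: int = 256,
                 seed: int = 0):
        self.grid = grid
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.dropout = dropout
        self.batch_norm = batch_norm
        self.base_channels = base_channels
        self.hidden = hidden
        self.seed = seed

    # -- construction -----------------------------------------------------
    def _init_nets(self, n_classes, with_decoder=False):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        ss = np.random.SeedSequence(self.seed)
        init_ss, train_ss, drop_ss = ss.spawn(3)
        init_rng = np.random.default_rng(init_ss)
        self._train_rng = np.random.default_rng(train_ss)
        drop_rng = np.random.default_rng(drop_ss)
        c = self.base_channels
        n_feat = 4 * c * (self.grid // 4) ** 2
        self.encoder_ = build_conv_encoder(init_rng, c)
        self.head_ = _build_head(init_rng, n_feat, self.hidden, n_classes,
                                 self.dropout, self.batch_norm, drop_rng)
        self.decoder_ = _build_decoder(init_rng, c) if with_decoder else None

    def _check_classes(self, y, classes):
        present = np.unique(y)
        if classes is None:
            self.classes_ = present
        else:
            self.classes_ = np.asarray(classes)
            missing = set(self.classes_) - set(present)
            if missing:
                raise ValueError(f"classes absent from training data: {sorted(missing)[:5]}")
        lut = {c: i for i, c in enumerate(self.classes_)}
        return np.array([lut[v] for v in y])

    # -- training ---------------------------------------------------------
    def fit(self, X, y, classes=None):
        codes = self._check_classes(np.asarray(y), classes)
        X = _prepare_X(X, self.grid)
        self._init_nets(len(self.classes_))
        params = self.encoder_.params() + self.head_.params()
        opt = nn.Adam(params, lr=self.learning_rate, weight_decay=self.weight_decay)
        self.loss_trace_ = []
        n = len(X)
        for _ in range(self.epochs):
            perm = self._train_rng.permutation(n)
            losses = []
            for i in range(0, n, self.batch_size):
                idx = perm[i:i + self.batch_size]
                opt.zero_grad()
                feat = self.encoder_.forward(X[idx], train=True)
                logits = self.head_.forward(feat, train=True)
                loss, dlogits = nn.softmax_cross_entropy(logits, codes[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {len(self.loss_trace_)}: {loss}"
                    )
                self.encoder_.backward(self.head_.backward(dlogits))
                opt.step()
                losses.append(loss)
            self.loss_trace_.append(float(np.mean(losses)))
        return self

    # -- inference --------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "encoder_")
        X = _prepare_X(X, self.grid)
        feat = self.encoder_.forward(X, train=False)
        return self.head_.forward(feat, train=False)

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_function(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


class DualTaskCNNClassifier(HistogramCNNClassifier):
    """Dual-task variant: classification plus reconstruction of the matching
    encoding histogram from the recall input.

    ``fit(X, y, target=...)`` requires, for every recall histogram, the
    encoding histogram of the same subject and image.  Dropout and batch
    normalisation are disabled regardless of the flags.
    """

    def __init__(self, grid: int = 24, epochs: int = 80, learning_rate: float = 5e-4,
                 weight_decay: float = 2e-5, batch_size: int = 100,
                 base_channels: int = 32, hidden: int = 256,
                 lambda_l1: float = 1000.0, seed: int = 0):
        super().__init__(grid=grid, epochs=epochs, learning_rate=learning_rate,
                         weight_decay=weight_decay, batch_size=batch_size,
                         dropout=False, batch_norm=False,
                         base_channels=base_channels, hidden=hidden, seed=seed)
        self.lambda_l1 = lambda_l1

    def fit(self, X, y, target=None, classes=None):
        if target is None:
            raise ValueError("dual-task training requires the paired encoding histograms")
        if len(target) != len(X):
            raise ValueError("every recall histogram must be paired with an encoding one")
        codes = self._check_classes(np.asarray(y), classes)
        X = _prepare_X(X, self.grid)
        T = _prepare_X(target, self.grid)
        self._init_nets(len(self.classes_), with_decoder=True)
        params = self.encoder_.params() + self.head_.params() + self.decoder_.params()
        opt = nn.Adam(params, lr=self.learning_rate, weight_decay=self.weight_decay)
        self.loss_trace_ = []
        self.ce_trace_ = []
        self.l1_trace_ = []
        n = len(X)
        for _ in range(self.epochs):
            perm = self._train_rng.permutation(n)
            ce_l, l1_l = [], []
            for i in range(0, n, self.batch_size):
                idx = perm[i:i + self.batch_size]
                opt.zero_grad()
                feat = self.encoder_.forward(X[idx], train=True)
                logits = self.head_.forward(feat, train=True)
                recon = self.decoder_.forward(feat, train=True)
                ce, dlogits = nn.softmax_cross_entropy(logits, codes[idx])
                l1, drecon = nn.l1_loss(recon, T[idx])
                if not (np.isfinite(ce) and np.isfinite(l1)):
                    raise RuntimeError(f"non-finite loss: CE={ce}, L1={l1}")
                dfeat = self.head_.backward(dlogits)
                if self.lambda_l1 != 0:
                    dfeat = dfeat + self.decoder_.backward(
                        (self.lambda_l1 * drecon).astype(np.float32)
                    )
                self.encoder_.backward(dfeat)
                opt.step()
                ce_l.append(ce)
                l1_l.append(l1)
            self.ce_trace_.append(float(np.mean(ce_l)))
            self.l1_trace_.append(float(np.mean(l1_l)))
            self.loss_trace_.append(self.ce_trace_[-1] + self.lambda_l1 * self.l1_trace_[-1])
        return self

    def reconstruct(self, X) -> np.ndarray:
        """Decoder output: predicted encoding histograms for recall inputs."""
        check_is_fitted(self, "decoder_")
        X = _prepare_X(X, self.grid)
        feat = self.encoder_.forward(X, train=False)
        return self.decoder_.forward(feat, train=False)[:, 0]


def classify(net: HistogramCNNClassifier, query) -> pd.Series:
    """Class-score table (logits) for one query histogram, sorted best-first."""
    x = query.flatten() if isinstance(query, GazeHistogram) else np.asarray(query).ravel()
    z = net.decision_function(x[None, :])[0]
    return pd.Series(z, index=net.classes_).sort_values(ascending=False, kind="stable")


def loso_cnn_evaluate(
    hists: list[GazeHistogram],
    phase: str = "encoding",
    dual: bool = False,
    **estimator_params,
) -> pd.DataFrame:
    """Leave-one-subject-out CNN retrieval.

    Trains one network per subject with that subject's data withheld and
    ranks the true image for each withheld query.  With ``dual=True`` the
    phase must be ``recall``; each recall histogram is paired with the same
    subject/image encoding histogram as the reconstruction target.
    """
    pool = [h for h in hists if h.phase == phase]
    subjects = sorted({h.subject_id for h in pool})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 subjects")
    classes = sorted({h.image_id for h in pool})
    C = len(classes)
    enc_by_key = {(h.subject_id, h.image_id): h for h in hists if h.phase == "encoding"}
    if dual and phase != "recall":
        raise ValueError("dual-task evaluation operates on the recall phase")

    rows = []
    for held_out in subjects:
        train = [h for h in pool if h.subject_id != held_out]
        test = [h for h in pool if h.subject_id == held_out]
        Xtr = np.stack([h.grid for h in train])
        ytr = [h.image_id for h in train]
        if dual:
            try:
                Ttr = np.stack([enc_by_key[(h.subject_id, h.image_id)].grid for h in train])
            except KeyError as exc:
                raise ValueError(f"unpaired recall histogram: {exc}") from exc
            model = DualTaskCNNClassifier(**estimator_params)
            model.fit(Xtr, ytr, target=Ttr, classes=classes)
        else:
            model = HistogramCNNClassifier(**estimator_params)
            model.fit(Xtr, ytr, classes=classes)
        logits = model.decision_function(np.stack([h.grid for h in test]))
        for h, z in zip(test, logits):
            scores = pd.Series(z, index=model.classes_)
            rows.append(
                (f"{held_out}:{h.image_id}", held_out, h.image_id,
                 rank_of_truth(scores, h.image_id), C)
            )
    return pd.DataFrame(rows, columns=RANK_COLUMNS)
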