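"""Baseline image retrieval: distance-weighted k-nearest-neighbour matching
of gaze-density histograms (Euclidean distance, k = 27).

The classifier scores each image class by the summed inverse distances of its
exemplars among the k nearest neighbours of the query.  Because the ROC
evaluation needs a full ranking over all classes (not just the vote winner),
classes without an exemplar among the k neighbours are ordered by a secondary
key: the distance to their nearest exemplar.  This extension reduces to the
plain weighted vote at rank 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .evaluation import RANK_COLUMNS, rank_of_truth
from .histograms import GazeHistogram

__all__ = ["KnnHistogramClassifier", "knn_score", "loso_knn_evaluate"]


class KnnHistogramClassifier(BaseEstimator, ClassifierMixin):
    """Distance-weighted kNN over flattened gaze histograms.

    Parameters
    ----------
    k : number of neighbours in the primary vote (default 27).
    epsilon : regulariser of the inverse-distance weight 1/(d + epsilon);
        an exact duplicate therefore deterministically wins.
    """

    def __init__(self, k: int = 27, epsilon: float = 1e-8):
        self.k = k
        self.epsilon = epsilon

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            X = X.reshape(len(X), -1)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if self.k > len(X):
            raise ValueError(f"k={self.k} exceeds number of exemplars {len(X)}")
        self.classes_, self._codes = np.unique(y, return_inverse=True)
        self.X_ = X
        self.n_features_in_ = X.shape[1]
        return self

    def score_table(self, x) -> pd.Series:
        """Per-class retrieval scores for one query (higher = better).

        Primary key: sum of 1/(d + eps) over the class's exemplars among the
        k nearest.  Classes with zero primary score get the negated distance
        to their nearest exemplar, which is below every positive primary
        score, preserving the two-key ordering in a single numeric score.
        """
        check_is_fitted(self, "X_")
        x = np.asarray(x, dtype=float).ravel()
        if x.shape[0] != self.n_features_in_:
            raise ValueError(
                f"query has {x.shape[0]} features, exemplars have {self.n_features_in_}"
            )
        d = cdist(x[None, :], self.X_)[0]
        nearest = np.argsort(d, kind="stable")[: self.k]
        primary = np.zeros(len(self.classes_))
        np.add.at(primary, self._codes[nearest], 1.0 / (d[nearest] + self.epsilon))
        dmin = np.full(len(self.classes_), np.inf)
        np.minimum.at(dmin, self._codes, d)
        score = np.where(primary > 0, primary, -dmin)
        return pd.Series(score, index=self.classes_)

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float).reshape(len(X), -1)
        return np.vstack([self.score_table(x).to_numpy() for x in X])

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def knn_score(model: KnnHistogramClassifier, query: GazeHistogram | np.ndarray) -> pd.Series:
    """Class-score table for one query histogram, sorted best-first."""
    x = query.flatten() if isinstance(query, GazeHistogram) else np.asarray(query).ravel()
    s = model.score_table(x)
    return s.sort_values(ascending=False, kind="stable")


def loso_knn_evaluate(
    hists: list[GazeHistogram], phase: str = "encoding", k: int = 27, epsilon: float = 1e-8
) -> pd.DataFrame:
    """Leave-one-subject-out kNN retrieval within one phase.

    For each held-out subject, every one of their histograms is scored
    against all *other* subjects' histograms of the same phase; returns a
    rank table (one row per query) with competition mid-ranks.
    """
    pool = [h for h in hists if h.phase == phase]
    subjects = sorted({h.subject_id for h in pool})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 subjects")
    C = len({h.image_id for h in pool})
    rows = []
    for held_out in subjects:
        train = [h for h in pool if h.subject_id != held_out]
        test = [h for h in pool if h.subject_id == held_out]
        model = KnnHistogramClassifier(k=min(k, len(train)), epsilon=epsilon).fit(
            np.stack([h.flatten() for h in train]),
            [h.image_id for h in train],
        )
        for h in test:
            scores = model.score_table(h.flatten())
            rows.append(
                (f"{held_out}:{h.image_id}", held_out, h.image_id,
                 rank_of_truth(scores, h.image_id), C)
            )
    return pd.DataFrame(rows, columns=RANK_COLUMNS)
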