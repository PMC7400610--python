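"""Rank-based retrieval evaluation.

Every retrieval method reduces to, per query, a score over all C candidate
images; accuracy is summarised by the rank of the true image.  Accumulating
ranks gives an ROC-style curve (fraction of queries whose true image is
within the top r, for r = 0..C) and its area (AUC).  AUC is defined as the
mean normalised rank ``(C - rank) / (C - 1)``, which is exactly 50 % when
ranks are uniform on 1..C (the chance level) and 100 % when every query
ranks its true image first.  Ties get competition mid-ranks so the chance
calibration stays unbiased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RANK_COLUMNS",
    "RocCurve",
    "rank_of_truth",
    "ranking_from_scores",
    "roc_auc",
    "top_k",
    "per_subject_auc",
    "confusion_pairs",
]

#: Column contract of a rank table (one row per query).
RANK_COLUMNS = ["query_id", "subject_id", "truth", "rank", "C"]


@dataclass
class RocCurve:
    """Rank-accumulation curve: ``fraction[r]`` = share of queries with rank <= r."""

    ranks: np.ndarray       # r = 0..C
    fraction: np.ndarray    # cumulative fraction, fraction[0] = 0
    auc: float

    def trapezoid_auc(self) -> float:
        """Area under the plotted curve with normalised axes; agrees with the
        mean-normalised-rank AUC within 1/(2(C-1))."""
        C = self.ranks[-1]
        return float(np.trapezoid(self.fraction, self.ranks / C))


def rank_of_truth(scores: pd.Series | dict, truth) -> int:
    """Competition mid-rank of the true image in a class-score table.

    Higher scores are better.  rank = 1 + (# strictly better) +
    (# tied - 1)/2, rounded half-up.
    """
    s = pd.Series(scores, dtype=float)
    if truth not in s.index:
        raise KeyError(f"true class {truth!r} absent from score table")
    v = s[truth]
    better = int((s > v).sum())
    tied = int((s == v).sum())
    return int(math.floor(1 + better + (tied - 1) / 2.0 + 0.5))


def ranking_from_scores(scores: pd.Series, rng: np.random.Generator | None = None) -> list:
    """Best-first class ordering; exact ties broken by ascending image id
    after an optional seeded shuffle (so tie resolution is reproducible but
    not systematically biased toward low ids)."""
    s = pd.Series(scores, dtype=float)
    ids = np.array(sorted(s.index))
    if rng is not None:
        ids = ids[rng.permutation(len(ids))]
    vals = s.loc[ids].to_numpy()
    order = np.argsort(-vals, kind="stable")
    return ids[order].tolist()


def _check_table(table: pd.DataFrame) -> int:
    if table.empty:
        raise ValueError("empty rank table")
    C = table["C"].unique()
    if len(C) != 1:
        raise ValueError(f"mixed candidate-set sizes in rank table: {C}")
    return int(C[0])


def roc_auc(table: pd.DataFrame) -> RocCurve:
    """Rank-accumulation ROC curve and AUC for a rank table."""
    C = _check_table(table)
    ranks = table["rank"].to_numpy()
    r = np.arange(C + 1)
    frac = np.array([(ranks <= k).mean() for k in r])
    auc = float(((C - ranks) / (C - 1)).mean())
    return RocCurve(ranks=r, fraction=frac, auc=auc)


def top_k(table: pd.DataFrame, k: int) -> float:
    """Percentage of queries whose true image ranks within the top k."""
    C = _check_table(table)
    if not (1 <= k <= C):
        raise ValueError(f"k must be in 1..{C}")
    return float(100.0 * (table["rank"].to_numpy() <= k).mean())


def per_subject_auc(table: pd.DataFrame) -> dict:
    """AUC per subject plus mean/SD across subjects.

    The pooled AUC equals the query-count-weighted mean of per-subject AUCs.
    """
    _check_table(table)
    per = {
        subj: roc_auc(g).auc for subj, g in table.groupby("subject_id", sort=True)
    }
    vals = np.array(list(per.values()))
    return {
        "per_subject": per,
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
    }


def confusion_pairs(predictions) -> pd.DataFrame:
    """Count (true image -> wrong top-1 prediction) events.

    Parameters
    ----------
    predictions : iterable of (truth, predicted_top1)

    Returns
    -------
    DataFrame with columns truth, predicted, count, sorted by descending
    count (ties by ids); correct predictions are excluded.
    """
    pairs = [(t, p) for t, p in predictions if t != p]
    if not pairs:
        return pd.DataFrame(columns=["truth", "predicted", "count"])
    df = pd.DataFrame(pairs, columns=["truth", "predicted"])
    out = (
        df.value_counts(["truth", "predicted"])
        .rename("count")
        .reset_index()
        .sort_values(["count", "truth", "predicted"], ascending=[False, True, True])
        .reset_index(drop=True)
    )
    return out
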