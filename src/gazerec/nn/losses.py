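"""Loss functions returning (scalar loss, gradient w.r.t. inputs)."""

from __future__ import annotations

import numpy as np

from .layers import DTYPE


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; labels are integer class codes."""
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    p = expz / expz.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = float(-np.log(np.maximum(p[np.arange(n), labels], 1e-30)).mean())
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, (d / n).astype(DTYPE)


def l1_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error per element."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    return loss, (np.sign(diff) / diff.size).astype(DTYPE)


def _pairwise_dist(a, b, eps=1e-9):
    d = np.sqrt(((a - b) ** 2).sum(axis=1) + eps)
    return d


def triplet_loss(anchor, positive, negative, margin=0.2):
    """Euclidean triplet hinge: mean relu(margin + d(a,p) - d(a,n)).

    Returns (loss, (d_anchor, d_positive, d_negative)).
    """
    eps = 1e-9
    d_ap = _pairwise_dist(anchor, positive, eps)
    d_an = _pairwise_dist(anchor, negative, eps)
    active = (margin + d_ap - d_an) > 0
    loss = float(np.maximum(margin + d_ap - d_an, 0.0).mean())
    n = len(anchor)
    w = active[:, None] / n
    u_ap = (anchor - positive) / d_ap[:, None]
    u_an = (anchor - negative) / d_an[:, None]
    da = w * (u_ap - u_an)
    dp = -w * u_ap
    dn = w * u_an
    return loss, (da.astype(DTYPE), dp.astype(DTYPE), dn.astype(DTYPE))


def hinge_pair_loss(anchor, positive, negative, margin=0.2):
    """Contrastive alternative: pull matching pairs together, push
    non-matching pairs apart beyond the margin.

    loss = mean d(a,p) + mean relu(margin - d(a,n)).
    """
    eps = 1e-9
    d_ap = _pairwise_dist(anchor, positive, eps)
    d_an = _pairwise_dist(anchor, negative, eps)
    active = (margin - d_an) > 0
    loss = float(d_ap.mean() + np.maximum(margin - d_an, 0.0).mean())
    n = len(anchor)
    u_ap = (anchor - positive) / d_ap[:, None]
    u_an = (anchor - negative) / d_an[:, None]
    da = u_ap / n - active[:, None] * u_an / n
    dp = -u_ap / n
    dn = active[:, None] * u_an / n
    return loss, (da.astype(DTYPE), dp.astype(DTYPE), dn.astype(DTYPE))
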