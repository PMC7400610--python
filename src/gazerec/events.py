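"""Fixation/saccade segmentation and eye-movement statistics.

Segmentation follows the velocity-based convention of commercial parsers:
angular velocity and acceleration are computed from the raw trace (boxcar
smoothing plus central differences) and a sample is saccadic when velocity
exceeds 30 deg/s or acceleration exceeds 8000 deg/s^2.  Maximal saccadic runs
become saccades; maximal non-saccadic valid runs of at least ``min_fix_ms``
become fixations; invalid (blink) runs, padded to absorb eyelid artefacts,
split any surrounding event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import Apparatus, GazeSequence, px_to_deg

__all__ = [
    "DetectorParams",
    "FixationEvent",
    "SaccadeEvent",
    "EventSet",
    "detect_events",
    "main_sequence",
    "spatial_coverage",
    "fraction_in_bounds",
    "duration_stats",
]


@dataclass(frozen=True)
class DetectorParams:
    vel_thresh_deg_s: float = 30.0
    acc_thresh_deg_s2: float = 8000.0
    min_fix_ms: int = 50
    smooth_half_width: int = 2  # samples, for both boxcar and central difference
    blink_pad_ms: int = 50

    def __post_init__(self) -> None:
        if self.vel_thresh_deg_s <= 0 or self.acc_thresh_deg_s2 <= 0:
            raise ValueError("thresholds must be strictly positive")


@dataclass(frozen=True)
class FixationEvent:
    onset_ms: int
    offset_ms: int
    x_px: float
    y_px: float

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: int
    offset_ms: int
    amplitude_deg: float
    peak_velocity_deg_s: float

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


@dataclass
class EventSet:
    subject_id: str
    image_id: str
    phase: str
    fixations: list[FixationEvent] = field(default_factory=list)
    saccades: list[SaccadeEvent] = field(default_factory=list)
    blink_windows: list[tuple[int, int]] = field(default_factory=list)
    warning: str | None = None


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs [i, j) where mask is True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, len(mask)]
    return list(zip(starts.tolist(), ends.tolist()))


def _smooth(v: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or len(v) < width:
        return v
    kernel = np.ones(width) / width
    out = np.convolve(v, kernel, mode="same")
    # shrink the kernel at the segment edges to avoid boundary bias
    half = width // 2
    for i in range(half):
        out[i] = v[: i + half + 1].mean()
        out[-(i + 1)] = v[-(i + half + 1):].mean()
    return out


def detect_events(
    seq: GazeSequence,
    params: DetectorParams | None = None,
    apparatus: Apparatus | None = None,
) -> EventSet:
    """Segment one gaze sequence into fixations, saccades and blink windows."""
    params = params or DetectorParams()
    apparatus = apparatus or Apparatus()
    es = EventSet(seq.subject_id, seq.image_id, seq.phase)

    if seq.valid.sum() < 2:
        es.warning = "fewer than 2 valid samples; no events detected"
        return es

    deg_x, deg_y = px_to_deg(apparatus)
    dt_s = 1.0 / seq.rate_hz
    h = max(1, params.smooth_half_width)
    pad = int(round(params.blink_pad_ms / 1000.0 * seq.rate_hz))

    # blocked = invalid runs padded by blink_pad_ms on each side
    blocked = ~seq.valid
    for i0, i1 in _runs(~seq.valid):
        blocked[max(0, i0 - pad): i1 + pad] = True
        es.blink_windows.append((int(seq.t_ms[i0]), int(seq.t_ms[i1 - 1])))

    t = seq.t_ms
    for s0, s1 in _runs(~blocked):
        if s1 - s0 < 2:
            continue
        xs = seq.x_px[s0:s1] * deg_x
        ys = seq.y_px[s0:s1] * deg_y
        xs = _smooth(xs, 2 * h + 1)
        ys = _smooth(ys, 2 * h + 1)
        n = s1 - s0
        idx = np.arange(n)
        lo = np.maximum(idx - h, 0)
        hi = np.minimum(idx + h, n - 1)
        span_s = (hi - lo) * dt_s
        with np.errstate(invalid="ignore", divide="ignore"):
            vx = (xs[hi] - xs[lo]) / span_s
            vy = (ys[hi] - ys[lo]) / span_s
        speed = np.hypot(vx, vy)
        acc = (speed[hi] - speed[lo]) / span_s
        saccadic = (speed > params.vel_thresh_deg_s) | (np.abs(acc) > params.acc_thresh_deg_s2)
        # close sub-fixation gaps: an interval too short to be a fixation
        # lying between two saccadic runs belongs to the same movement
        for r0, r1 in _runs(~saccadic):
            if r0 > 0 and r1 < n and t[s0 + r1 - 1] - t[s0 + r0] < params.min_fix_ms:
                saccadic[r0:r1] = True

        for r0, r1 in _runs(saccadic):
            g0, g1 = s0 + r0, s0 + r1
            pre = g0 - 1 if r0 > 0 else g0
            post = g1 if r1 < n else g1 - 1
            ax = (seq.x_px[post] - seq.x_px[pre]) * deg_x
            ay = (seq.y_px[post] - seq.y_px[pre]) * deg_y
            es.saccades.append(
                SaccadeEvent(
                    onset_ms=int(t[g0]),
                    offset_ms=int(t[g1 - 1]),
                    amplitude_deg=float(np.hypot(ax, ay)),
                    peak_velocity_deg_s=float(speed[r0:r1].max()),
                )
            )
        for r0, r1 in _runs(~saccadic):
            g0, g1 = s0 + r0, s0 + r1
            dur = int(t[g1 - 1] - t[g0])
            if dur < params.min_fix_ms:
                continue  # sub-threshold noise, belongs to no event
            es.fixations.append(
                FixationEvent(
                    onset_ms=int(t[g0]),
                    offset_ms=int(t[g1 - 1]),
                    x_px=float(seq.x_px[g0:g1].mean()),
                    y_px=float(seq.y_px[g0:g1].mean()),
                )
            )
    es.fixations.sort(key=lambda f: f.onset_ms)
    es.saccades.sort(key=lambda s: s.onset_ms)
    return es


def main_sequence(event_sets) -> pd.DataFrame:
    """One row per saccade: amplitude (deg), peak velocity (deg/s), phase.

    The amplitude/peak-velocity scatter is the main-sequence diagram used to
    compare encoding and recall saccade dynamics.
    """
    rows = [
        (e.subject_id, e.image_id, e.phase, s.amplitude_deg, s.peak_velocity_deg_s)
        for e in event_sets
        for s in e.saccades
    ]
    return pd.DataFrame(
        rows, columns=["subject", "image", "phase", "amplitude_deg", "peak_velocity_deg_s"]
    )


def spatial_coverage(events: EventSet, screen: tuple[int, int] = (1920, 1200)) -> float:
    """Percentage of screen area covered by the bounding box of fixation centroids."""
    if not events.fixations:
        raise ValueError("spatial coverage undefined for zero fixations")
    xs = np.array([f.x_px for f in events.fixations])
    ys = np.array([f.y_px for f in events.fixations])
    area = (xs.max() - xs.min()) * (ys.max() - ys.min())
    return 100.0 * area / (screen[0] * screen[1])


def fraction_in_bounds(events: EventSet, stimulus_rect: tuple[float, float, float, float]) -> float:
    """Fraction of fixation centroids inside the closed rectangle (x0, y0, x1, y1)."""
    if not events.fixations:
        raise ValueError("fraction_in_bounds undefined for zero fixations")
    x0, y0, x1, y1 = stimulus_rect
    inside = [
        (x0 <= f.x_px <= x1) and (y0 <= f.y_px <= y1) for f in events.fixations
    ]
    return float(np.mean(inside))


def duration_stats(event_sets) -> dict:
    """Per-phase fixation count/duration summaries and phase comparisons.

    Fixation durations are compared between encoding and recall with a Welch
    t-test (unequal variances, Welch-Satterthwaite df) and a two-sided
    Mann-Whitney U; fixation counts per trial with the same Welch t.
    """
    per_phase: dict[str, dict] = {}
    durations: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for phase in ("encoding", "recall"):
        sets = [e for e in event_sets if e.phase == phase]
        if not sets:
            continue
        durs = np.array([f.duration_ms for e in sets for f in e.fixations], dtype=float)
        cnts = np.array([len(e.fixations) for e in sets], dtype=float)
        if len(durs) < 2:
            raise ValueError(f"phase {phase!r} has fewer than 2 fixations")
        durations[phase] = durs
        counts[phase] = cnts
        per_phase[phase] = {
            "n_trials": len(sets),
            "fix_count_mean": float(cnts.mean()),
            "fix_count_sd": float(cnts.std(ddof=1)) if len(cnts) > 1 else float("nan"),
            "fix_dur_mean_ms": float(durs.mean()),
            "fix_dur_sd_ms": float(durs.std(ddof=1)),
        }
    out = {"per_phase": per_phase}
    if len(per_phase) == 2:
        t_dur = stats.ttest_ind(durations["encoding"], durations["recall"], equal_var=False)
        u_dur = stats.mannwhitneyu(
            durations["encoding"], durations["recall"], alternative="two-sided", method="asymptotic"
        )
        t_cnt = stats.ttest_ind(counts["encoding"], counts["recall"], equal_var=False)
        out["duration_welch"] = {
            "t": float(t_dur.statistic), "df": float(t_dur.df), "p": float(t_dur.pvalue)
        }
        out["duration_mannwhitney"] = {"U": float(u_dur.statistic), "p": float(u_dur.pvalue)}
        out["count_welch"] = {
            "t": float(t_cnt.statistic), "df": float(t_cnt.df), "p": float(t_cnt.pvalue)
        }
    return out
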