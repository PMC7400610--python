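"""Synthetic looking-at-nothing gaze generator.

Emulates the statistical structure of a gaze-based image-retrieval study:

* **encoding** trials — 5 s of viewing an image; fixation locations are drawn
  from an image-specific saliency model (a small Gaussian mixture standing in
  for stimulus-driven attention), with about 16 fixations of about 278 ms.
* **recall** trials — 5 s of mental imagery on a blank screen; fixation
  locations revisit a random subset of the encoding locations, but through a
  per-trial similarity transform (shrinkage toward the screen centre plus a
  random translation) and per-fixation jitter, with about 11 longer
  (about 452 ms) fixations.  Sequence order is not preserved.

Raw 1000 Hz samples are rendered from the planted fixation plan: Gaussian
tremor during fixations and smooth saccadic transitions whose peak velocity
follows the saturating main-sequence law ``V_peak = V_max (1 - exp(-A/A_0))``.
Blinks appear as windows of invalid samples.  Every trial also returns the
planted ground truth so that detectors and distortion estimators can be
tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import Apparatus, GazeSequence, TrialSet, px_to_deg

__all__ = [
    "ImageModel",
    "SimConfig",
    "GroundTruth",
    "SimulationError",
    "make_image_models",
    "simulate_encoding_trial",
    "simulate_recall_trial",
    "simulate_study",
]


class SimulationError(RuntimeError):
    """Raised when a trial cannot be realised (e.g. infeasible time budget)."""


@dataclass(frozen=True)
class ImageModel:
    """Saliency stand-in for one image: a K-component bivariate Gaussian mixture.

    ``means`` is (K, 2) in screen pixels, ``covs`` is (K, 2, 2), ``weights``
    sums to one.
    """

    image_id: str
    means: np.ndarray
    covs: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("mixture weights must be positive and sum to 1")
        if not (2 <= len(w) <= 6):
            raise ValueError("mixture must have between 2 and 6 components")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n fixation locations (px) from the mixture."""
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        out = np.empty((n, 2))
        for k in np.unique(comp):
            idx = comp == k
            out[idx] = rng.multivariate_normal(
                self.means[k], self.covs[k], size=int(idx.sum()), method="cholesky"
            )
        return out


@dataclass
class SimConfig:
    """Stated world of the simulated study.

    Count/duration laws are (mean, sd) of rounded/truncated normals; the
    defaults reproduce the study design (28 subjects x 100 images, 5 s trials
    at 1000 Hz) and its published eye-movement statistics: encoding trials
    with 16 (SD 2.8) fixations of 278.0 (SD 73.4) ms, recall trials with
    11 (SD 3.6) fixations of 452.2 (SD 308.0) ms, and recall shrinkage of the
    covered area toward screen centre.
    """

    n_subjects: int = 28
    n_images: int = 100
    trial_ms: int = 5000
    rate_hz: float = 1000.0
    enc_fix_count: tuple[float, float] = (16.0, 2.8)
    enc_fix_dur_ms: tuple[float, float] = (278.0, 73.4)
    rec_fix_count: tuple[float, float] = (11.0, 3.6)
    rec_fix_dur_ms: tuple[float, float] = (452.2, 308.0)
    shrink_range: tuple[float, float] = (0.5, 0.95)
    translate_sd_px: float = 60.0
    jitter_sd_px: float = 25.0
    blink_rate_per_trial: float = 0.6
    blink_dur_ms: tuple[float, float] = (150.0, 50.0)
    # main-sequence rendering
    v_max_deg_s: float = 500.0
    a0_deg: float = 8.0
    tremor_sd_deg: float = 0.1
    min_fix_dur_ms: float = 50.0
    # minimum distance between consecutive planted encoding fixations; jumps
    # smaller than this would be microsaccades, which the fixation plan folds
    # into a single longer fixation rather than planting as separate events
    min_sacc_amp_px: float = 30.0
    # per-subject multiplier range on the drawn shrink factor ("imagery style")
    subject_style_range: tuple[float, float] = (0.85, 1.15)
    n_clone_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_images < 1:
            raise ValueError("n_subjects and n_images must be >= 1")
        lo, hi = self.shrink_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("shrink_range must be a sub-interval of (0, 1]")
        for name in ("enc_fix_count", "enc_fix_dur_ms", "rec_fix_count", "rec_fix_dur_ms",
                     "blink_dur_ms"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} sd must be >= 0")
        if self.translate_sd_px < 0 or self.jitter_sd_px < 0 or self.tremor_sd_deg < 0:
            raise ValueError("noise scales must be >= 0")


@dataclass
class GroundTruth:
    """Planted parameters of one simulated trial.

    ``fix_xy`` are the rendered (clipped, pre-tremor) fixation centres;
    for recall trials ``scale``/``translation`` hold the similarity transform
    applied to the encoding locations and ``source_indices`` which encoding
    fixations were revisited.
    """

    subject_id: str
    image_id: str
    phase: str
    fix_xy: np.ndarray          # (n_fix, 2) px
    fix_onset_ms: np.ndarray    # (n_fix,)
    fix_dur_ms: np.ndarray      # (n_fix,)
    blink_windows: list[tuple[float, float]] = field(default_factory=list)
    scale: float | None = None
    translation: tuple[float, float] | None = None
    source_indices: np.ndarray | None = None

    @property
    def n_fixations(self) -> int:
        return len(self.fix_xy)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("fix_xy", "fix_onset_ms", "fix_dur_ms", "source_indices"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        return d


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_image_models(
    n_images: int,
    screen: tuple[int, int] = (1920, 1200),
    seed: int | np.random.Generator = 0,
    n_clone_pairs: int = 0,
    clone_shift_px: float = 30.0,
) -> list[ImageModel]:
    """Draw independent saliency mixtures for ``n_images`` images.

    If ``n_clone_pairs`` > 0, the last ``n_clone_pairs`` images are near
    clones of the first ``n_clone_pairs`` (means perturbed by
    ``clone_shift_px``), producing deliberately confusable image pairs.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if 2 * n_clone_pairs > n_images:
        raise ValueError("too many clone pairs for n_images")
    rng = _as_rng(seed)
    W, H = screen
    models: list[ImageModel] = []
    for i in range(n_images - n_clone_pairs):
        K = int(rng.integers(2, 7))
        # keep means away from the border so most fixations land on screen
        means = np.column_stack(
            [rng.uniform(0.15 * W, 0.85 * W, K), rng.uniform(0.15 * H, 0.85 * H, K)]
        )
        sds = rng.uniform(0.02, 0.08, (K, 2)) * np.array([W, H])
        covs = np.zeros((K, 2, 2))
        covs[:, 0, 0] = sds[:, 0] ** 2
        covs[:, 1, 1] = sds[:, 1] ** 2
        w = rng.dirichlet(np.full(K, 2.0))
        w = np.clip(w, 0.05, None)
        w = w / w.sum()
        models.append(ImageModel(f"img{i:03d}", means, covs, w))
    for j in range(n_clone_pairs):
        src = models[j]
        i = n_images - n_clone_pairs + j
        shift = rng.normal(0.0, clone_shift_px, size=src.means.shape)
        means = np.clip(src.means + shift, [0, 0], [W - 1, H - 1])
        models.append(ImageModel(f"img{i:03d}", means, src.covs.copy(), src.weights.copy()))
    return models


def _truncated_normal(rng, mean, sd, low, size):
    x = rng.normal(mean, sd, size)
    return np.maximum(x, low)


def _plan_trial(fix_xy, mean_sd_dur, cfg: SimConfig, apparatus: Apparatus, rng):
    """Assign fixation and saccade durations so the plan fills trial_ms exactly.

    Saccade durations follow from the main-sequence law with a raised-cosine
    velocity profile (duration = 2A / V_peak); fixation durations are drawn
    from the phase's duration law, floored at min_fix_dur_ms, and rescaled to
    fit the remaining budget.
    """
    n = len(fix_xy)
    dx, dy = px_to_deg(apparatus)
    deltas = np.diff(fix_xy, axis=0)
    amp_deg = np.hypot(deltas[:, 0] * dx, deltas[:, 1] * dy)
    v_peak = cfg.v_max_deg_s * (1.0 - np.exp(-amp_deg / cfg.a0_deg))
    with np.errstate(divide="ignore", invalid="ignore"):
        sacc_ms = np.where(v_peak > 0, 2.0 * amp_deg / v_peak * 1000.0, 0.0)
    sacc_ms = np.maximum(sacc_ms, 6.0)  # >= a few samples even for tiny jumps

    budget = cfg.trial_ms - sacc_ms.sum()
    if budget < n * cfg.min_fix_dur_ms:
        raise SimulationError(
            f"trial budget infeasible: {n} fixations x {cfg.min_fix_dur_ms} ms minimum "
            f"exceeds {budget:.0f} ms left after saccades"
        )
    fix_ms = _truncated_normal(rng, mean_sd_dur[0], mean_sd_dur[1], cfg.min_fix_dur_ms, n)
    # renormalise to fill the budget exactly, respecting the floor
    for _ in range(8):
        free = fix_ms > cfg.min_fix_dur_ms
        fixed_total = fix_ms[~free].sum()
        if not free.any():
            fix_ms = np.full(n, budget / n)
            break
        scale = (budget - fixed_total) / fix_ms[free].sum()
        fix_ms = np.where(free, fix_ms * scale, fix_ms)
        if np.all(fix_ms >= cfg.min_fix_dur_ms - 1e-9):
            break
        fix_ms = np.maximum(fix_ms, cfg.min_fix_dur_ms)
    return fix_ms, sacc_ms, amp_deg


def _render(fix_xy, fix_ms, sacc_ms, cfg: SimConfig, apparatus: Apparatus, rng,
            subject_id: str, image_id: str, phase: str):
    """Render a fixation/saccade plan into raw samples plus ground truth."""
    W, H = apparatus.screen_w_px, apparatus.screen_h_px
    n_samples = int(round(cfg.trial_ms * cfg.rate_hz / 1000.0))
    dt_ms = 1000.0 / cfg.rate_hz
    t = np.arange(n_samples) * dt_ms

    x = np.empty(n_samples)
    y = np.empty(n_samples)
    onset = np.empty(len(fix_xy))
    cursor = 0.0
    dx_deg, _ = px_to_deg(apparatus)
    tremor_px = cfg.tremor_sd_deg / dx_deg if cfg.tremor_sd_deg > 0 else 0.0

    for i, (px, py) in enumerate(fix_xy):
        onset[i] = cursor
        end = cursor + fix_ms[i]
        if i == len(fix_xy) - 1:
            end = cfg.trial_ms  # absorb float residue
        sl = slice(*np.searchsorted(t, [cursor, end]))
        m = sl.stop - sl.start
        x[sl] = px + _colored_noise(m, rng, tremor_px)
        y[sl] = py + _colored_noise(m, rng, tremor_px)
        cursor = end
        if i < len(fix_xy) - 1:
            end = cursor + sacc_ms[i]
            sl = slice(*np.searchsorted(t, [cursor, end]))
            u = (t[sl] - cursor) / sacc_ms[i]
            # raised-cosine velocity profile: progress u - sin(2 pi u)/(2 pi)
            s = u - np.sin(2 * np.pi * u) / (2 * np.pi)
            x[sl] = px + (fix_xy[i + 1, 0] - px) * s
            y[sl] = py + (fix_xy[i + 1, 1] - py) * s
            cursor = end

    np.clip(x, 0, W - 1, out=x)
    np.clip(y, 0, H - 1, out=y)

    valid = np.ones(n_samples, dtype=bool)
    blink_windows: list[tuple[float, float]] = []
    n_blinks = rng.poisson(cfg.blink_rate_per_trial)
    for _ in range(n_blinks):
        dur = max(float(rng.normal(*cfg.blink_dur_ms)), dt_ms)
        start = float(rng.uniform(0, max(cfg.trial_ms - dur, 0)))
        blink_windows.append((start, start + dur))
        sl = slice(*np.searchsorted(t, [start, start + dur]))
        valid[sl] = False
    x[~valid] = np.nan
    y[~valid] = np.nan

    seq = GazeSequence(
        subject_id=subject_id, image_id=image_id, phase=phase,
        t_ms=np.round(t).astype(np.int64), x_px=x, y_px=y, valid=valid,
        rate_hz=cfg.rate_hz, screen_w_px=W, screen_h_px=H,
    )
    truth = GroundTruth(
        subject_id=subject_id, image_id=image_id, phase=phase,
        fix_xy=np.asarray(fix_xy, dtype=float), fix_onset_ms=onset,
        fix_dur_ms=np.asarray(fix_ms, dtype=float), blink_windows=blink_windows,
    )
    return seq, truth


def _colored_noise(n: int, rng, sd: float, corr_samples: float = 20.0) -> np.ndarray:
    """Slow fixational drift: Gaussian noise with marginal sd ``sd`` and
    correlation time ``corr_samples``, so sample-to-sample velocity stays far
    below saccade-detection thresholds."""
    if n == 0 or sd == 0:
        return np.zeros(n)
    half = int(4 * corr_samples)
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / corr_samples) ** 2)
    k /= k.sum()
    w = rng.normal(0.0, 1.0, n + 2 * half)
    smoothed = np.convolve(w, k, mode="valid")[:n]
    return smoothed * (sd / np.sqrt((k**2).sum()))


def _draw_count(rng, mean_sd, n_min=2) -> int:
    return int(max(n_min, round(rng.normal(*mean_sd))))


def simulate_encoding_trial(
    model: ImageModel,
    cfg: SimConfig,
    subject_seed,
    subject_id: str = "s00",
    apparatus: Apparatus | None = None,
) -> tuple[GazeSequence, GroundTruth]:
    """Simulate one 5 s encoding trial on ``model``'s image."""
    rng = _as_rng(subject_seed)
    app = apparatus or Apparatus()
    W, H = app.screen_w_px, app.screen_h_px
    n_fix = _draw_count(rng, cfg.enc_fix_count)
    fix_xy = np.clip(model.sample(n_fix, rng), [0, 0], [W - 1, H - 1])
    # enforce a minimum saccade amplitude between consecutive fixations
    for i in range(1, n_fix):
        for _ in range(25):
            if np.hypot(*(fix_xy[i] - fix_xy[i - 1])) >= cfg.min_sacc_amp_px:
                break
            fix_xy[i] = np.clip(model.sample(1, rng)[0], [0, 0], [W - 1, H - 1])
    fix_ms, sacc_ms, _ = _plan_trial(fix_xy, cfg.enc_fix_dur_ms, cfg, app, rng)
    return _render(fix_xy, fix_ms, sacc_ms, cfg, app, rng, subject_id, model.image_id, "encoding")


def simulate_recall_trial(
    enc_truth: GroundTruth,
    cfg: SimConfig,
    subject_seed,
    apparatus: Apparatus | None = None,
    subject_style: float = 1.0,
) -> tuple[GazeSequence, GroundTruth]:
    """Simulate the recall trial matched to an encoding trial.

    Revisits a random subset of the encoding fixation locations through the
    per-trial similarity transform ``x -> s (x - c) + c + tau`` (c the screen
    centre, s uniform on ``shrink_range`` scaled by the subject's imagery
    style, tau Gaussian translation), plus per-fixation jitter.
    """
    rng = _as_rng(subject_seed)
    app = apparatus or Apparatus()
    W, H = app.screen_w_px, app.screen_h_px
    n_enc = enc_truth.n_fixations
    n_rec = _draw_count(rng, cfg.rec_fix_count)
    if n_rec <= n_enc:
        src = rng.choice(n_enc, size=n_rec, replace=False)
    else:
        src = rng.choice(n_enc, size=n_rec, replace=True)
    s = float(rng.uniform(*cfg.shrink_range)) * subject_style
    s = float(np.clip(s, 1e-3, 1.0))
    tau = rng.normal(0.0, cfg.translate_sd_px, 2)
    c = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    base = enc_truth.fix_xy[src]
    fix_xy = s * (base - c) + c + tau
    if cfg.jitter_sd_px > 0:
        fix_xy = fix_xy + rng.normal(0.0, cfg.jitter_sd_px, fix_xy.shape)
    fix_xy = np.clip(fix_xy, [0, 0], [W - 1, H - 1])
    fix_ms, sacc_ms, _ = _plan_trial(fix_xy, cfg.rec_fix_dur_ms, cfg, app, rng)
    seq, truth = _render(fix_xy, fix_ms, sacc_ms, cfg, app, rng,
                         enc_truth.subject_id, enc_truth.image_id, "recall")
    truth.scale = s
    truth.translation = (float(tau[0]), float(tau[1]))
    truth.source_indices = src
    return seq, truth


def simulate_study(
    cfg: SimConfig,
    apparatus: Apparatus | None = None,
    image_models: list[ImageModel] | None = None,
) -> tuple[TrialSet, dict[tuple[str, str, str], GroundTruth]]:
    """Simulate the full study design: every subject encodes and recalls every image.

    Deterministic given ``cfg.seed``: per-trial generators are spawned from a
    single SeedSequence, so the same config yields byte-identical trials.
    """
    app = apparatus or Apparatus()
    root = np.random.SeedSequence(cfg.seed)
    model_ss, style_ss, trial_ss = root.spawn(3)
    if image_models is None:
        image_models = make_image_models(
            cfg.n_images, (app.screen_w_px, app.screen_h_px),
            np.random.default_rng(model_ss), cfg.n_clone_pairs,
        )
    style_rng = np.random.default_rng(style_ss)
    styles = style_rng.uniform(*cfg.subject_style_range, cfg.n_subjects)

    sequences = []
    truths: dict[tuple[str, str, str], GroundTruth] = {}
    trial_seeds = trial_ss.spawn(cfg.n_subjects * cfg.n_images)
    k = 0
    for si in range(cfg.n_subjects):
        subject = f"s{si:02d}"
        for model in image_models:
            rng = np.random.default_rng(trial_seeds[k])
            k += 1
            enc_seq, enc_truth = simulate_encoding_trial(model, cfg, rng, subject, app)
            rec_seq, rec_truth = simulate_recall_trial(
                enc_truth, cfg, rng, app, subject_style=float(styles[si])
            )
            sequences.extend([enc_seq, rec_seq])
            truths[enc_seq.key] = enc_truth
            truths[rec_seq.key] = rec_truth
    return TrialSet(sequences=sequences, apparatus=app), truths
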