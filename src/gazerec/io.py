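"""Data model and file formats for raw gaze recordings.

The package works on per-trial gaze sequences: 1000 Hz samples of on-screen
pixel position for one subject viewing (``encoding``) or mentally recalling
(``recall``) one image.  Samples recorded during blinks or track loss are
flagged invalid and carry no position.  Trials are exchanged as a plain CSV
dialect (one row per sample) so fixtures stay diffable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Apparatus",
    "GazeSequence",
    "TrialSet",
    "GazeFormatError",
    "GazeValidationError",
    "read_trials",
    "write_trials",
    "px_to_deg",
]

#: Canonical column order of the gaze CSV dialect.
CSV_COLUMNS = ["subject", "image", "phase", "t_ms", "x_px", "y_px", "valid"]

PHASES = ("encoding", "recall")


class GazeFormatError(ValueError):
    """Raised when a gaze CSV file does not follow the documented dialect."""


class GazeValidationError(ValueError):
    """Raised when gaze data violates a structural invariant (e.g. duplicate
    or non-monotone timestamps within a trial)."""


@dataclass(frozen=True)
class Apparatus:
    """Physical recording geometry used for pixel-to-degree conversion.

    Defaults describe a 0.52 m x 0.32 m display at 1920 x 1200 px viewed
    from 0.7 m.
    """

    screen_w_m: float = 0.52
    screen_h_m: float = 0.32
    distance_m: float = 0.7
    screen_w_px: int = 1920
    screen_h_px: int = 1200

    def __post_init__(self) -> None:
        for name in ("screen_w_m", "screen_h_m", "distance_m", "screen_w_px", "screen_h_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Apparatus.{name} must be strictly positive")


@dataclass
class GazeSequence:
    """Time-ordered raw samples of one trial (one subject, image, phase).

    ``x_px``/``y_px`` are NaN wherever ``valid`` is False; invalid positions
    must never enter any computation.
    """

    subject_id: str
    image_id: str
    phase: str
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    rate_hz: float = 1000.0
    screen_w_px: int = 1920
    screen_h_px: int = 1200

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=np.int64)
        self.x_px = np.asarray(self.x_px, dtype=np.float64)
        self.y_px = np.asarray(self.y_px, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise GazeValidationError("sample arrays must have equal length")
        if self.phase not in PHASES:
            raise GazeValidationError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if n and self.t_ms[0] < 0:
            raise GazeValidationError("timestamps must be non-negative")
        if n > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise GazeValidationError(
                f"non-monotone timestamps in trial "
                f"({self.subject_id}, {self.image_id}, {self.phase})"
            )
        if np.any(~np.isfinite(self.x_px[self.valid])) or np.any(
            ~np.isfinite(self.y_px[self.valid])
        ):
            raise GazeValidationError("valid samples must have finite positions")

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.image_id, self.phase)

    @property
    def duration_ms(self) -> int:
        return int(self.t_ms[-1] - self.t_ms[0]) if len(self) else 0

    def valid_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Positions of valid samples only."""
        return self.x_px[self.valid], self.y_px[self.valid]


@dataclass
class TrialSet:
    """Collection of gaze sequences with the apparatus they were recorded on."""

    sequences: list[GazeSequence] = field(default_factory=list)
    apparatus: Apparatus = field(default_factory=Apparatus)

    def __post_init__(self) -> None:
        keys = [s.key for s in self.sequences]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, str, str]] = set()
            for k in keys:
                if k in seen:
                    raise GazeValidationError(f"duplicate trial {k}")
                seen.add(k)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[GazeSequence]:
        return iter(self.sequences)

    def subjects(self) -> list[str]:
        return sorted({s.subject_id for s in self.sequences})

    def images(self) -> list[str]:
        return sorted({s.image_id for s in self.sequences})

    def select(self, phase: str | None = None, subject_id: str | None = None) -> list[GazeSequence]:
        out = self.sequences
        if phase is not None:
            out = [s for s in out if s.phase == phase]
        if subject_id is not None:
            out = [s for s in out if s.subject_id == subject_id]
        return out


def px_to_deg(apparatus: Apparatus) -> tuple[float, float]:
    """Per-axis conversion factors from screen pixels to degrees of visual angle.

    Uses the small-angle (one-pixel-pitch) arctangent at screen distance; the
    factor is treated as constant over the screen.  The error of this
    approximation at the screen edge is below 3 % for the default geometry.

    Returns
    -------
    (deg_per_px_x, deg_per_px_y)
    """
    pitch_x = apparatus.screen_w_m / apparatus.screen_w_px
    pitch_y = apparatus.screen_h_m / apparatus.screen_h_px
    deg_x = math.degrees(math.atan(pitch_x / apparatus.distance_m))
    deg_y = math.degrees(math.atan(pitch_y / apparatus.distance_m))
    return deg_x, deg_y


def _sequences_to_frame(sequences: Iterable[GazeSequence]) -> pd.DataFrame:
    frames = []
    for s in sequences:
        frames.append(
            pd.DataFrame(
                {
                    "subject": s.subject_id,
                    "image": s.image_id,
                    "phase": s.phase,
                    "t_ms": s.t_ms,
                    "x_px": s.x_px,
                    "y_px": s.y_px,
                    "valid": s.valid.astype(int),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=CSV_COLUMNS)
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["subject", "image", "phase", "t_ms"], kind="stable").reset_index(
        drop=True
    )


def write_trials(trials: TrialSet, path) -> str:
    """Write a TrialSet to the gaze CSV dialect.

    One row per sample, sorted by (subject, image, phase, t_ms).  Invalid
    samples leave the position fields empty.
    """
    df = _sequences_to_frame(trials.sequences)
    # Empty position fields for invalid samples; fixed decimal formatting so
    # that write -> read -> write is byte-identical.
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            if row.valid:
                x, y = f"{row.x_px:.3f}", f"{row.y_px:.3f}"
            else:
                x, y = "", ""
            fh.write(f"{row.subject},{row.image},{row.phase},{row.t_ms},{x},{y},{row.valid}\n")
    return str(path)


def read_trials(path, apparatus: Apparatus | None = None) -> TrialSet:
    """Read a gaze CSV file into a TrialSet.

    Raises
    ------
    GazeFormatError
        If the header does not match the documented dialect.
    GazeValidationError
        If timestamps within a trial are duplicated or non-monotone.
    """
    try:
        df = pd.read_csv(
            path,
            dtype={"subject": str, "image": str, "phase": str},
            keep_default_na=False,
            na_values=[""],
        )
    except pd.errors.EmptyDataError as exc:
        raise GazeFormatError(f"{path}: empty file, missing header") from exc
    if list(df.columns) != CSV_COLUMNS:
        raise GazeFormatError(
            f"{path}: expected header {','.join(CSV_COLUMNS)}, got {','.join(map(str, df.columns))}"
        )
    bad_t = pd.to_numeric(df["t_ms"], errors="coerce").isna()
    bad_v = pd.to_numeric(df["valid"], errors="coerce").isna()
    bad = bad_t | bad_v
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise GazeFormatError(f"{path}: malformed rows at lines {lines[:20]}")
    df["t_ms"] = df["t_ms"].astype(np.int64)
    df["valid"] = df["valid"].astype(int).astype(bool)

    sequences = []
    for (subject, image, phase), g in df.groupby(["subject", "image", "phase"], sort=True):
        g = g.sort_values("t_ms", kind="stable")
        if g["t_ms"].duplicated().any():
            raise GazeValidationError(
                f"{path}: duplicated timestamp in trial ({subject}, {image}, {phase})"
            )
        sequences.append(
            GazeSequence(
                subject_id=subject,
                image_id=image,
                phase=phase,
                t_ms=g["t_ms"].to_numpy(),
                x_px=g["x_px"].to_numpy(dtype=float),
                y_px=g["y_px"].to_numpy(dtype=float),
                valid=g["valid"].to_numpy(),
            )
        )
    return TrialSet(sequences=sequences, apparatus=apparatus or Apparatus())
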