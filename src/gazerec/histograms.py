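"""Gaze-density histograms: the representation all retrieval operates on.

The screen is divided into a regular G x G grid (default 24 x 24) and the
raw valid samples of one trial are counted per cell, so cell mass encodes
dwell time; the temporal order of samples is deliberately discarded.
Variants: a binary visited-cell map, a G x G x T spatiotemporal stack, and a
displacement histogram of consecutive-sample motion vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GazeSequence

__all__ = [
    "GazeHistogram",
    "build_histogram",
    "binary_histogram",
    "spatiotemporal_histogram",
    "displacement_histogram",
    "write_histograms",
    "read_histograms",
]


@dataclass
class GazeHistogram:
    """G x G gaze-density grid for one trial.

    ``grid[row, col]`` indexes y (row) then x (col).  In count mode entries
    are integer sample counts; normalized grids sum to 1 unless all-zero.
    ``discarded`` counts valid samples that fell outside the screen.
    """

    grid: np.ndarray
    subject_id: str
    image_id: str
    phase: str
    total_samples: int
    normalized: bool
    discarded: int = 0
    warning: str | None = None

    @property
    def G(self) -> int:
        return self.grid.shape[0]

    def flatten(self) -> np.ndarray:
        return self.grid.ravel()


def _cell_indices(x, y, W, H, G):
    """Half-open cells [low, high); the terminal screen edge maps into the
    last cell so border samples are not lost."""
    gx = np.floor(x / (W / G)).astype(int)
    gy = np.floor(y / (H / G)).astype(int)
    gx[gx == G] = G - 1
    gy[gy == G] = G - 1
    inb = (gx >= 0) & (gx < G) & (gy >= 0) & (gy < G)
    return gx, gy, inb


def build_histogram(seq: GazeSequence, G: int = 24, normalize: bool = False) -> GazeHistogram:
    """Aggregate one trial's valid raw samples into a G x G count grid."""
    if G < 2:
        raise ValueError("G must be >= 2")
    x, y = seq.valid_xy()
    W, H = seq.screen_w_px, seq.screen_h_px
    grid = np.zeros((G, G))
    warning = None
    if len(x) == 0:
        warning = "no valid samples; all-zero histogram"
        discarded = 0
    else:
        gx, gy, inb = _cell_indices(x, y, W, H, G)
        np.add.at(grid, (gy[inb], gx[inb]), 1.0)
        discarded = int((~inb).sum())
    total = int(grid.sum())
    if normalize and total > 0:
        grid = grid / grid.sum()
    return GazeHistogram(
        grid=grid, subject_id=seq.subject_id, image_id=seq.image_id, phase=seq.phase,
        total_samples=total, normalized=normalize and total > 0, discarded=discarded,
        warning=warning,
    )


def binary_histogram(h: GazeHistogram) -> GazeHistogram:
    """Visited-cell map: 1 where any sample landed, 0 elsewhere (drops dwell time)."""
    if h.normalized:
        raise ValueError("binary_histogram expects a count-mode histogram")
    return GazeHistogram(
        grid=(h.grid > 0).astype(float), subject_id=h.subject_id, image_id=h.image_id,
        phase=h.phase, total_samples=h.total_samples, normalized=False,
        discarded=h.discarded, warning=h.warning,
    )


def spatiotemporal_histogram(seq: GazeSequence, G: int = 24, T: int = 5) -> np.ndarray:
    """G x G x T stack of per-time-bin spatial histograms.

    Time bins split the trial span [t_first, t_last] into T equal intervals;
    summing over the last axis reproduces ``build_histogram`` exactly.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if G < 2:
        raise ValueError("G must be >= 2")
    out = np.zeros((G, G, T))
    m = seq.valid
    if not m.any():
        return out
    t = seq.t_ms[m].astype(float)
    x, y = seq.x_px[m], seq.y_px[m]
    t0, t1 = float(seq.t_ms[0]), float(seq.t_ms[-1])
    span = max(t1 - t0, 1.0)
    tb = np.minimum((T * (t - t0) / span).astype(int), T - 1)
    gx, gy, inb = _cell_indices(x, y, seq.screen_w_px, seq.screen_h_px, G)
    np.add.at(out, (gy[inb], gx[inb], tb[inb]), 1.0)
    return out


def displacement_histogram(
    seq: GazeSequence, G: int = 24, bin_px: float | None = None
) -> np.ndarray:
    """Positional histogram concatenated with a consecutive-sample displacement
    histogram, shape (2, G, G).

    Displacements (dx, dy) between consecutive valid samples are binned on a
    centred G x G grid with bin width ``bin_px`` (default: screen width / G,
    matching the positional cell size); out-of-range displacements clamp to
    the border cells.  A zero displacement falls in the central cell.
    """
    if seq.valid.sum() < 2:
        raise ValueError("displacement histogram needs >= 2 valid samples")
    pos = build_histogram(seq, G).grid
    x, y = seq.valid_xy()
    dxs, dys = np.diff(x), np.diff(y)
    if bin_px is None:
        bin_px = seq.screen_w_px / G
    c = G // 2
    gx = np.clip(np.floor(dxs / bin_px + 0.5).astype(int) + c, 0, G - 1)
    gy = np.clip(np.floor(dys / bin_px + 0.5).astype(int) + c, 0, G - 1)
    disp = np.zeros((G, G))
    np.add.at(disp, (gy, gx), 1.0)
    return np.stack([pos, disp])


def write_histograms(hists: list[GazeHistogram], path) -> str:
    """Write histograms to one TSV: metadata columns followed by the G*G
    flattened grid (row-major, y-row then x-column)."""
    import pandas as pd

    if not hists:
        raise ValueError("nothing to write")
    G = hists[0].G
    rows = []
    for h in hists:
        if h.G != G:
            raise ValueError("mixed grid sizes")
        rows.append([h.subject_id, h.image_id, h.phase, G, int(h.normalized),
                     h.total_samples, h.discarded, *h.grid.ravel()])
    cols = ["subject", "image", "phase", "G", "normalized", "total_samples",
            "discarded"] + [f"c{i}" for i in range(G * G)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return str(path)


def read_histograms(path) -> list[GazeHistogram]:
    """Inverse of :func:`write_histograms`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "image": str})
    out = []
    for _, r in df.iterrows():
        G = int(r["G"])
        grid = r[[f"c{i}" for i in range(G * G)]].to_numpy(dtype=float).reshape(G, G)
        out.append(GazeHistogram(
            grid=grid, subject_id=r["subject"], image_id=r["image"], phase=r["phase"],
            total_samples=int(r["total_samples"]), normalized=bool(r["normalized"]),
            discarded=int(r["discarded"]),
        ))
    return out
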