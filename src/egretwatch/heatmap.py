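"""Spatio-temporal occupancy fields on a 200-px cell grid.

Per-frame detection counts are binned to cells, smoothed spatially with an
exponential distance kernel,

    x[t, i, k] = sum_j exp(-beta * d(p_i, p_j)) * c[t, j, k],

then smoothed in time recursively,

    s[t] = lam * x[t] + (1 - lam) * s[t-1],

and finally averaged over a period for rendering.  The spatial sum runs
over the *source* cell j; as printed elsewhere the summand is constant in
j, which would make the kernel irrelevant, so the source-cell reading is
used.  Distances are in pixels between cell centres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellGrid",
    "assign_counts",
    "counts_over_time",
    "spatial_smooth",
    "temporal_smooth",
    "period_heatmap",
    "render",
]

DEFAULT_BETA = 0.01  # px^-1
DEFAULT_LAMBDA = 0.1


@dataclass
class CellGrid:
    """Tiling of the frame into ``cell_size`` squares (last row/col partial)."""

    frame_width: int
    frame_height: int
    cell_size: int = 200

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.n_rows = int(np.ceil(self.frame_height / self.cell_size))
        self.n_cols = int(np.ceil(self.frame_width / self.cell_size))
        rows = np.arange(self.n_rows)
        cols = np.arange(self.n_cols)
        cy = (rows * self.cell_size + np.minimum((rows + 1) * self.cell_size,
                                                 self.frame_height)) / 2.0
        cx = (cols * self.cell_size + np.minimum((cols + 1) * self.cell_size,
                                                 self.frame_width)) / 2.0
        self.centers_y, self.centers_x = cy, cx

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances between cell centres (flattened order)."""
        gy, gx = np.meshgrid(self.centers_y, self.centers_x, indexing="ij")
        pts = np.column_stack([gy.ravel(), gx.ravel()])
        diff = pts[:, None, :] - pts[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell (row, col) containing pixel (x, y); cells are half-open."""
        return (
            min(int(y // self.cell_size), self.n_rows - 1),
            min(int(x // self.cell_size), self.n_cols - 1),
        )


def assign_counts(
    records_at_t: pd.DataFrame, grid: CellGrid, species: str | None = None
) -> np.ndarray:
    """Bin detections of one frame to cells by box centre.

    Returns an ``(n_rows, n_cols)`` integer array whose total equals the
    number of assigned detections.
    """
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    sel = records_at_t
    if species is not None:
        sel = sel[sel["species"] == species]
    cx = (sel["x_min"].to_numpy() + sel["x_max"].to_numpy()) / 2.0
    cy = (sel["y_min"].to_numpy() + sel["y_max"].to_numpy()) / 2.0
    for x, y in zip(cx, cy):
        r, c = grid.cell_of(x, y)
        counts[r, c] += 1
    return counts


def counts_over_time(
    records: pd.DataFrame,
    grid: CellGrid,
    species: str | None = None,
    score_threshold: float = 0.5,
) -> tuple[np.ndarray, pd.DatetimeIndex]:
    """Stack per-frame cell counts: ``(T, n_rows, n_cols)`` plus frame times."""
    sel = records[records["score"] >= score_threshold]
    times = pd.DatetimeIndex(sorted(sel["timestamp"].unique()))
    stack = np.zeros((len(times), grid.n_rows, grid.n_cols), dtype=int)
    for k, (t, frame) in enumerate(sel.groupby("timestamp", sort=True)):
        stack[k] = assign_counts(frame, grid, species)
    return stack, times


def spatial_smooth(c_t: np.ndarray, grid: CellGrid, beta: float = DEFAULT_BETA) -> np.ndarray:
    """Distance-kernel smoothing of one frame's cell counts.

    ``beta = 0`` makes every cell equal the total count; large ``beta``
    recovers the raw counts.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    kernel = np.exp(-beta * grid.distance_matrix())
    flat = c_t.reshape(c_t.shape[:-2] + (grid.n_cells,))
    return (flat @ kernel.T).reshape(c_t.shape)


def temporal_smooth(
    x_series: np.ndarray, lam: float = DEFAULT_LAMBDA, s0: np.ndarray | None = None
) -> np.ndarray:
    """Recursive exponential smoothing along the leading (time) axis.

    ``s0`` defaults to the first observation.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    x_series = np.asarray(x_series, dtype=float)
    out = np.empty_like(x_series)
    s = x_series[0].copy() if s0 is None else np.asarray(s0, dtype=float).copy()
    for t in range(x_series.shape[0]):
        s = lam * x_series[t] + (1.0 - lam) * s
        out[t] = s
    return out


def period_heatmap(
    s_series: np.ndarray,
    times: pd.DatetimeIndex | None = None,
    start=None,
    end=None,
) -> np.ndarray:
    """Per-cell time-mean of the smoothed field within ``[start, end]``."""
    if times is not None and (start is not None or end is not None):
        mask = np.ones(len(times), dtype=bool)
        if start is not None:
            mask &= times >= pd.Timestamp(start)
        if end is not None:
            mask &= times <= pd.Timestamp(end)
        s_series = s_series[mask]
    if s_series.shape[0] == 0:
        raise ValueError("empty period")
    return s_series.mean(axis=0)


def _normalized(field: np.ndarray) -> np.ndarray:
    m = field.max()
    return field / m if m > 0 else np.zeros_like(field)


def render(
    field_great: np.ndarray,
    field_little: np.ndarray,
    background: np.ndarray | None = None,
    alpha: float = 0.65,
) -> np.ndarray:
    """Red/blue overlay of the two species fields, per-species normalized.

    Fields are upsampled cell-by-cell to the background size (or 200 px per
    cell when no background is given).  All-zero fields render the plain
    background.
    """
    g = _normalized(np.asarray(field_great, float))
    l = _normalized(np.asarray(field_little, float))
    if background is None:
        h, w = g.shape[0] * 200, g.shape[1] * 200
        background = np.full((h, w, 3), 235, dtype=np.uint8)
    h, w = background.shape[:2]
    ry, rx = int(np.ceil(h / g.shape[0])), int(np.ceil(w / g.shape[1]))
    g_px = np.kron(g, np.ones((ry, rx)))[:h, :w]
    l_px = np.kron(l, np.ones((ry, rx)))[:h, :w]
    out = background.astype(float)
    red = np.array([220.0, 40.0, 40.0])
    blue = np.array([40.0, 60.0, 220.0])
    out = out + alpha * g_px[..., None] * (red - out)
    out = out + alpha * l_px[..., None] * (blue - out)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def field_table(field: np.ndarray, species: str) -> pd.DataFrame:
    """Long-form per-cell values: cell_row, cell_col, species, value."""
    rows, cols = np.meshgrid(
        np.arange(field.shape[0]), np.arange(field.shape[1]), indexing="ij"
    )
    return pd.DataFrame(
        {
            "cell_row": rows.ravel(),
            "cell_col": cols.ravel(),
            "species": species,
            "value": field.ravel(),
        }
    )
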