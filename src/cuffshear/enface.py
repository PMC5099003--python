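"""En-face unwrapping: metric maps on the lumen surface flattened to a 2D
(axial x circumferential) grid, with flow from the bottom row to the top."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import CenterlineFrame
from .metrics import MetricMap

logger = logging.getLogger(__name__)


@dataclass
class EnfaceGrid:
    """2D metric image over (axial bin, circumferential bin)."""

    values: np.ndarray       # (n_s_bins, n_theta_bins)
    s_edges: np.ndarray      # (n_s_bins + 1,) mm
    theta_edges: np.ndarray  # (n_theta_bins + 1,) rad
    metric_name: str

    def to_frame(self) -> pd.DataFrame:
        ns, nt = self.values.shape
        si, ti = np.meshgrid(np.arange(ns), np.arange(nt), indexing="ij")
        return pd.DataFrame({
            "s_bin": si.ravel(),
            "theta_bin": ti.ravel(),
            "s_center_mm": 0.5 * (self.s_edges[si] + self.s_edges[si + 1]).ravel(),
            "theta_center_rad": 0.5 * (self.theta_edges[ti]
                                       + self.theta_edges[ti + 1]).ravel(),
            "value": self.values.ravel(),
        })


def enface(
    metric_map: MetricMap,
    frame: CenterlineFrame,
    n_s_bins: int,
    n_theta_bins: int,
) -> EnfaceGrid:
    """Bin nodes by (s, theta) and average the metric per cell.

    Cells left empty by the triangulation are filled from the nearest
    occupied cell along theta in the same axial row (circularly), falling
    back to the nearest occupied row in the same column; fills are logged.
    """
    if n_s_bins < 1 or n_theta_bins < 1:
        raise ValueError("bin counts must be positive")
    s_edges = np.linspace(0.0, frame.length, n_s_bins + 1)
    theta_edges = np.linspace(0.0, 2 * np.pi, n_theta_bins + 1)
    si = np.clip(np.digitize(frame.axial, s_edges) - 1, 0, n_s_bins - 1)
    ti = np.clip(np.digitize(frame.angular, theta_edges) - 1, 0,
                 n_theta_bins - 1)

    flat = si * n_theta_bins + ti
    sums = np.bincount(flat, weights=metric_map.values,
                       minlength=n_s_bins * n_theta_bins)
    counts = np.bincount(flat, minlength=n_s_bins * n_theta_bins)
    with np.errstate(invalid="ignore"):
        grid = (sums / counts).reshape(n_s_bins, n_theta_bins)
    occupied = counts.reshape(n_s_bins, n_theta_bins) > 0

    n_empty = int(np.sum(~occupied))
    if n_empty:
        logger.info("enface: filling %d empty cell(s) by nearest neighbour",
                    n_empty)
        for i, j in zip(*np.where(~occupied)):
            row = occupied[i]
            if row.any():
                offsets = np.arange(n_theta_bins)
                dist = np.minimum((offsets - j) % n_theta_bins,
                                  (j - offsets) % n_theta_bins)
                dist = np.where(row, dist, n_theta_bins + 1)
                grid[i, j] = grid[i, int(np.argmin(dist))]
            else:
                col = occupied[:, j]
                if not col.any():
                    raise ValueError("en-face grid has an empty row and column")
                rows = np.where(col)[0]
                grid[i, j] = grid[rows[np.argmin(np.abs(rows - i))], j]
    return EnfaceGrid(values=grid, s_edges=s_edges, theta_edges=theta_edges,
                      metric_name=metric_map.metric_name)
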