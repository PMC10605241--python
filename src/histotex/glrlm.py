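"""Gray-level run-length matrix construction and its 11 texture features.

A run is a maximal sequence of consecutive pixels with the same gray level
along one direction; the run-length matrix r(g, l) counts runs of level g and
length l. Pixels outside the ROI (level 0) break runs and are never counted.
The 11 statistics follow the Galloway / Chu / Dasarathy conventions: emphases
weight the run distribution by powers of run length l and of the 1-based gray
level g (e.g. low gray-level run emphasis divides by g²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import QuantizedImage

__all__ = ["RunLengthMatrix", "compute_glrlm", "glrlm_features", "GLRLM_FEATURE_NAMES"]

GLRLM_FEATURE_NAMES = [
    "sre",
    "lre",
    "gln",
    "rln",
    "rp",
    "lgre",
    "hgre",
    "srlge",
    "srhge",
    "lrlge",
    "lrhge",
]


@dataclass
class RunLengthMatrix:
    """Run counts by gray level (rows, 1-based) and run length (cols, 1-based)."""

    r: np.ndarray
    n_levels: int
    direction: tuple[int, int]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.int64)
        if self.r.ndim != 2 or self.r.shape[0] != self.n_levels:
            raise ValueError("r must have one row per gray level")
        if (self.r < 0).any():
            raise ValueError("run counts must be non-negative")

    @property
    def longest_run(self) -> int:
        return int(self.r.shape[1])

    @property
    def n_runs(self) -> int:
        """Nr, the total number of runs."""
        return int(self.r.sum())

    @property
    def n_pixels(self) -> int:
        """Np, the number of pixels covered: sum of l·r(g, l)."""
        lengths = np.arange(1, self.r.shape[1] + 1)
        return int((self.r * lengths).sum())


def _lines_for_direction(grid: np.ndarray, direction: tuple[int, int]) -> list[np.ndarray]:
    """1-D scan lines of ``grid`` along a direction; sign of the direction is immaterial."""
    dr, dc = direction
    if dr < 0 or (dr == 0 and dc < 0):  # a run is the same read either way
        dr, dc = -dr, -dc
    if (dr, dc) == (0, 1):
        return list(grid)
    if (dr, dc) == (1, 0):
        return list(grid.T)
    if (dr, dc) == (1, 1):
        h, w = grid.shape
        return [grid.diagonal(k) for k in range(-(h - 1), w)]
    if (dr, dc) == (1, -1):
        g = np.fliplr(grid)
        h, w = g.shape
        return [g.diagonal(k) for k in range(-(h - 1), w)]
    raise ValueError(f"unsupported run direction {direction}; use unit steps")


def compute_glrlm(q: QuantizedImage, direction: tuple[int, int] = (0, 1)) -> RunLengthMatrix:
    """Extract maximal runs along every scan line of ``direction``.

    Level-0 (masked-out) pixels terminate runs and contribute nothing, so
    Np always equals the number of in-ROI pixels traversed.
    """
    lines = _lines_for_direction(q.grid, direction)
    # Concatenate lines with a 0 sentinel so runs cannot straddle lines;
    # 0 is also the masked-pixel level, handled identically.
    parts: list[np.ndarray] = []
    for ln in lines:
        parts.append(np.asarray(ln))
        parts.append(np.zeros(1, dtype=np.int64))
    v = np.concatenate(parts)
    change = np.flatnonzero(np.diff(v) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [len(v) - 1]))
    vals = v[starts]
    keep = vals > 0
    vals = vals[keep]
    lengths = ends[keep] - starts[keep] + 1
    ng = q.n_levels
    if len(vals) == 0:
        raise ValueError("no in-ROI pixels: empty run-length matrix")
    lmax = int(lengths.max())
    r = np.zeros((ng, lmax), dtype=np.int64)
    np.add.at(r, (vals - 1, lengths - 1), 1)
    return RunLengthMatrix(r, ng, tuple(direction))


def glrlm_features(R: RunLengthMatrix) -> dict[str, float]:
    """The 11 run-length statistics (short/long run, gray-level and joint emphases)."""
    r = R.r.astype(float)
    nr = float(R.n_runs)
    if nr < 1:
        raise ValueError("run-length matrix is empty")
    np_ = float(R.n_pixels)
    g = np.arange(1, R.n_levels + 1, dtype=float)[:, None]
    length = np.arange(1, R.longest_run + 1, dtype=float)[None, :]

    f: dict[str, float] = {}
    f["sre"] = float((r / length**2).sum() / nr)
    f["lre"] = float((r * length**2).sum() / nr)
    f["gln"] = float((r.sum(axis=1) ** 2).sum() / nr)
    f["rln"] = float((r.sum(axis=0) ** 2).sum() / nr)
    f["rp"] = nr / np_
    f["lgre"] = float((r / g**2).sum() / nr)
    f["hgre"] = float((r * g**2).sum() / nr)
    f["srlge"] = float((r / (g**2 * length**2)).sum() / nr)
    f["srhge"] = float((r * g**2 / length**2).sum() / nr)
    f["lrlge"] = float((r * length**2 / g**2).sum() / nr)
    f["lrhge"] = float((r * g**2 * length**2).sum() / nr)
    return f
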