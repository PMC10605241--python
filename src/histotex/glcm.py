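"""Gray-level co-occurrence matrix construction and its 22 texture features.

A GLCM tabulates how often a pixel of gray level *i* co-occurs with a pixel of
gray level *j* at a fixed spatial displacement (dr, dc). After (optional)
symmetrization and normalization to unit sum, a family of classical
second-order statistics is read off the matrix: the Haralick set (contrast,
correlation, sum/difference statistics, the two information measures of
correlation, energy, entropy), the Soh additions (autocorrelation, cluster
shade/prominence, dissimilarity, maximum probability, homogeneity variants)
and the normalized inverse-difference pair IDN/IDMN.

Gray levels are 1-based (level 0 marks pixels outside the ROI and is excluded
from pair counting). All entropy-type features use a configurable log base
(default 2, so entropies are in bits) with the convention 0·log 0 = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .images import QuantizedImage

__all__ = ["GLCMatrix", "compute_glcm", "glcm_features", "GLCM_FEATURE_NAMES"]

GLCM_FEATURE_NAMES = [
    "autocorrelation",
    "contrast",
    "correlation1",
    "correlation2",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity1",
    "homogeneity2",
    "maximum_probability",
    "sum_of_squares",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "idn",
    "idmn",
]


@dataclass
class GLCMatrix:
    """Normalized co-occurrence probabilities with derived marginals.

    ``p[i-1, j-1]`` is the probability of the ordered level pair (i, j).
    ``p_sum[k-2]`` is the distribution of i+j for k = 2..2·Ng and
    ``p_diff[k]`` the distribution of |i-j| for k = 0..Ng-1.
    """

    p: np.ndarray
    n_levels: int
    offset: tuple[int, int]
    symmetric: bool = True
    px: np.ndarray = field(init=False, repr=False)
    py: np.ndarray = field(init=False, repr=False)
    p_sum: np.ndarray = field(init=False, repr=False)
    p_diff: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        ng = self.n_levels
        if self.p.shape != (ng, ng):
            raise ValueError(f"p must be {ng}x{ng}")
        total = self.p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"p must sum to 1, got {total}")
        self.px = self.p.sum(axis=1)
        self.py = self.p.sum(axis=0)
        i = np.arange(1, ng + 1)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        self.p_sum = np.bincount((ii + jj).ravel(), weights=self.p.ravel(), minlength=2 * ng + 1)[2:]
        self.p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=self.p.ravel(), minlength=ng)[:ng]

    @property
    def levels(self) -> np.ndarray:
        return np.arange(1, self.n_levels + 1, dtype=float)

    @property
    def mu_x(self) -> float:
        return float(self.levels @ self.px)

    @property
    def mu_y(self) -> float:
        return float(self.levels @ self.py)

    @property
    def sigma_x(self) -> float:
        return float(np.sqrt(((self.levels - self.mu_x) ** 2) @ self.px))

    @property
    def sigma_y(self) -> float:
        return float(np.sqrt(((self.levels - self.mu_y) ** 2) @ self.py))


def compute_glcm(
    q: QuantizedImage, offset: tuple[int, int] = (0, 1), symmetric: bool = True
) -> GLCMatrix:
    """Count level pairs at displacement ``offset`` over all in-ROI pixel pairs.

    A pair contributes only when both its pixels are inside the ROI.  With
    ``symmetric=True`` the transposed counts are added before normalization,
    which makes the features invariant to the sign of the offset.
    """
    dr, dc = offset
    if abs(dr) + abs(dc) < 1:
        raise ValueError("offset must displace by at least one pixel")
    grid = q.grid
    h, w = grid.shape
    # Overlapping windows: a at (r, c), b at (r + dr, c + dc).
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"no valid pixel pair for offset {offset} on a {h}x{w} grid")
    a = grid[r0:r1, c0:c1]
    b = grid[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        raise ValueError(f"no in-ROI pixel pair for offset {offset}")
    ng = q.n_levels
    idx = (a[valid] - 1) * ng + (b[valid] - 1)
    counts = np.bincount(idx, minlength=ng * ng).reshape(ng, ng).astype(float)
    if symmetric:
        counts = counts + counts.T
    return GLCMatrix(counts / counts.sum(), ng, (dr, dc), symmetric)


def _xlog(v: np.ndarray | float, base: float) -> np.ndarray:
    """log with 0 mapped to 0 (for x·log x style sums)."""
    v = np.asarray(v, dtype=float)
    out = np.zeros_like(v)
    nz = v > 0
    out[nz] = np.log(v[nz]) / np.log(base)
    return out


def glcm_features(G: GLCMatrix, log_base: float = 2.0) -> dict[str, float]:
    """Compute the 22 co-occurrence features from a normalized GLCM.

    Degenerate marginals (zero standard deviation) force the two correlation
    features to 0 with a warning; the information-measure guards keep imc1/imc2
    finite on single-level images.
    """
    p = G.p
    ng = G.n_levels
    lv = G.levels
    ii, jj = np.meshgrid(lv, lv, indexing="ij")
    mu_x, mu_y = G.mu_x, G.mu_y
    sx, sy = G.sigma_x, G.sigma_y

    f: dict[str, float] = {}
    f["autocorrelation"] = float((ii * jj * p).sum())
    f["contrast"] = float((((ii - jj) ** 2) * p).sum())
    if sx > 0 and sy > 0:
        f["correlation1"] = float(((ii - mu_x) * (jj - mu_y) * p).sum() / (sx * sy))
        f["correlation2"] = float((f["autocorrelation"] - mu_x * mu_y) / (sx * sy))
    else:
        warnings.warn("glcm_features: degenerate marginal, correlation set to 0", stacklevel=2)
        f["correlation1"] = 0.0
        f["correlation2"] = 0.0
    f["cluster_prominence"] = float((((ii + jj - mu_x - mu_y) ** 4) * p).sum())
    f["cluster_shade"] = float((((ii + jj - mu_x - mu_y) ** 3) * p).sum())
    f["dissimilarity"] = float((np.abs(ii - jj) * p).sum())
    f["energy"] = float((p**2).sum())
    f["entropy"] = float(-(p * _xlog(p, log_base)).sum())
    f["homogeneity1"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    f["homogeneity2"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    f["maximum_probability"] = float(p.max())
    f["sum_of_squares"] = float((((ii - mu_x) ** 2) * p).sum())

    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    ps = G.p_sum
    sum_average = float(k_sum @ ps)
    f["sum_average"] = sum_average
    f["sum_variance"] = float(((k_sum - sum_average) ** 2) @ ps)
    f["sum_entropy"] = float(-(ps * _xlog(ps, log_base)).sum())

    k_diff = np.arange(0, ng, dtype=float)
    pd = G.p_diff
    mu_diff = float(k_diff @ pd)
    f["difference_variance"] = float(((k_diff - mu_diff) ** 2) @ pd)
    f["difference_entropy"] = float(-(pd * _xlog(pd, log_base)).sum())

    hx = float(-(G.px * _xlog(G.px, log_base)).sum())
    hy = float(-(G.py * _xlog(G.py, log_base)).sum())
    hxy = f["entropy"]
    pxy = np.outer(G.px, G.py)
    hxy1 = float(-(p * _xlog(pxy, log_base)).sum())
    hxy2 = float(-(pxy * _xlog(pxy, log_base)).sum())
    denom = max(hx, hy)
    f["imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    f["imc2"] = float(np.sqrt(max(0.0, 1.0 - log_base ** (-2.0 * (hxy2 - hxy)))))

    f["idn"] = float((p / (1.0 + np.abs(ii - jj) / ng)).sum())
    f["idmn"] = float((p / (1.0 + ((ii - jj) ** 2) / ng**2)).sum())
    return f
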