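"""Independent brute-force oracles used only by the test suite.

Everything here is written from the published definitions with plain Python
loops and O(n^2) enumeration, deliberately sharing no code with the package
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_glcm(grid: np.ndarray, n_levels: int, offset: tuple[int, int], symmetric: bool) -> np.ndarray:
    """Pair-enumeration co-occurrence matrix (level 0 = ignored pixel)."""
    dr, dc = offset
    h, w = grid.shape
    counts = np.zeros((n_levels, n_levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = grid[r, c], grid[r2, c2]
                if a > 0 and b > 0:
                    counts[a - 1, b - 1] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def brute_glrlm(grid: np.ndarray, n_levels: int, direction: tuple[int, int]) -> np.ndarray:
    """Run enumeration by walking each scan line pixel by pixel."""
    dr, dc = direction
    if dr < 0 or (dr == 0 and dc < 0):
        dr, dc = -dr, -dc
    h, w = grid.shape
    # collect starting points whose predecessor along (dr, dc) is off-grid
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < h and 0 <= pc < w):
                starts.append((r, c))
    runs: list[tuple[int, int]] = []
    for r, c in starts:
        cur, length = 0, 0
        while 0 <= r < h and 0 <= c < w:
            v = grid[r, c]
            if v == cur:
                length += 1
            else:
                if cur > 0:
                    runs.append((cur, length))
                cur, length = v, 1
            r, c = r + dr, c + dc
        if cur > 0:
            runs.append((cur, length))
    lmax = max(length for _, length in runs)
    out = np.zeros((n_levels, lmax), dtype=int)
    for g, length in runs:
        out[g - 1, length - 1] += 1
    return out


def _log(x: float, base: float) -> float:
    return math.log(x, base) if x > 0 else 0.0


def literal_glcm_features(p: np.ndarray, base: float = 2.0) -> dict[str, float]:
    """The 22 co-occurrence statistics evaluated with literal loops."""
    ng = p.shape[0]
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sx = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sy = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    f: dict[str, float] = {}
    f["autocorrelation"] = sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng))
    f["contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    if sx > 0 and sy > 0:
        f["correlation1"] = (
            sum((i + 1 - mu_x) * (j + 1 - mu_y) * p[i][j] for i in range(ng) for j in range(ng))
            / (sx * sy)
        )
        f["correlation2"] = (f["autocorrelation"] - mu_x * mu_y) / (sx * sy)
    else:
        f["correlation1"] = f["correlation2"] = 0.0
    f["cluster_prominence"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 4 * p[i][j] for i in range(ng) for j in range(ng)
    )
    f["cluster_shade"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 3 * p[i][j] for i in range(ng) for j in range(ng)
    )
    f["dissimilarity"] = sum(abs(i - j) * p[i][j] for i in range(ng) for j in range(ng))
    f["energy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    f["entropy"] = -sum(p[i][j] * _log(p[i][j], base) for i in range(ng) for j in range(ng))
    f["homogeneity1"] = sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    f["homogeneity2"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    f["maximum_probability"] = max(p[i][j] for i in range(ng) for j in range(ng))
    f["sum_of_squares"] = sum(
        (i + 1 - mu_x) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
    )
    f["sum_average"] = sum(k * p_sum[k] for k in p_sum)
    f["sum_variance"] = sum((k - f["sum_average"]) ** 2 * p_sum[k] for k in p_sum)
    f["sum_entropy"] = -sum(p_sum[k] * _log(p_sum[k], base) for k in p_sum)
    mu_d = sum(k * p_diff[k] for k in p_diff)
    f["difference_variance"] = sum((k - mu_d) ** 2 * p_diff[k] for k in p_diff)
    f["difference_entropy"] = -sum(p_diff[k] * _log(p_diff[k], base) for k in p_diff)
    hx = -sum(px[i] * _log(px[i], base) for i in range(ng))
    hy = -sum(py[j] * _log(py[j], base) for j in range(ng))
    hxy = f["entropy"]
    hxy1 = -sum(p[i][j] * _log(px[i] * py[j], base) for i in range(ng) for j in range(ng))
    hxy2 = -sum(px[i] * py[j] * _log(px[i] * py[j], base) for i in range(ng) for j in range(ng))
    f["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    f["imc2"] = math.sqrt(max(0.0, 1.0 - base ** (-2.0 * (hxy2 - hxy))))
    f["idn"] = sum(p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    f["idmn"] = sum(p[i][j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng))
    return f


def literal_glrlm_features(r: np.ndarray) -> dict[str, float]:
    """The 11 run-length statistics evaluated with literal loops."""
    ng, lmax = r.shape
    nr = float(r.sum())
    np_ = float(sum((l + 1) * r[g][l] for g in range(ng) for l in range(lmax)))
    terms = [(g + 1, l + 1, float(r[g][l])) for g in range(ng) for l in range(lmax)]
    f = {
        "sre": sum(v / l**2 for g, l, v in terms) / nr,
        "lre": sum(v * l**2 for g, l, v in terms) / nr,
        "gln": sum(sum(r[g]) ** 2 for g in range(ng)) / nr,
        "rln": sum(sum(r[:, l]) ** 2 for l in range(lmax)) / nr,
        "rp": nr / np_,
        "lgre": sum(v / g**2 for g, l, v in terms) / nr,
        "hgre": sum(v * g**2 for g, l, v in terms) / nr,
        "srlge": sum(v / (g**2 * l**2) for g, l, v in terms) / nr,
        "srhge": sum(v * g**2 / l**2 for g, l, v in terms) / nr,
        "lrlge": sum(v * l**2 / g**2 for g, l, v in terms) / nr,
        "lrhge": sum(v * g**2 * l**2 for g, l, v in terms) / nr,
    }
    return {k: float(v) for k, v in f.items()}


def pair_count_auc(scores, labels, positive="GBM") -> float:
    """Mann–Whitney AUC by O(n^2) pair counting with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(str)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else 0.5 if x == y else 0.0
    return total / (len(pos) * len(neg))


def _rank_auc(scores: np.ndarray, pos: np.ndarray) -> float:
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    m = int(pos.sum())
    n = len(scores) - m
    return (ranks[pos].sum() - m * (m + 1) / 2.0) / (m * n)


def permutation_auc_test(scores_a, scores_b, labels, n_perm=10_000, seed=0, positive="GBM"):
    """Paired permutation test on |AUC_A - AUC_B| by randomly swapping the two
    score vectors per case. Returns the two-sided p-value."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    pos = np.asarray(labels).astype(str) == positive
    obs = abs(_rank_auc(scores_a, pos) - _rank_auc(scores_b, pos))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        swap = rng.random(len(scores_a)) < 0.5
        a = np.where(swap, scores_b, scores_a)
        b = np.where(swap, scores_a, scores_b)
        if abs(_rank_auc(a, pos) - _rank_auc(b, pos)) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
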