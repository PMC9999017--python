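"""Independent brute-force oracles for the texture features.

These deliberately use the slowest, most explicit formulation possible —
per-pixel loops, flood fill, direct formula transcription — so they share
no code path with the package implementation.
"""
from __future__ import annotations

import math
from collections import deque

import numpy as np

DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


def glcm_oracle(levels: np.ndarray, n_levels: int,
                directions=DIRECTIONS) -> dict[str, float]:
    """Exhaustive symmetric pair enumeration, per-direction normalization,
    matrix averaging, then direct formula evaluation."""
    h, w = levels.shape
    mats = []
    for dy, dx in directions:
        m = [[0.0] * n_levels for _ in range(n_levels)]
        total = 0
        for y in range(h):
            for x in range(w):
                if levels[y, x] <= 0:
                    continue
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and levels[ny, nx] > 0:
                    a, b = levels[y, x] - 1, levels[ny, nx] - 1
                    m[a][b] += 1
                    m[b][a] += 1
                    total += 2
        if total:
            mats.append([[v / total for v in row] for row in m])
    p = [[sum(m[i][j] for m in mats) / len(mats) for j in range(n_levels)]
         for i in range(n_levels)]
    homog = energy = contrast = dissim = h10 = h2 = 0.0
    mu_i = mu_j = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            v = p[i][j]
            gi, gj = i + 1, j + 1
            homog += v / (1 + abs(gi - gj))
            energy += v * v
            contrast += (gi - gj) ** 2 * v
            dissim += abs(gi - gj) * v
            mu_i += gi * v
            mu_j += gj * v
            if v > 0:
                h10 -= v * math.log10(v)
                h2 -= v * math.log2(v)
    var_i = sum((i + 1 - mu_i) ** 2 * p[i][j]
                for i in range(n_levels) for j in range(n_levels))
    var_j = sum((j + 1 - mu_j) ** 2 * p[i][j]
                for i in range(n_levels) for j in range(n_levels))
    if var_i > 0 and var_j > 0:
        cov = sum((i + 1 - mu_i) * (j + 1 - mu_j) * p[i][j]
                  for i in range(n_levels) for j in range(n_levels))
        corr = cov / math.sqrt(var_i * var_j)
    else:
        corr = 0.0
    return {"GLCM_Homogeneity": homog, "GLCM_Energy": energy,
            "GLCM_Contrast": contrast, "GLCM_Correlation": corr,
            "GLCM_Entropy_log10": h10, "GLCM_Entropy_log2": h2,
            "GLCM_Dissimilarity": dissim}


def flood_zones(levels: np.ndarray) -> list[tuple[int, int]]:
    """8-connected flat zones by explicit BFS flood fill: (level, size)."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for y in range(h):
        for x in range(w):
            if levels[y, x] <= 0 or seen[y, x]:
                continue
            lv = levels[y, x]
            size = 0
            queue = deque([(y, x)])
            seen[y, x] = True
            while queue:
                cy, cx = queue.popleft()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = cy + dy, cx + dx
                        if (0 <= ny < h and 0 <= nx < w and not seen[ny, nx]
                                and levels[ny, nx] == lv):
                            seen[ny, nx] = True
                            queue.append((ny, nx))
            zones.append((int(lv), size))
    return zones


def glzlm_oracle(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    zones = flood_zones(levels)
    nz = len(zones)
    npix = sum(s for _, s in zones)
    by_level: dict[int, float] = {}
    by_size: dict[int, float] = {}
    for lv, s in zones:
        by_level[lv] = by_level.get(lv, 0) + 1
        by_size[s] = by_size.get(s, 0) + 1
    return {
        "GLZLM_SZE": sum(1.0 / s ** 2 for _, s in zones) / nz,
        "GLZLM_LZE": sum(float(s ** 2) for _, s in zones) / nz,
        "GLZLM_LGZE": sum(1.0 / lv ** 2 for lv, _ in zones) / nz,
        "GLZLM_HGZE": sum(float(lv ** 2) for lv, _ in zones) / nz,
        "GLZLM_SZLGE": sum(1.0 / (lv ** 2 * s ** 2) for lv, s in zones) / nz,
        "GLZLM_SZHGE": sum(lv ** 2 / s ** 2 for lv, s in zones) / nz,
        "GLZLM_LZLGE": sum(s ** 2 / lv ** 2 for lv, s in zones) / nz,
        "GLZLM_LZHGE": sum(float(lv ** 2 * s ** 2) for lv, s in zones) / nz,
        "GLZLM_GLNU": sum(c ** 2 for c in by_level.values()) / nz,
        "GLZLM_ZLNU": sum(c ** 2 for c in by_size.values()) / nz,
        "GLZLM_ZP": nz / npix,
    }


def boundary_edge_perimeter(mask: np.ndarray) -> int:
    """Count pixel edges adjacent to background, one pixel at a time."""
    h, w = mask.shape
    edges = 0
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < h and 0 <= nx < w) or not mask[ny, nx]:
                    edges += 1
    return edges


def spearman_oracle(x, y) -> float:
    """1 - 6*sum(d^2)/(n(n^2-1)) on tie-free data."""
    n = len(x)
    rx = {v: i + 1 for i, v in enumerate(sorted(x))}
    ry = {v: i + 1 for i, v in enumerate(sorted(y))}
    d2 = sum((rx[a] - ry[b]) ** 2 for a, b in zip(x, y))
    return 1 - 6 * d2 / (n * (n * n - 1))


def imbalance_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Direct transcription of the rank definition with index tie-breaks."""
    a = np.atleast_2d(np.asarray(a, dtype=float).T).T
    n = len(b)
    total = 0
    for i in range(n):
        best = None
        for j in range(n):
            if j == i:
                continue
            d = float(np.linalg.norm(a[i] - a[j]))
            if best is None or d < best[0] or (d == best[0] and j < best[1]):
                best = (d, j)
        j = best[1]
        others = sorted((abs(float(b[i]) - float(b[k])), k)
                        for k in range(n) if k != i)
        rank = [k for _, k in others].index(j) + 1
        total += rank
    return 2.0 * total / n / n
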