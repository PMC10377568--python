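"""Independent brute-force reference for the texture matrices and features.

Everything here is computed by naive per-pixel enumeration in plain Python
loops, written from the mathematical definitions and kept deliberately
separate from the optimized implementation it cross-checks.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def brute_glcm(levels: np.ndarray, mask: np.ndarray, n_bins: int,
               offsets=OFFSETS, radius: int = 1) -> np.ndarray:
    """Symmetrized pooled co-occurrence probabilities by pair enumeration."""
    H, W = levels.shape
    counts = np.zeros((n_bins, n_bins))
    for dr, dc in offsets:
        dr, dc = dr * radius, dc * radius
        for r in range(H):
            for c in range(W):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < H and 0 <= c2 < W and mask[r, c] and mask[r2, c2]:
                    i, j = levels[r, c] - 1, levels[r2, c2] - 1
                    counts[i, j] += 1
                    counts[j, i] += 1
    total = counts.sum()
    return counts / total


def brute_glcm_features(p: np.ndarray) -> dict[str, float]:
    B = p.shape[0]
    mu = sum((i + 1) * p[i, j] for i in range(B) for j in range(B))
    var = sum(((i + 1) - mu) ** 2 * p[i, j] for i in range(B) for j in range(B))
    sigma = math.sqrt(var)
    out = dict.fromkeys(
        ["autocorr", "prominence", "shade", "contrast", "correlation",
         "energy", "entropy", "homogeneity"], 0.0)
    for i in range(B):
        for j in range(B):
            v = p[i, j]
            gi, gj = i + 1, j + 1
            out["autocorr"] += gi * gj * v
            out["prominence"] += (gi + gj - 2 * mu) ** 4 * v
            out["shade"] += (gi + gj - 2 * mu) ** 3 * v
            out["contrast"] += (gi - gj) ** 2 * v
            if sigma > 0:
                out["correlation"] += (gi - mu) * (gj - mu) * v / (sigma**2)
            out["energy"] += v * v
            if v > 0:
                out["entropy"] -= v * math.log2(v)
            out["homogeneity"] += v / (1 + abs(gi - gj))
    return out


def brute_runs(levels: np.ndarray, mask: np.ndarray,
               directions=OFFSETS) -> list[tuple[int, int]]:
    """All (level, length) runs by walking each lattice line pixelwise."""
    H, W = levels.shape
    runs = []
    for dr, dc in directions:
        starts = []
        for r in range(H):
            for c in range(W):
                pr, pc = r - dr, c - dc
                if not (0 <= pr < H and 0 <= pc < W):
                    starts.append((r, c))
        for r0, c0 in starts:
            r, c = r0, c0
            cur, length = 0, 0
            while 0 <= r < H and 0 <= c < W:
                v = levels[r, c] if mask[r, c] else 0
                if v == cur:
                    length += 1
                else:
                    if cur != 0:
                        runs.append((cur, length))
                    cur, length = v, 1
                r, c = r + dr, c + dc
            if cur != 0:
                runs.append((cur, length))
    return runs


def brute_glrlm(levels, mask, n_bins, directions=OFFSETS) -> np.ndarray:
    runs = brute_runs(levels, mask, directions)
    max_len = max(l for _, l in runs)
    r = np.zeros((n_bins, max_len))
    for lev, length in runs:
        r[lev - 1, length - 1] += 1
    return r


def brute_glrlm_features(r: np.ndarray) -> dict[str, float]:
    n = r.sum()
    B, L = r.shape
    out = dict.fromkeys(["gln", "hglre", "lrhgle", "lrlgle", "lglre",
                         "rln", "sre"], 0.0)
    for i in range(B):
        for j in range(L):
            v = r[i, j] / n
            gi, gj = i + 1, j + 1
            out["hglre"] += gi**2 * v
            out["lrhgle"] += gi**2 * gj**2 * v
            out["lrlgle"] += gj**2 / gi**2 * v
            out["lglre"] += v / gi**2
            out["sre"] += v / gj**2
    out["gln"] = sum(r[i, :].sum() ** 2 for i in range(B)) / n
    out["rln"] = sum(r[:, j].sum() ** 2 for j in range(L)) / n
    return out


def brute_zones(levels, mask, connectivity=8) -> list[tuple[int, int]]:
    """(level, size) of connected equal-level components by flood fill."""
    H, W = levels.shape
    seen = np.zeros((H, W), dtype=bool)
    if connectivity == 8:
        nbrs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    zones = []
    for r in range(H):
        for c in range(W):
            if seen[r, c] or not mask[r, c]:
                continue
            lev = levels[r, c]
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                y, x = stack.pop()
                size += 1
                for dy, dx in nbrs:
                    ny, nx = y + dy, x + dx
                    if (0 <= ny < H and 0 <= nx < W and not seen[ny, nx]
                            and mask[ny, nx] and levels[ny, nx] == lev):
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            zones.append((int(lev), size))
    return zones


def brute_glszm(levels, mask, n_bins, connectivity=8) -> np.ndarray:
    zones = brute_zones(levels, mask, connectivity)
    max_size = max(sz for _, sz in zones)
    s = np.zeros((n_bins, max_size))
    for lev, sz in zones:
        s[lev - 1, sz - 1] += 1
    return s


def brute_glszm_features(s: np.ndarray) -> dict[str, float]:
    n = s.sum()
    B, Z = s.shape
    p_i = [s[i, :].sum() / n for i in range(B)]
    mean = sum((i + 1) * p_i[i] for i in range(B))
    out = {
        "glm": mean,
        "gln": sum(s[i, :].sum() ** 2 for i in range(B)) / n,
        "glv": sum((i + 1) ** 2 * p_i[i] for i in range(B)) - mean**2,
        "hgle": 0.0, "lze": 0.0, "lzhgle": 0.0, "lzlgle": 0.0, "lgle": 0.0,
    }
    for i in range(B):
        for j in range(Z):
            v = s[i, j] / n
            gi, gj = i + 1, j + 1
            out["hgle"] += gi**2 * v
            out["lze"] += gj**2 * v
            out["lzhgle"] += gi**2 * gj**2 * v
            out["lzlgle"] += gj**2 / gi**2 * v
            out["lgle"] += v / gi**2
    return out
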