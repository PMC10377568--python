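"""Gray-level texture matrices and the 23-feature radiomic panel.

Computes, for one quantized 2D image, the gray-level co-occurrence matrix
(GLCM), run-length matrix (GLRLM) and size-zone matrix (GLSZM), and from
them the 23 named texture features used to score how distinguishable
synthetic images are from real ones: 8 GLCM, 7 GLRLM and 8 GLSZM features.

Conventions
-----------
* Gray levels are indexed 1..B so the 1/i**2 low-level emphasis terms are
  finite; level 0 marks out-of-mask pixels, which never enter any matrix.
* "Combined" offsets pool the counts of the four unique 2D directions
  (0,r), (r,0), (r,r), (r,-r) into one matrix before normalization
  (merged-matrix aggregation), so each feature has a single value.
* The GLCM is always symmetrized (each pixel pair counted in both orders).
* Entropy uses log base 2 with 0*log(0) := 0.
* GLSZM zones grow with 8-connectivity by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .prep import DEFAULT_BINS, QuantizedImage, normalize_unit, quantize

__all__ = [
    "GLCMatrix", "RunLengthMatrix", "SizeZoneMatrix",
    "COMBINED_OFFSETS", "FEATURE_NAMES",
    "glcm_matrix", "glcm_features",
    "glrlm_matrix", "glrlm_features",
    "glszm_matrix", "glszm_features",
    "extract_all",
]

#: the four unique 2D directions pooled under "combined", at unit radius
COMBINED_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

GLCM_FEATURES = (
    "GLCM Auto Correlation", "GLCM Cluster Prominence", "GLCM Cluster Shade",
    "GLCM Contrast", "GLCM Correlation", "GLCM Energy", "GLCM Entropy",
    "GLCM Homogeneity",
)
GLRLM_FEATURES = (
    "GLRLM Grey Level Nonuniformity", "GLRLM High Grey Level Run Emphasis",
    "GLRLM Long Run High Grey Level Emphasis",
    "GLRLM Long Run Low Grey Level Emphasis",
    "GLRLM Low Gray Level Run Emphasis", "GLRLM Run Length Nonuniformity",
    "GLRLM Short Run Emphasis",
)
GLSZM_FEATURES = (
    "GLSZM Grey Level Mean", "GLSZM Grey Level Nonuniformity",
    "GLSZM Grey Level Variance", "GLSZM High Grey Level Emphasis",
    "GLSZM Large Zone Emphasis", "GLSZM Large Zone High Grey Level Emphasis",
    "GLSZM Large Zone Low Grey Level Emphasis", "GLSZM Low Grey Level Emphasis",
)
#: report order: GLCM, GLRLM, GLSZM
FEATURE_NAMES: tuple[str, ...] = GLCM_FEATURES + GLRLM_FEATURES + GLSZM_FEATURES


@dataclass
class GLCMatrix:
    """Symmetric joint gray-level probabilities p(i, j), i, j = 1..B."""

    p: np.ndarray
    offsets_used: tuple[tuple[int, int], ...]
    radius: int


@dataclass
class RunLengthMatrix:
    """r(i, j) = number of runs of level i and length j, pooled over
    directions; r has shape (B, max run length)."""

    r: np.ndarray
    n_runs: int
    directions_used: tuple[tuple[int, int], ...]


@dataclass
class SizeZoneMatrix:
    """s(i, j) = number of connected zones of level i and size j; shape
    (B, max zone size)."""

    s: np.ndarray
    n_zones: int
    connectivity: int


def _resolve_offsets(offsets, radius: int) -> tuple[tuple[int, int], ...]:
    if offsets == "combined" or offsets is None:
        return tuple((dr * radius, dc * radius) for dr, dc in COMBINED_OFFSETS)
    return tuple(tuple(o) for o in offsets)


def glcm_matrix(
    q: QuantizedImage,
    radius: int = 1,
    offsets="combined",
) -> GLCMatrix:
    """Pooled, symmetrized co-occurrence matrix of in-mask pixel pairs."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    offs = _resolve_offsets(offsets, radius)
    B = q.n_bins
    lv = q.levels
    inside = q.mask.astype(bool)
    counts = np.zeros((B, B), dtype=float)
    H, W = lv.shape
    for dr, dc in offs:
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        a = lv[r0:r1, c0:c1]
        b = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = inside[r0:r1, c0:c1] & inside[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if not ok.any():
            continue
        np.add.at(counts, (a[ok] - 1, b[ok] - 1), 1.0)
    counts = counts + counts.T  # each pair in both orders
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-mask pixel pair at the requested offsets")
    return GLCMatrix(p=counts / total, offsets_used=offs, radius=radius)


def glcm_features(M: GLCMatrix) -> dict[str, float]:
    p = M.p
    B = p.shape[0]
    i = np.arange(1, B + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)  # row marginal; equals column marginal by symmetry
    mu = float((i * pi).sum())
    sigma = float(np.sqrt(((i - mu) ** 2 * pi).sum()))
    dev = ii + jj - 2.0 * mu
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    if sigma > 0:
        correlation = float(((ii - mu) * (jj - mu) * p).sum() / (sigma * sigma))
    else:
        correlation = 0.0  # constant image convention
    return {
        "GLCM Auto Correlation": float((ii * jj * p).sum()),
        "GLCM Cluster Prominence": float((dev**4 * p).sum()),
        "GLCM Cluster Shade": float((dev**3 * p).sum()),
        "GLCM Contrast": float(((ii - jj) ** 2 * p).sum()),
        "GLCM Correlation": correlation,
        "GLCM Energy": float((p**2).sum()),
        "GLCM Entropy": float(-(p * logp).sum()),
        "GLCM Homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
    }


def _rle_lines(lv: np.ndarray, direction: tuple[int, int]):
    """Yield the 1-D level sequences along every line of a direction.
    Out-of-mask pixels are level 0 and act as run separators."""
    dr, dc = direction
    if (dr, dc) == (0, 1):
        yield from lv
    elif (dr, dc) == (1, 0):
        yield from lv.T
    elif (dr, dc) == (1, 1):
        H, W = lv.shape
        for k in range(-(H - 1), W):
            yield np.diagonal(lv, offset=k)
    elif (dr, dc) == (1, -1):
        fl = np.fliplr(lv)
        H, W = fl.shape
        for k in range(-(H - 1), W):
            yield np.diagonal(fl, offset=k)
    else:
        raise ValueError(f"unsupported direction {direction}")


def _runs_of_line(line: np.ndarray):
    """(level, length) for each maximal run of equal nonzero values."""
    n = line.size
    if n == 0:
        return
    change = np.flatnonzero(np.diff(line)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    for s, e in zip(starts, ends):
        v = line[s]
        if v != 0:
            yield int(v), int(e - s)


def glrlm_matrix(q: QuantizedImage, directions="combined") -> RunLengthMatrix:
    """Run-length counts pooled over directions; mask gaps terminate runs."""
    if not q.mask.any():
        raise ValueError("empty mask")
    dirs = _resolve_offsets(directions, 1)
    lv = np.where(q.mask.astype(bool), q.levels, 0)
    B = q.n_bins
    max_len = max(lv.shape)
    counts = np.zeros((B, max_len), dtype=float)
    n_runs = 0
    for d in dirs:
        for line in _rle_lines(lv, d):
            for level, length in _runs_of_line(np.ascontiguousarray(line)):
                counts[level - 1, length - 1] += 1
                n_runs += 1
    # trim trailing all-zero run-length columns (keep at least one)
    last = max(int(np.max(np.nonzero(counts.sum(axis=0))[0])) if n_runs else 0, 0)
    return RunLengthMatrix(r=counts[:, : last + 1], n_runs=n_runs,
                           directions_used=dirs)


def glrlm_features(R: RunLengthMatrix) -> dict[str, float]:
    r = R.r
    n = float(R.n_runs)
    if n < 1:
        raise ValueError("run-length matrix has no runs")
    B, L = r.shape
    i = np.arange(1, B + 1, dtype=float)[:, None]
    j = np.arange(1, L + 1, dtype=float)[None, :]
    rbar = r / n
    return {
        "GLRLM Grey Level Nonuniformity": float((r.sum(axis=1) ** 2).sum() / n),
        "GLRLM High Grey Level Run Emphasis": float((i**2 * rbar).sum()),
        "GLRLM Long Run High Grey Level Emphasis": float((i**2 * j**2 * rbar).sum()),
        "GLRLM Long Run Low Grey Level Emphasis": float((j**2 / i**2 * rbar).sum()),
        "GLRLM Low Gray Level Run Emphasis": float((rbar / i**2).sum()),
        "GLRLM Run Length Nonuniformity": float((r.sum(axis=0) ** 2).sum() / n),
        "GLRLM Short Run Emphasis": float((rbar / j**2).sum()),
    }


def glszm_matrix(q: QuantizedImage, connectivity: int = 8) -> SizeZoneMatrix:
    """Size-zone counts: connected components of equal-level in-mask pixels."""
    if not q.mask.any():
        raise ValueError("empty mask")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    lv = np.where(q.mask.astype(bool), q.levels, 0)
    B = q.n_bins
    zones: list[tuple[int, int]] = []
    for level in range(1, B + 1):
        binary = lv == level
        if not binary.any():
            continue
        labeled, n = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        zones.extend((level, int(sz)) for sz in sizes)
    max_size = max(sz for _, sz in zones)
    s = np.zeros((B, max_size), dtype=float)
    for level, sz in zones:
        s[level - 1, sz - 1] += 1
    return SizeZoneMatrix(s=s, n_zones=len(zones), connectivity=connectivity)


def glszm_features(S: SizeZoneMatrix) -> dict[str, float]:
    s = S.s
    n = float(S.n_zones)
    if n < 1:
        raise ValueError("size-zone matrix has no zones")
    B, Z = s.shape
    i = np.arange(1, B + 1, dtype=float)[:, None]
    j = np.arange(1, Z + 1, dtype=float)[None, :]
    p_i = s.sum(axis=1) / n  # zone-level marginal
    iv = np.arange(1, B + 1, dtype=float)
    glm = float((iv * p_i).sum())
    return {
        "GLSZM Grey Level Mean": glm,
        "GLSZM Grey Level Nonuniformity": float((s.sum(axis=1) ** 2).sum() / n),
        "GLSZM Grey Level Variance": float((iv**2 * p_i).sum() - glm**2),
        "GLSZM High Grey Level Emphasis": float((i**2 * s).sum() / n),
        "GLSZM Large Zone Emphasis": float((j**2 * s).sum() / n),
        "GLSZM Large Zone High Grey Level Emphasis": float((i**2 * j**2 * s).sum() / n),
        "GLSZM Large Zone Low Grey Level Emphasis": float((j**2 / i**2 * s).sum() / n),
        "GLSZM Low Grey Level Emphasis": float((s / i**2).sum() / n),
    }


def extract_all(
    image: np.ndarray,
    mask: np.ndarray,
    n_bins: int = DEFAULT_BINS,
    radius: int = 1,
    offsets="combined",
    connectivity: int = 8,
    normalize: bool = True,
) -> dict[str, float]:
    """Full panel: normalize -> quantize -> three matrices -> 23 features.

    Returns an ordered dict keyed by :data:`FEATURE_NAMES`.
    """
    img = normalize_unit(image) if normalize else np.asarray(image, dtype=float)
    q = quantize(img, mask, n_bins=n_bins)
    feats: dict[str, float] = {}
    feats.update(glcm_features(glcm_matrix(q, radius=radius, offsets=offsets)))
    feats.update(glrlm_features(glrlm_matrix(q, directions=offsets)))
    feats.update(glszm_features(glszm_matrix(q, connectivity=connectivity)))
    out = {name: feats[name] for name in FEATURE_NAMES}
    if not all(np.isfinite(v) for v in out.values()):
        raise ValueError("non-finite feature value produced")
    return out
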