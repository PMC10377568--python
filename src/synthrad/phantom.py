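"""Synthetic paired-contrast brain phantoms.

Generates aligned pseudo-T2W / pseudo-FLAIR slice pairs with a known,
deterministic tissue-dependent intensity relationship between the two
contrasts.  Each phantom is an elliptical "brain" containing nested
elliptical tissue regions (outer grey-matter-like tissue, a white-matter-like
band, a central fluid-like region, optional lesion blobs).  The fluid class
is bright in domain A (T2W-like) and dark in domain B (FLAIR-like),
mimicking fluid attenuation, so translating A to B is a learnable,
anatomy-preserving contrast remapping.

Acquisition noise is modelled as additive Gaussian noise, drawn
independently for the two domains, with intensities clipped to [0, 1].
No MRI physics (k-space, bias fields, partial volume) is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "TissueModel",
    "PairedSlice",
    "default_tissue_model",
    "generate_phantom_pair",
    "generate_dataset",
    "degrade",
]


@dataclass
class TissueModel:
    """Per-class intensity model for the two contrasts.

    ``intensity_A[k]`` / ``intensity_B[k]`` give the mean intensity of tissue
    class ``k`` (labels 1..K; background is 0) in domain A (T2W-like) and
    domain B (FLAIR-like).  ``noise_sigma`` is the standard deviation of the
    additive Gaussian acquisition noise, in intensity units.
    """

    intensity_A: dict[int, float]
    intensity_B: dict[int, float]
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.intensity_A) != set(self.intensity_B):
            raise ValueError("intensity_A and intensity_B must cover the same classes")
        for table in (self.intensity_A, self.intensity_B):
            for k, v in table.items():
                if k < 1:
                    raise ValueError(f"tissue labels must be >= 1, got {k}")
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"class {k} intensity {v} outside [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PairedSlice:
    """One aligned (image_A, image_B, mask) triple — the unit of training
    and evaluation."""

    image_A: np.ndarray
    image_B: np.ndarray
    mask: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        if not (self.image_A.shape == self.image_B.shape == self.mask.shape):
            raise ValueError("image_A, image_B and mask must share one shape")
        if not self.mask.any():
            raise ValueError("mask must contain at least one foreground pixel")


#: Default 4-class model: 1 = outer tissue, 2 = white-matter-like band,
#: 3 = central fluid-like region (bright in A, suppressed in B), 4 = lesion.
def default_tissue_model(noise_sigma: float = 0.02, seed: int = 0) -> TissueModel:
    return TissueModel(
        intensity_A={1: 0.45, 2: 0.35, 3: 0.90, 4: 0.75},
        intensity_B={1: 0.50, 2: 0.40, 3: 0.10, 4: 0.85},
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _ellipse(shape: tuple[int, int], center, semi, angle: float = 0.0) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / semi[0]) ** 2 + (v / semi[1]) ** 2 <= 1.0


def _label_map(size: int, rng: np.random.Generator, labels: list[int]) -> np.ndarray:
    """Nested elliptical tissue regions with randomized geometry."""
    c = size / 2.0
    jitter = rng.uniform(-0.03, 0.03, size=2) * size
    center = (c + jitter[0], c + jitter[1])
    angle = rng.uniform(0, np.pi)
    brain_semi = (size * rng.uniform(0.36, 0.42), size * rng.uniform(0.30, 0.36))

    region = np.zeros((size, size), dtype=np.int32)
    brain = _ellipse((size, size), center, brain_semi, angle)
    region[brain] = labels[0]
    if len(labels) > 1:
        wm = _ellipse(
            (size, size), center, (brain_semi[0] * 0.72, brain_semi[1] * 0.70), angle
        )
        region[wm] = labels[1]
    if len(labels) > 2:
        fluid = _ellipse(
            (size, size), center, (brain_semi[0] * 0.28, brain_semi[1] * 0.24), angle
        )
        region[fluid] = labels[2]
    if len(labels) > 3 and rng.random() < 0.7:
        # lesion blob somewhere in the white-matter band
        theta = rng.uniform(0, 2 * np.pi)
        r = 0.5 * (brain_semi[0] * 0.72 + brain_semi[0] * 0.28)
        lc = (center[0] + r * np.cos(theta) * 0.7, center[1] + r * np.sin(theta) * 0.7)
        semi = (size * rng.uniform(0.04, 0.08), size * rng.uniform(0.04, 0.08))
        lesion = _ellipse((size, size), lc, semi, rng.uniform(0, np.pi))
        region[lesion & (region > 0)] = labels[3]
    return region


def generate_phantom_pair(
    size: int, tissue: TissueModel, id: str = "phantom", randomize_geometry: bool = True
) -> PairedSlice:
    """Generate one aligned pseudo-T2W / pseudo-FLAIR pair.

    Deterministic given ``tissue.seed``.  ``size`` is the canvas side in
    pixels (>= 16); the brain mask is the set of nonzero tissue labels.
    """
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    rng = np.random.default_rng(tissue.seed)
    labels = sorted(tissue.intensity_A)
    if randomize_geometry:
        region = _label_map(size, rng, labels)
    else:
        region = np.zeros((size, size), dtype=np.int32)
        c = size / 2.0
        region[_ellipse((size, size), (c, c), (size * 0.4, size * 0.33))] = labels[0]
        for i, lab in enumerate(labels[1:3], start=1):
            shrink = 0.72**i
            region[
                _ellipse((size, size), (c, c), (size * 0.4 * shrink, size * 0.33 * shrink))
            ] = lab
    mask = (region > 0).astype(np.uint8)
    if not mask.any():
        raise ValueError("degenerate geometry produced an empty mask")

    lut_A = np.zeros(max(labels) + 1)
    lut_B = np.zeros(max(labels) + 1)
    for k in labels:
        lut_A[k] = tissue.intensity_A[k]
        lut_B[k] = tissue.intensity_B[k]
    image_A = lut_A[region]
    image_B = lut_B[region]
    if tissue.noise_sigma > 0:
        image_A = image_A + rng.normal(0, tissue.noise_sigma, region.shape) * mask
        image_B = image_B + rng.normal(0, tissue.noise_sigma, region.shape) * mask
    image_A = np.clip(image_A, 0.0, 1.0)
    image_B = np.clip(image_B, 0.0, 1.0)
    return PairedSlice(image_A=image_A, image_B=image_B, mask=mask, id=id)


def generate_dataset(
    n_pairs: int,
    size: int = 64,
    base_seed: int = 0,
    noise_sigma: float = 0.02,
    tissue: TissueModel | None = None,
) -> list[PairedSlice]:
    """Generate ``n_pairs`` phantoms with per-slice seeds ``base_seed + i``."""
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    out = []
    for i in range(n_pairs):
        base = tissue or default_tissue_model(noise_sigma=noise_sigma)
        t = TissueModel(
            intensity_A=dict(base.intensity_A),
            intensity_B=dict(base.intensity_B),
            noise_sigma=base.noise_sigma,
            seed=base_seed + i,
        )
        out.append(generate_phantom_pair(size, t, id=f"pair{i:04d}"))
    return out


def degrade(image: np.ndarray, level: float, seed: int = 0) -> np.ndarray:
    """Blend an image with a smoothed copy and additive noise, both scaled
    by ``level`` in [0, 1].  ``level=0`` returns the input unchanged.

    Used to manufacture "synthetic-quality" surrogates with a controllable
    distance from the originals.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"level must be in [0, 1], got {level}")
    if level == 0.0:
        return image.copy()
    rng = np.random.default_rng(seed)
    smoothed = ndimage.gaussian_filter(image.astype(float), sigma=1.5 * level)
    blended = (1.0 - level) * image + level * smoothed
    noisy = blended + level * 0.08 * rng.standard_normal(image.shape)
    return np.clip(noisy, 0.0, 1.0)
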