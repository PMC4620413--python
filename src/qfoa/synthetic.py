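"""Synthetic stand-ins for the non-public CT feature data.

Two generators are provided.  ``generate_feature_dataset`` emits Gaussian
class-conditional feature tables with the size and class imbalance of the
study cohort (17/41 positive/negative training samples, 16/40 test samples —
33 positive and 81 negative in total) and a single difficulty knob, the
separation between the class means in units of the within-class standard
deviation.  ``generate_texture_images`` is a toy texture front-end: smooth
low-frequency fields for the healthy class and rough high-frequency fields
for the disease class, from which ``extract_gray_fractal_features`` computes
gray-level statistics and a box-counting fractal dimension, standing in for
the gray/fractal feature extraction a real CT pipeline would perform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage

from .tuning import Dataset

__all__ = [
    "SyntheticSpec",
    "GrayFractalFeatures",
    "generate_feature_dataset",
    "generate_texture_images",
    "extract_gray_fractal_features",
    "box_counting_dimension",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and difficulty of a synthetic feature cohort.

    Defaults reproduce the study cohort totals: 33 positive and 81 negative
    samples split 58 train / 56 test.  ``separation`` is the Euclidean
    distance between the class means in units of the (unit) within-class
    standard deviation; 0 makes the classes indistinguishable, 6 cleanly
    separable.
    """

    n_pos_train: int = 17
    n_neg_train: int = 41
    n_pos_test: int = 16
    n_neg_test: int = 40
    dims: int = 10
    separation: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pos_train", "n_neg_train", "n_pos_test", "n_neg_test", "dims"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


def _sample_split(
    rng: np.random.Generator, n_pos: int, n_neg: int, dims: int, offset: np.ndarray
) -> Dataset:
    pos = rng.standard_normal((n_pos, dims)) + offset
    neg = rng.standard_normal((n_neg, dims))
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)])
    return Dataset(features=X, labels=y)


def generate_feature_dataset(spec: SyntheticSpec) -> tuple[Dataset, Dataset]:
    """Draw (train, test) with Gaussian class-conditional features.

    Negatives are N(0, I); positives are N(separation * u, I) for the fixed
    unit vector u = (1,...,1)/sqrt(dims), so the stated separation is the
    exact between-mean distance.  Train and test are drawn independently from
    one seeded stream; the output is deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    u = np.ones(spec.dims) / np.sqrt(spec.dims)
    offset = spec.separation * u
    train = _sample_split(rng, spec.n_pos_train, spec.n_neg_train, spec.dims, offset)
    test = _sample_split(rng, spec.n_pos_test, spec.n_neg_test, spec.dims, offset)
    return train, test


def _to_uint8(field: np.ndarray) -> np.ndarray:
    lo, hi = field.min(), field.max()
    if hi == lo:
        return np.full(field.shape, 128, dtype=np.uint8)
    return np.round(255.0 * (field - lo) / (hi - lo)).astype(np.uint8)


def generate_texture_images(
    n_per_class: int, size: int = 128, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Generate 8-bit grayscale texture images, n per class.

    Class -1 is a smooth low-frequency field (white noise blurred with a
    Gaussian kernel, sigma = size/32); class +1 is a rough high-frequency
    field (lightly smoothed white noise).  Returns ``(images, labels)`` with
    images of shape (2*n_per_class, size, size), dtype uint8, smooth class
    first.  Deterministic per seed.
    """
    if size < 16:
        raise ValueError("size must be >= 16")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    smooth_sigma = size / 32.0
    images = []
    for _ in range(n_per_class):
        images.append(_to_uint8(ndimage.gaussian_filter(rng.standard_normal((size, size)), smooth_sigma)))
    for _ in range(n_per_class):
        images.append(_to_uint8(ndimage.gaussian_filter(rng.standard_normal((size, size)), 0.5)))
    labels = np.concatenate([-np.ones(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)])
    return np.stack(images), labels


def box_counting_dimension(mask: np.ndarray) -> float:
    """Box-counting dimension of a 2-D boolean mask.

    Counts occupied boxes at dyadic box sides 2, 4, ..., side/4 and fits
    log N(eps) against log(1/eps) by least squares.  The smallest (1-pixel)
    and largest scales are excluded from the fit: at 1 pixel the count is the
    raw foreground area and at the image scale every box is trivially
    occupied, so neither reflects the scaling region.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty 2-D array")
    if not mask.any():
        raise ValueError("mask has no foreground pixels")
    side = min(mask.shape)
    max_exp = max(int(np.floor(np.log2(side))) - 2, 1)
    sizes = [2**k for k in range(1, max_exp + 1)]
    if len(sizes) < 2:
        sizes = [1, 2]
    counts = []
    for eps in sizes:
        h = (mask.shape[0] + eps - 1) // eps
        w = (mask.shape[1] + eps - 1) // eps
        padded = np.zeros((h * eps, w * eps), dtype=bool)
        padded[: mask.shape[0], : mask.shape[1]] = mask
        blocks = padded.reshape(h, eps, w, eps).any(axis=(1, 3))
        counts.append(int(blocks.sum()))
    x = np.log(1.0 / np.asarray(sizes, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


@dataclass(frozen=True)
class GrayFractalFeatures:
    """Gray-level statistics plus fractal dimension of one image.

    ``degenerate`` flags a constant image, for which the median-threshold
    binarization has no information: the dimension is then reported for the
    full-support mask (close to 2, the dimension of a filled region).
    """

    mean_intensity: float
    std_intensity: float
    entropy_bits: float
    fractal_dimension: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mean_intensity, self.std_intensity, self.entropy_bits, self.fractal_dimension]
        )


def extract_gray_fractal_features(image: np.ndarray) -> GrayFractalFeatures:
    """Gray statistics and box-counting dimension of a grayscale image.

    Features: mean intensity, intensity standard deviation, Shannon entropy
    of the 256-bin intensity histogram in bits, and the box-counting fractal
    dimension of the image binarized at its median (pixels >= median are
    foreground; parameter-free and monotone-invariant).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    counts, _ = np.histogram(img, bins=256, range=(0, 256))
    p = counts[counts > 0] / img.size
    entropy = float(-(p * np.log2(p)).sum())
    median = np.median(img)
    mask = img >= median
    degenerate = bool(mask.all() or not mask.any())
    if degenerate:
        mask = np.ones_like(mask, dtype=bool)
    dim = box_counting_dimension(mask)
    return GrayFractalFeatures(
        mean_intensity=float(img.mean()),
        std_intensity=float(img.std()),
        entropy_bits=entropy,
        fractal_dimension=dim,
        degenerate=degenerate,
    )
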