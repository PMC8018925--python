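"""Intensity normalization transforms.

The core transform maps arbitrary T2W scanner intensities to pseudo-T2
values in milliseconds by linearly scaling the two extracted reference
intensities onto their 3 T literature T2 values:

    pT2(x,y,z) = (I - I_muscle) / (I_fat - I_muscle) * (T2_fat - T2_muscle)
                 + T2_muscle

with T2_fat = 121 ms and T2_muscle = 40 ms. A muscle-only variant scales
proportionally through the origin using the muscle ROI *mean*:

    pT2(x,y,z) = I / mean(muscle ROI) * T2_muscle

Note the deliberate asymmetry: the dual-reference map uses the 90th/10th
percentile references, the muscle-only map uses the ROI mean. Three
commonly used comparison normalizers are provided: min-max histogram
stretching, histogram equalization, and Gaussian (z-score) normalization.
All transforms here are monotone non-decreasing in the input intensity,
so voxel rank order is preserved by each of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.exposure import equalize_hist as _sk_equalize_hist

from .roi import ReferenceIntensities
from .volume_io import Volume

__all__ = [
    "TissueT2Constants",
    "ImageStats",
    "autoref_normalize",
    "muscle_normalize",
    "stretch_normalize",
    "equalize_histogram",
    "gaussian_normalize",
]


@dataclass(frozen=True)
class TissueT2Constants:
    """Literature reference-tissue T2 values at 3 T (ms).

    The prostate mean/sd are reporting aids only (the literature range
    pseudo-T2 values are compared against), never used in the transform.
    """

    t2_fat: float = 121.0
    t2_muscle: float = 40.0
    prostate_t2_mean: float = 80.0
    prostate_t2_sd: float = 34.0

    def __post_init__(self) -> None:
        if not (self.t2_fat > self.t2_muscle > 0):
            raise ValueError("require T2_fat > T2_muscle > 0")


@dataclass(frozen=True)
class ImageStats:
    """Volume-wide intensity summaries used by the comparison methods."""

    i_min: float
    i_max: float
    mu: float
    sigma: float

    @classmethod
    def of(cls, v: Volume) -> "ImageStats":
        return cls(i_min=float(v.data.min()), i_max=float(v.data.max()),
                   mu=float(v.data.mean()), sigma=float(v.data.std()))


def autoref_normalize(v: Volume, refs: ReferenceIntensities,
                      c: TissueT2Constants = TissueT2Constants(),
                      clip_negative: bool = False) -> Volume:
    """Dual-reference pseudo-T2 normalization (fat + muscle anchors).

    A strictly increasing affine map sending the muscle reference to
    T2_muscle and the fat reference to T2_fat. Voxels darker than the
    muscle reference map below 40 ms (negative values possible); they are
    kept unless ``clip_negative`` is set.
    """
    if not refs.i_fat > refs.i_muscle:
        raise ValueError("fat reference must exceed muscle reference")
    scale = (c.t2_fat - c.t2_muscle) / (refs.i_fat - refs.i_muscle)
    data = (v.data - refs.i_muscle) * scale + c.t2_muscle
    if clip_negative:
        data = np.maximum(data, 0.0)
    return replace(v, data=data, units="ms")


def muscle_normalize(v: Volume, refs: ReferenceIntensities,
                     c: TissueT2Constants = TissueT2Constants()) -> Volume:
    """Muscle-only proportional pseudo-T2 normalization.

    Scales intensities so the *mean* of the muscle ROI maps to T2_muscle;
    zero maps to zero.
    """
    if not refs.muscle_mean > 0:
        raise ValueError("muscle ROI mean must be positive")
    data = v.data / refs.muscle_mean * c.t2_muscle
    return replace(v, data=data, units="ms")


def stretch_normalize(v: Volume) -> Volume:
    """Min-max histogram stretching onto [0, 1]."""
    stats = ImageStats.of(v)
    if stats.i_max == stats.i_min:
        raise ValueError("constant volume cannot be stretched")
    data = (v.data - stats.i_min) / (stats.i_max - stats.i_min)
    return replace(v, data=data, units="au")


def equalize_histogram(v: Volume, levels: int = 64) -> Volume:
    """Histogram equalization via CDF matching at ``levels`` bins.

    A monotone non-decreasing remapping onto [0, 1] whose discrete
    histogram is as uniform as the cumulative-distribution construction
    allows. A constant volume is returned unchanged with a warning.
    """
    if v.data.max() == v.data.min():
        warnings.warn("constant volume: histogram equalization is a no-op")
        return v.copy()
    data = _sk_equalize_hist(v.data, nbins=levels)
    return replace(v, data=data, units="au")


def gaussian_normalize(v: Volume) -> Volume:
    """Z-score (Gaussian kernel) normalization: (I - mu) / sigma."""
    stats = ImageStats.of(v)
    if stats.sigma == 0:
        raise ValueError("zero-variance volume cannot be z-scored")
    data = (v.data - stats.mu) / stats.sigma
    return replace(v, data=data, units="au")
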