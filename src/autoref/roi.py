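"""Reference-tissue ROI extraction and reference intensities.

From the detector's scored rectangles, the three slices holding the
highest-probability box per tissue are selected. Inside each selected
rectangle, Otsu thresholding followed by a morphological opening (disk of
one-pixel radius) isolates the largest connected bright structure (fat) or
dark structure (muscle). The fat reference intensity is the 90th
percentile of the voxels pooled over the (up to three) fat ROIs and the
muscle reference the 10th percentile of the pooled muscle ROI voxels; the
muscle ROI mean is also recorded for the muscle-only normalization
variant.

Percentiles use the linear-interpolation convention throughout. When a
tissue yields no usable ROI, or the fat reference does not exceed the
muscle reference, the case is flagged unusable via
:class:`~autoref.errors.ExtractionError` rather than silently patched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as _cc_label
from skimage.morphology import disk, opening

from .acf import DetectionBox
from .errors import ExtractionError
from .volume_io import Volume

__all__ = [
    "ReferenceIntensities",
    "select_top_slices",
    "otsu_threshold",
    "extract_roi",
    "extract_references",
]

OTSU_BINS = 256


@dataclass
class ReferenceIntensities:
    """Extracted fat/muscle reference scalars with provenance."""

    i_fat: float  # 90th percentile of pooled fat-ROI voxels
    i_muscle: float  # 10th percentile of pooled muscle-ROI voxels
    muscle_mean: float  # mean of pooled muscle-ROI voxels
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("i_fat", "i_muscle", "muscle_mean"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")
        if not self.i_fat > self.i_muscle:
            raise ExtractionError(
                f"fat reference {self.i_fat} does not exceed muscle "
                f"reference {self.i_muscle}; case unusable")


def select_top_slices(boxes: list[DetectionBox], k: int = 3) -> list[DetectionBox]:
    """Best box of each of the ``k`` most confident slices.

    Per slice only the highest-scoring box is considered; slices are
    ranked by that score and the top ``k`` slices' boxes returned (fewer
    when fewer slices carry detections). Ties rank the lower slice first.
    """
    best: dict[int, DetectionBox] = {}
    for b in boxes:
        cur = best.get(b.slice)
        if cur is None or b.score > cur.score:
            best[b.slice] = b
    ranked = sorted(best.values(), key=lambda b: (-b.score, b.slice))
    return ranked[:k]


def otsu_threshold(values: np.ndarray) -> float:
    """Between-class-variance-maximizing threshold of a 1D sample.

    The sample is binned into a 256-bin histogram spanning its range; the
    returned threshold is the center of the bin whose split maximizes the
    between-class variance (first maximum on ties).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if np.unique(values).size < 2:
        raise ValueError("Otsu threshold undefined for a constant sample")
    counts, edges = np.histogram(values, bins=OTSU_BINS)
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = counts.astype(np.float64)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    s0 = np.cumsum(counts * centers)
    s1 = s0[-1] - s0
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = s0 / w0
        m1 = s1 / w1
        var_between = w0 * w1 * (m0 - m1) ** 2
    var_between = np.nan_to_num(var_between[:-1])
    return float(centers[int(np.argmax(var_between))])


def extract_roi(slice_image: np.ndarray, box: DetectionBox,
                polarity: str) -> np.ndarray:
    """Largest connected bright/dark structure inside a detected rectangle.

    Within the box: Otsu-threshold the intensities, keep the bright
    (above-threshold) or dark (below-threshold) side, apply a morphological
    opening with a one-pixel-radius disk, and return the largest
    8-connected component as a boolean mask in full slice coordinates.
    An all-constant box yields an empty mask with a warning.
    """
    if polarity not in ("bright", "dark"):
        raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    img = np.asarray(slice_image, dtype=np.float64)
    ny, nx = img.shape
    if not (0 <= box.y0 < box.y1 <= ny and 0 <= box.x0 < box.x1 <= nx):
        raise ValueError(f"box {box} exceeds slice bounds {img.shape}")
    patch = img[box.y0:box.y1, box.x0:box.x1]
    out = np.zeros(img.shape, dtype=bool)
    if np.unique(patch).size < 2:
        warnings.warn("constant box content: empty ROI")
        return out
    thr = otsu_threshold(patch)
    binary = patch > thr if polarity == "bright" else patch < thr
    binary = opening(binary, disk(1))
    if not binary.any():
        return out
    labels = _cc_label(binary, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = labels == int(np.argmax(sizes))
    out[box.y0:box.y1, box.x0:box.x1] = keep
    return out


def _pool_rois(v: Volume, boxes: list[DetectionBox], polarity: str):
    values, masks, slices = [], [], []
    for b in boxes:
        if not (0 <= b.slice < v.shape[0]):
            raise ValueError(f"box slice {b.slice} outside volume")
        mask = extract_roi(v.data[b.slice], b, polarity)
        if mask.any():
            values.append(v.data[b.slice][mask])
            masks.append(mask)
            slices.append(b.slice)
    return values, masks, slices


def extract_references(v: Volume, fat_boxes: list[DetectionBox],
                       muscle_boxes: list[DetectionBox]) -> ReferenceIntensities:
    """Pool ROI voxels per tissue and take the 90th/10th percentiles.

    Raises :class:`ExtractionError` when a tissue has no usable ROI or the
    references come out inconsistent (fat not brighter than muscle).
    """
    fat_vals, fat_masks, fat_slices = _pool_rois(v, fat_boxes, "bright")
    mus_vals, mus_masks, mus_slices = _pool_rois(v, muscle_boxes, "dark")
    if not fat_vals:
        raise ExtractionError("no usable fat ROI: extraction failed")
    if not mus_vals:
        raise ExtractionError("no usable muscle ROI: extraction failed")
    fat_pool = np.concatenate(fat_vals)
    mus_pool = np.concatenate(mus_vals)
    provenance = {
        "fat": {"slices": fat_slices, "boxes": fat_boxes,
                "masks": fat_masks, "n_voxels": int(fat_pool.size)},
        "muscle": {"slices": mus_slices, "boxes": muscle_boxes,
                   "masks": mus_masks, "n_voxels": int(mus_pool.size)},
    }
    return ReferenceIntensities(
        i_fat=float(np.percentile(fat_pool, 90)),
        i_muscle=float(np.percentile(mus_pool, 10)),
        muscle_mean=float(mus_pool.mean()),
        provenance=provenance)
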