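"""Preprocessing: N4 bias-field correction, percentile rescaling, resizing.

The pipeline runs, in order: N4 bias correction, clipping/division at the
volume-wide 99th percentile, and in-plane resampling of every transverse
slice to 0.5 x 0.5 mm followed by a centered crop/pad to 384 x 384 pixels.
Slice count and slice spacing are never changed.

The percentile rescale is invariant to global positive scaling of the
input, and the downstream dual-reference normalization is invariant to any
affine intensity map, so the rescale step exists to stabilize detector
features, not to normalize: its exact affine convention is immaterial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import SimpleITK as sitk
from skimage.transform import resize as _sk_resize

from .acf import DetectionBox
from .volume_io import MaskVolume, Volume

__all__ = [
    "PreprocessConfig",
    "correct_bias",
    "rescale_p99",
    "resize_inplane",
    "preprocess",
    "resize_mask_inplane",
    "inplane_grid_transform",
    "transform_box",
]


@dataclass
class PreprocessConfig:
    bias_correction: bool = True
    bias_iterations: int = 50  # per fitting level
    bias_levels: int = 3
    bias_shrink: int = 4  # in-plane shrink factor for field estimation
    rescale_percentile: float = 99.0
    target_size: tuple[int, int] = (384, 384)  # (rows, cols)
    target_spacing: tuple[float, float] = (0.5, 0.5)  # (dy, dx) mm
    interp_order: int = 1  # bilinear

    def __post_init__(self) -> None:
        if not (0.0 < self.rescale_percentile <= 100.0):
            raise ValueError("rescale percentile must lie in (0, 100]")
        if any(s <= 0 for s in self.target_size) or any(
                s <= 0 for s in self.target_spacing):
            raise ValueError("target size and spacing must be positive")


def correct_bias(v: Volume, cfg: PreprocessConfig | None = None) -> Volume:
    """Divide out a smooth multiplicative field estimated by N4.

    The field is estimated on an in-plane-shrunk copy (log-domain
    histogram sharpening with B-spline field fitting), evaluated at full
    resolution, exponentiated (hence strictly positive) and divided out of
    the original volume. A constant volume is returned unchanged with a
    warning. Non-positive inputs are shifted to positive for estimation
    only; the returned volume is the original divided by the field.
    """
    cfg = cfg or PreprocessConfig()
    data = v.data
    if data.max() == data.min():
        warnings.warn("constant volume: nothing to correct")
        return v.copy()
    shift = 0.0
    if data.min() <= 0:
        shift = 1.0 - data.min()
    img = sitk.GetImageFromArray((data + shift).astype(np.float32))
    dz, dy, dx = v.spacing
    img.SetSpacing((dx, dy, dz))
    shrink = max(1, int(cfg.bias_shrink))
    small = sitk.Shrink(img, [shrink, shrink, 1]) if shrink > 1 else img
    n4 = sitk.N4BiasFieldCorrectionImageFilter()
    n4.SetMaximumNumberOfIterations([int(cfg.bias_iterations)] * int(cfg.bias_levels))
    n4.Execute(small)
    log_field = sitk.GetArrayFromImage(n4.GetLogBiasFieldAsImage(img))
    field = np.exp(log_field.astype(np.float64))
    return replace(v, data=data / field)


def rescale_p99(v: Volume, cfg: PreprocessConfig | None = None) -> Volume:
    """Clip at the volume-wide 99th percentile, then divide by it.

    Linear-interpolation percentile convention. The transform is monotone
    non-decreasing and maps the volume into ``[min(v)/p99, 1]``.
    """
    cfg = cfg or PreprocessConfig()
    p = float(np.percentile(v.data, cfg.rescale_percentile))
    if p <= 0:
        raise ValueError(f"non-positive {cfg.rescale_percentile}th percentile {p}")
    return replace(v, data=np.minimum(v.data, p) / p)


def _crop_pad_1d(n: int, target: int) -> tuple[slice, tuple[int, int]]:
    """Centered crop slice and pad widths for one axis.

    Odd differences put the extra cropped/padded pixel on the high-index
    side (posterior rows / display-left columns).
    """
    if n >= target:
        extra = n - target
        lo = extra // 2
        return slice(lo, lo + target), (0, 0)
    extra = target - n
    lo = extra // 2
    return slice(0, n), (lo, extra - lo)


def _resize_slices(data: np.ndarray, spacing, cfg: PreprocessConfig,
                   order: int) -> np.ndarray:
    nz, ny, nx = data.shape
    _, dy, dx = spacing
    ty, tx = cfg.target_spacing
    ny_r = int(round(ny * dy / ty))
    nx_r = int(round(nx * dx / tx))
    out_rows, out_cols = cfg.target_size
    ry, py = _crop_pad_1d(ny_r, out_rows)
    rx, px = _crop_pad_1d(nx_r, out_cols)
    out = np.zeros((nz, out_rows, out_cols), dtype=np.float64)
    for z in range(nz):
        sl = data[z]
        if (ny_r, nx_r) != (ny, nx):
            sl = _sk_resize(sl, (ny_r, nx_r), order=order,
                            anti_aliasing=False, preserve_range=True)
        sl = sl[ry, rx]
        if py != (0, 0) or px != (0, 0):
            sl = np.pad(sl, (py, px))
        out[z] = sl
    return out


def resize_inplane(v: Volume, cfg: PreprocessConfig | None = None) -> Volume:
    """Resample slices to the target in-plane grid (default 384x384 @ 0.5 mm).

    Bilinear by default; slice count and dz are unchanged; physical extent
    is preserved by the resampling and adjusted only by the centered
    crop/pad to the fixed matrix size.
    """
    cfg = cfg or PreprocessConfig()
    dz = v.spacing[0]
    if (v.shape[1:] == cfg.target_size
            and v.spacing[1:] == tuple(cfg.target_spacing)):
        return v.copy()
    data = _resize_slices(v.data, v.spacing, cfg, cfg.interp_order)
    return replace(v, data=data,
                   spacing=(dz, cfg.target_spacing[0], cfg.target_spacing[1]))


def resize_mask_inplane(m: MaskVolume, cfg: PreprocessConfig | None = None) -> MaskVolume:
    """Nearest-neighbour analogue of :func:`resize_inplane` for masks."""
    cfg = cfg or PreprocessConfig()
    spacing3 = m.spacing
    if (m.shape[1:] == cfg.target_size and spacing3[1:] == tuple(cfg.target_spacing)):
        return MaskVolume(m.data.copy(), m.spacing, label=m.label)
    data = _resize_slices(m.data.astype(np.float64), spacing3, cfg, order=0)
    return MaskVolume((data > 0.5).astype(np.uint8),
                      (spacing3[0],) + tuple(cfg.target_spacing), label=m.label)


def preprocess(v: Volume, cfg: PreprocessConfig | None = None) -> Volume:
    """Full preprocessing: bias correction -> percentile rescale -> resize."""
    cfg = cfg or PreprocessConfig()
    if cfg.bias_correction:
        v = correct_bias(v, cfg)
    v = rescale_p99(v, cfg)
    return resize_inplane(v, cfg)


# ---------------------------------------------------------------------------
# Coordinate bookkeeping for annotations


def inplane_grid_transform(shape, spacing, cfg: PreprocessConfig | None = None):
    """Map original in-plane pixel coords to preprocessed-grid coords.

    Returns ``(sy, sx, oy, ox)`` such that a point at row ``y``/col ``x``
    of the original slice lands at ``y * sy + oy`` / ``x * sx + ox``.
    """
    cfg = cfg or PreprocessConfig()
    _, ny, nx = shape
    _, dy, dx = spacing
    ty, tx = cfg.target_spacing
    sy, sx = dy / ty, dx / tx
    ny_r, nx_r = int(round(ny * sy)), int(round(nx * sx))
    ry, py = _crop_pad_1d(ny_r, cfg.target_size[0])
    rx, px = _crop_pad_1d(nx_r, cfg.target_size[1])
    oy = py[0] - ry.start
    ox = px[0] - rx.start
    return sy, sx, oy, ox


def transform_box(box: DetectionBox, transform) -> DetectionBox:
    """Apply an in-plane grid transform to a box's pixel bounds."""
    sy, sx, oy, ox = transform
    return DetectionBox(
        box.slice,
        int(round(box.x0 * sx + ox)), int(round(box.y0 * sy + oy)),
        int(round(box.x1 * sx + ox)), int(round(box.y1 * sy + oy)),
        score=box.score, tissue=box.tissue)
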