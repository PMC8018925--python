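"""Reading, writing and reorienting 3D scalar volumes and binary masks.

Volumes are held as ``(z, y, x)`` arrays with spacing ``(dz, dy, dx)`` in mm.
The canonical anatomical frame used by the rest of the pipeline is the ITK
LPS convention viewed slice-wise:

* slice index ``z`` increases inferior -> superior,
* row index ``y`` increases anterior -> posterior (posterior tissue sits in
  the bottom rows of a displayed transverse slice),
* column index ``x`` increases patient-right -> patient-left.

All supported formats (MetaImage, NIfTI-1, DICOM series) go through
SimpleITK, which exposes direction cosines uniformly; reorientation is a
pure axis permutation/flip, so the voxel multiset is preserved exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

from .errors import FormatError, OrientationError, SeriesError

__all__ = [
    "Volume",
    "MaskVolume",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "reorient_canonical",
]

_IDENTITY = np.eye(3)


@dataclass
class Volume:
    """A 3D scalar image.

    Parameters
    ----------
    data:
        ``(nz, ny, nx)`` array of finite scalars.
    spacing:
        ``(dz, dy, dx)`` voxel spacing in mm, all strictly positive.
    units:
        ``"au"`` for arbitrary scanner units, ``"ms"`` for pseudo-T2 maps.
    canonical:
        True once the volume satisfies the canonical-frame convention.
    direction:
        Optional 3x3 direction-cosine matrix (ITK order, rows = physical
        axes) describing the on-disk orientation; ``None`` when unknown.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    units: str = "au"
    canonical: bool = False
    direction: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        if self.units not in ("au", "ms"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())


@dataclass
class MaskVolume:
    """A binary mask paired with a :class:`Volume` of identical shape."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    label: str = "whole-prostate"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        uniq = np.unique(self.data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _sidecar_path(path: str) -> str:
    return str(path) + ".units.json"


def _from_sitk(img: sitk.Image) -> Volume:
    data = sitk.GetArrayFromImage(img).astype(np.float64)
    # SimpleITK spacing is (dx, dy, dz); arrays come back (z, y, x).
    sx, sy, sz = img.GetSpacing()
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    canonical = np.allclose(direction, _IDENTITY, atol=1e-6)
    return Volume(
        data=data,
        spacing=(sz, sy, sx),
        units="au",
        canonical=canonical,
        direction=direction,
    )


def _to_sitk(v: Volume, dtype) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.astype(dtype)))
    dz, dy, dx = v.spacing
    img.SetSpacing((dx, dy, dz))
    if v.direction is not None:
        img.SetDirection(tuple(v.direction.ravel()))
    return img


def _read_dicom_series(path: str) -> sitk.Image:
    reader = sitk.ImageSeriesReader()
    names = reader.GetGDCMSeriesFileNames(str(path))
    if not names:
        raise FormatError(f"no DICOM series found under {path}")
    # Reject series whose per-file geometry disagrees before stacking.
    spacings, orients = set(), set()
    for name in names:
        fr = sitk.ImageFileReader()
        fr.SetFileName(name)
        fr.ReadImageInformation()
        spacings.add(tuple(round(s, 6) for s in fr.GetSpacing()[:2]))
        orients.add(tuple(round(d, 6) for d in fr.GetDirection()))
    if len(spacings) > 1 or len(orients) > 1:
        raise SeriesError(f"inconsistent DICOM series under {path}: "
                          f"{len(spacings)} spacings, {len(orients)} orientations")
    reader.SetFileNames(names)
    return reader.Execute()


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a MetaImage/NIfTI volume or a DICOM-series directory.

    DICOM rescale slope/intercept are applied by the reader. Units default
    to ``"au"`` unless a sidecar written by :func:`write_volume` is present.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file or directory: {path}")
    try:
        if os.path.isdir(path):
            img = _read_dicom_series(path)
        else:
            img = sitk.ReadImage(path)
    except (SeriesError, FormatError):
        raise
    except RuntimeError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    v = _from_sitk(img)
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
        v.units = meta.get("units", v.units)
    return v


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a volume as 32-bit float MetaImage or NIfTI.

    Non-default units are recorded in a small JSON sidecar next to the
    image so that ``read_volume`` can restore them.
    """
    path = str(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    img = _to_sitk(v, np.float32)
    try:
        sitk.WriteImage(img, path)
    except RuntimeError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
    if v.units != "au":
        with open(_sidecar_path(path), "w") as fh:
            json.dump({"units": v.units}, fh)


def read_mask(path: str | os.PathLike, label: str = "whole-prostate") -> MaskVolume:
    v = read_volume(path)
    return MaskVolume(data=(v.data > 0.5).astype(np.uint8), spacing=v.spacing, label=label)


def write_mask(m: MaskVolume, path: str | os.PathLike) -> None:
    v = Volume(data=m.data.astype(np.float64), spacing=m.spacing, canonical=True)
    img = _to_sitk(v, np.uint8)
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def reorient_canonical(v: Volume) -> Volume:
    """Reorient a volume into the canonical LPS-slicewise frame.

    Idempotent; a pure permutation/flip of the voxel grid. Raises
    :class:`OrientationError` when no direction metadata is available and
    the caller has not asserted ``canonical=True``.
    """
    if v.canonical:
        return v
    if v.direction is None:
        raise OrientationError(
            "volume has no orientation metadata; construct it with "
            "canonical=True to assert the frame explicitly")
    img = _to_sitk(v, np.float64)
    try:
        img = sitk.DICOMOrient(img, "LPS")
    except RuntimeError as exc:
        raise OrientationError(f"ambiguous orientation: {exc}") from exc
    out = _from_sitk(img)
    out.units = v.units
    if not out.canonical:
        raise OrientationError("direction matrix is not axis-aligned")
    return out
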