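"""Synthetic pelvic T2W phantoms with ground truth.

Each phantom case emulates the structures the normalization pipeline relies
on: an ellipsoidal prostate near the volume center, a dark levator-ani
muscle band posterior to it (inside the muscle focus region), and a bright
posterior subcutaneous fat pad (inside the fat focus region), on a
moderately bright pelvic background. Intensities are corrupted the way
scanner data are: a smooth multiplicative bias field, then a per-case
random gain/offset (scanner & protocol variation), then additive Gaussian
noise. All realized parameters are recorded so tests can compare pipeline
output against the truth.

The prostate's intensity is, by default, *anchored*: it is placed on the
fat/muscle-anchored linear intensity axis at the position corresponding to
its nominal T2, so a correct dual-reference normalization must recover the
encoded prostate T2 from the arbitrary-unit volume.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .acf import DetectionBox, FAT_REGION, MUSCLE_REGION, focus_region_bounds
from .errors import SpecError
from .volume_io import MaskVolume, Volume, write_mask, write_volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
    "case_seed",
    "write_phantom_case",
]

TISSUES = ("background", "prostate", "fat", "muscle")


@dataclass
class PhantomSpec:
    """Parameters of the synthetic pelvic phantom.

    Intensity means/sds are in arbitrary units; the sd is the case-to-case
    variability of the realized tissue mean, not voxel noise (voxel noise
    is ``noise_sd``). ``prostate_mean=None`` (the default) anchors the
    prostate on the fat/muscle intensity axis at ``t2_prostate``.
    """

    shape: tuple[int, int, int] = (24, 192, 192)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)  # mm

    background_mean: float = 300.0
    background_sd: float = 15.0
    muscle_mean: float = 120.0
    muscle_sd: float = 6.0
    fat_mean: float = 900.0
    fat_sd: float = 45.0
    prostate_mean: float | None = None  # None -> anchored at t2_prostate
    prostate_sd: float = 20.0

    t2_fat: float = 121.0  # ms, 3 T literature value
    t2_muscle: float = 40.0
    t2_prostate: float = 80.0

    bias_amplitude: float = 0.2  # max multiplicative deviation
    noise_sd: float = 10.0  # au
    rician_noise: bool = False

    gain_range: tuple[float, float] = (0.7, 1.3)
    offset_range: tuple[float, float] = (-30.0, 30.0)
    geom_jitter_px: int = 4
    radius_jitter_frac: float = 0.08

    def __post_init__(self) -> None:
        if not (self.fat_mean > self.background_mean > self.muscle_mean):
            raise SpecError("require fat mean > background mean > muscle mean")
        for sd in (self.background_sd, self.muscle_sd, self.fat_sd,
                   self.prostate_sd, self.noise_sd):
            if sd < 0:
                raise SpecError("standard deviations must be >= 0")
        if not (0.0 <= self.bias_amplitude <= 0.5):
            raise SpecError("bias amplitude must lie in [0, 0.5]")
        nz, ny, nx = self.shape
        if nz < 8 or ny < 64 or nx < 64:
            raise SpecError(f"grid {self.shape} too small for the phantom anatomy")


@dataclass
class PhantomTruth:
    """Realized per-case parameters."""

    means: dict  # tissue -> realized mean intensity (pre-bias, pre-jitter)
    gain: float
    offset: float
    true_t2: dict  # tissue -> encoded T2 in ms (prostate: implied by means)
    bias_amplitude: float
    noise_sd: float


@dataclass
class PhantomCase:
    volume: Volume
    masks: dict  # tissue -> MaskVolume
    boxes: dict = field(default_factory=dict)  # tissue -> [DetectionBox]
    truth: PhantomTruth | None = None


def _smooth_bias_field(shape, amplitude: float, rng: np.random.Generator):
    if amplitude == 0:
        return np.ones(shape)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=(2.0, 24.0, 24.0), mode="nearest")
    lo, hi = smooth.min(), smooth.max()
    if hi == lo:
        return np.ones(shape)
    return 1.0 - amplitude + (smooth - lo) / (hi - lo) * 2.0 * amplitude


def _jitter(rng: np.random.Generator, j: int) -> int:
    return int(rng.integers(-j, j + 1)) if j > 0 else 0


def _band_boxes(mask: np.ndarray, tissue: str) -> list[DetectionBox]:
    """Tight per-slice bounding boxes of a tissue mask."""
    boxes = []
    for z in range(mask.shape[0]):
        ys, xs = np.nonzero(mask[z])
        if ys.size == 0:
            continue
        boxes.append(DetectionBox(z, int(xs.min()), int(ys.min()),
                                  int(xs.max()) + 1, int(ys.max()) + 1,
                                  score=1.0, tissue=tissue))
    return boxes


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomCase:
    """Render one phantom case deterministically from ``(spec, seed)``."""
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.shape

    # realized tissue means (case-to-case biological/protocol variation)
    means = {
        "background": spec.background_mean + spec.background_sd * rng.standard_normal(),
        "muscle": spec.muscle_mean + spec.muscle_sd * rng.standard_normal(),
        "fat": spec.fat_mean + spec.fat_sd * rng.standard_normal(),
    }
    t2f, t2m = spec.t2_fat, spec.t2_muscle
    if spec.prostate_mean is None:
        # place the prostate on the fat/muscle-anchored intensity axis
        frac = (spec.t2_prostate - t2m) / (t2f - t2m)
        means["prostate"] = means["muscle"] + frac * (means["fat"] - means["muscle"])
        t2_prostate = spec.t2_prostate
    else:
        means["prostate"] = spec.prostate_mean + spec.prostate_sd * rng.standard_normal()
        t2_prostate = (t2m + (means["prostate"] - means["muscle"])
                       / (means["fat"] - means["muscle"]) * (t2f - t2m))

    jp = spec.geom_jitter_px
    rj = spec.radius_jitter_frac

    # prostate: ellipsoid slightly anterior of center
    cz = nz / 2.0 + _jitter(rng, 1)
    cy = 0.42 * ny + _jitter(rng, jp)
    cx = 0.50 * nx + _jitter(rng, jp)
    radii = np.array([0.25 * nz, 0.115 * ny, 0.18 * nx])
    radii *= rng.uniform(1.0 - rj, 1.0 + rj, size=3) if rj > 0 else 1.0
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    prostate = (((zz - cz) / radii[0]) ** 2 + ((yy - cy) / radii[1]) ** 2
                + ((xx - cx) / radii[2]) ** 2) <= 1.0

    # muscle band: posterior to the prostate, inside the muscle focus region
    (mz0, mz1), (my0, my1) = focus_region_bounds(MUSCLE_REGION, nz, ny)
    m_rows = (int(0.625 * ny) + _jitter(rng, jp), int(0.710 * ny) + _jitter(rng, jp))
    m_cols_c = nx // 2 + _jitter(rng, 2 * jp)
    m_half_w = int(0.105 * nx)
    m_slices = (mz0 + 1 + _jitter(rng, 1), mz1 - 1 + _jitter(rng, 1))
    muscle = np.zeros(spec.shape, dtype=bool)
    muscle[m_slices[0]:m_slices[1], m_rows[0]:m_rows[1],
           m_cols_c - m_half_w:m_cols_c + m_half_w] = True

    # fat pad: posterior subcutaneous, inside the fat focus region
    (fz0, fz1), (fy0, fy1) = focus_region_bounds(FAT_REGION, nz, ny)
    f_rows = (int(0.80 * ny) + _jitter(rng, jp), int(0.92 * ny) + _jitter(rng, jp))
    f_cols_c = nx // 2 + _jitter(rng, 2 * jp)
    f_half_w = int(0.13 * nx)
    fat = np.zeros(spec.shape, dtype=bool)
    fat[fz0:fz1, f_rows[0]:f_rows[1],
        f_cols_c - f_half_w:f_cols_c + f_half_w] = True

    # enforce disjointness (prostate has priority, then muscle)
    muscle &= ~prostate
    fat &= ~prostate & ~muscle
    for name, m in (("prostate", prostate), ("muscle", muscle), ("fat", fat)):
        if not m.any():
            raise SpecError(f"{name} mask is empty on grid {spec.shape}")

    img = np.full(spec.shape, means["background"], dtype=np.float64)
    img[prostate] = means["prostate"]
    img[muscle] = means["muscle"]
    img[fat] = means["fat"]

    img *= _smooth_bias_field(spec.shape, spec.bias_amplitude, rng)
    gain = float(rng.uniform(*spec.gain_range))
    offset = float(rng.uniform(*spec.offset_range))
    img = gain * img + offset
    if spec.noise_sd > 0:
        if spec.rician_noise:
            n1 = rng.normal(0.0, spec.noise_sd, spec.shape)
            n2 = rng.normal(0.0, spec.noise_sd, spec.shape)
            img = np.sqrt((img + n1) ** 2 + n2 ** 2)
        else:
            img = img + rng.normal(0.0, spec.noise_sd, spec.shape)

    volume = Volume(data=img, spacing=spec.spacing, units="au", canonical=True)
    masks = {name: MaskVolume(m.astype(np.uint8), spec.spacing, label=label)
             for name, m, label in (("prostate", prostate, "whole-prostate"),
                                    ("muscle", muscle, "tissue-truth"),
                                    ("fat", fat, "tissue-truth"))}
    boxes = {"fat": _band_boxes(fat, "fat"), "muscle": _band_boxes(muscle, "muscle")}
    truth = PhantomTruth(
        means=means, gain=gain, offset=offset,
        true_t2={"fat": t2f, "muscle": t2m, "prostate": float(t2_prostate)},
        bias_amplitude=spec.bias_amplitude, noise_sd=spec.noise_sd)
    return PhantomCase(volume=volume, masks=masks, boxes=boxes, truth=truth)


def case_seed(seed: int, index: int) -> int:
    """Deterministic per-case seed derived from a cohort seed."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2 ** 31))


def generate_cohort(spec: PhantomSpec, n: int, seed: int) -> list[PhantomCase]:
    """Generate ``n`` independent cases; case ``i`` depends only on (spec, seed, i)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_phantom(spec, case_seed(seed, i)) for i in range(n)]


def write_phantom_case(case: PhantomCase, out_dir: str, name: str) -> None:
    """Write one case: volume + masks (MetaImage), truth JSON, boxes CSV."""
    os.makedirs(out_dir, exist_ok=True)
    write_volume(case.volume, os.path.join(out_dir, f"{name}.mhd"))
    for tissue, mask in case.masks.items():
        write_mask(mask, os.path.join(out_dir, f"{name}_{tissue}_mask.mhd"))
    if case.truth is not None:
        with open(os.path.join(out_dir, f"{name}_truth.json"), "w") as fh:
            json.dump(asdict(case.truth), fh, indent=2)
    with open(os.path.join(out_dir, f"{name}_boxes.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case", "tissue", "slice", "x0", "y0", "x1", "y1"])
        for tissue, boxes in case.boxes.items():
            for b in boxes:
                writer.writerow([name, tissue, b.slice, b.x0, b.y0, b.x1, b.y1])
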