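"""End-to-end pipeline wiring and run configuration.

One entry point, :func:`run_pipeline`, executes preprocessing, fat/muscle
rectangle detection, top-3 slice selection, ROI extraction and the chosen
normalization, and returns the normalized volume together with a
provenance record (selected slices and boxes, reference intensities,
config hash, seed) sufficient to re-derive the references from the
preprocessed volume.
"""

from __future__ import annotations

import csv
import glob
import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, fields

from . import acf
from .errors import AutoRefError, ConfigError, TrainingError
from .normalize import (TissueT2Constants, autoref_normalize, equalize_histogram,
                        gaussian_normalize, muscle_normalize, stretch_normalize)
from .preprocess import (PreprocessConfig, inplane_grid_transform, preprocess,
                         transform_box)
from .roi import extract_references, select_top_slices
from .volume_io import Volume, read_volume, reorient_canonical

log = logging.getLogger("autoref")

METHODS = ("autoref", "muscle", "stretch", "histeq", "gaussian")

__all__ = ["RunConfig", "run_pipeline", "load_annotated_cases",
            "prepare_training_cases", "METHODS"]


def _from_dict(cls, d: dict):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(d, dict):
        raise ConfigError(f"expected mapping for {cls.__name__}, got {type(d).__name__}")
    names = {f.name for f in fields(cls)}
    unknown = sorted(set(d) - names)
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {unknown}")
    return cls(**d)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    constants: TissueT2Constants = field(default_factory=TissueT2Constants)
    detector: acf.DetectorConfig = field(default_factory=acf.DetectorConfig)
    fat_model: str | None = None
    muscle_model: str | None = None
    method: str = "autoref"
    top_k: int = 3
    clip_negative: bool = False
    histeq_levels: int = 64
    n_bins: int = 100
    cv_iters: int = 10
    cv_folds: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("preprocess", PreprocessConfig),
                         ("constants", TissueT2Constants),
                         ("detector", acf.DetectorConfig)):
            if key in d and isinstance(d[key], dict):
                if key == "detector" and "scales" in d[key]:
                    d[key]["scales"] = tuple(d[key]["scales"])
                d[key] = _from_dict(sub, d[key])
        return _from_dict(cls, d)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)

    def config_hash(self) -> str:
        def default(o):
            return sorted(o) if isinstance(o, set) else str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _box_record(b: acf.DetectionBox) -> dict:
    return {"slice": b.slice, "x0": b.x0, "y0": b.y0, "x1": b.x1,
            "y1": b.y1, "score": b.score, "tissue": b.tissue}


def _load_model(path: str | None, tissue: str) -> acf.DetectorModel:
    if path is None or not os.path.exists(path or ""):
        raise ConfigError(f"{tissue} detector model not found: {path!r}")
    return acf.DetectorModel.load(path)


def run_pipeline(volume: Volume | str, cfg: RunConfig):
    """Run preprocessing, detection, ROI extraction and normalization.

    ``volume`` may be a :class:`Volume` or a path. Returns
    ``(normalized_volume, provenance)``; any stage failure raises a
    stage-tagged :class:`~autoref.errors.AutoRefError` subclass.
    """
    t_start = time.perf_counter()
    if isinstance(volume, str):
        volume = read_volume(volume)
    if not volume.canonical:
        volume = reorient_canonical(volume)

    provenance: dict = {"method": cfg.method, "seed": cfg.seed,
                        "config_hash": cfg.config_hash(), "timings_s": {}}

    t0 = time.perf_counter()
    pre = preprocess(volume, cfg.preprocess)
    provenance["timings_s"]["preprocess"] = round(time.perf_counter() - t0, 3)
    log.info("preprocess done in %.2fs", time.perf_counter() - t0)

    if cfg.method in ("autoref", "muscle"):
        fat_model = _load_model(cfg.fat_model, "fat")
        muscle_model = _load_model(cfg.muscle_model, "muscle")
        t0 = time.perf_counter()
        fat_boxes = select_top_slices(acf.detect(pre, fat_model), cfg.top_k)
        muscle_boxes = select_top_slices(acf.detect(pre, muscle_model), cfg.top_k)
        provenance["timings_s"]["detect"] = round(time.perf_counter() - t0, 3)
        log.info("detection done in %.2fs (%d fat, %d muscle slices)",
                 time.perf_counter() - t0, len(fat_boxes), len(muscle_boxes))
        t0 = time.perf_counter()
        refs = extract_references(pre, fat_boxes, muscle_boxes)
        provenance["timings_s"]["roi"] = round(time.perf_counter() - t0, 3)
        provenance["references"] = {"i_fat": refs.i_fat,
                                    "i_muscle": refs.i_muscle,
                                    "muscle_mean": refs.muscle_mean}
        provenance["fat"] = {"slices": refs.provenance["fat"]["slices"],
                             "boxes": [_box_record(b) for b in fat_boxes]}
        provenance["muscle"] = {"slices": refs.provenance["muscle"]["slices"],
                                "boxes": [_box_record(b) for b in muscle_boxes]}
        if cfg.method == "autoref":
            out = autoref_normalize(pre, refs, cfg.constants,
                                    clip_negative=cfg.clip_negative)
        else:
            out = muscle_normalize(pre, refs, cfg.constants)
    elif cfg.method == "stretch":
        out = stretch_normalize(pre)
    elif cfg.method == "histeq":
        out = equalize_histogram(pre, levels=cfg.histeq_levels)
    else:
        out = gaussian_normalize(pre)

    provenance["timings_s"]["total"] = round(time.perf_counter() - t_start, 3)
    provenance["units"] = out.units
    return out, provenance


# ---------------------------------------------------------------------------
# Annotated-case loading for detector training


def _read_boxes_csv(path: str) -> list[acf.DetectionBox]:
    boxes = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            boxes.append(acf.DetectionBox(
                int(row["slice"]), int(row["x0"]), int(row["y0"]),
                int(row["x1"]), int(row["y1"]), score=1.0,
                tissue=row["tissue"]))
    return boxes


def load_annotated_cases(case_dir: str):
    """Load ``(Volume, boxes)`` pairs written by the phantom writer.

    Expects ``<name>.mhd`` volumes next to ``<name>_boxes.csv`` annotation
    files with original-grid pixel coordinates.
    """
    out = []
    for csv_path in sorted(glob.glob(os.path.join(case_dir, "*_boxes.csv"))):
        name = os.path.basename(csv_path)[:-len("_boxes.csv")]
        vol_path = os.path.join(case_dir, f"{name}.mhd")
        if not os.path.exists(vol_path):
            raise ConfigError(f"annotation {csv_path} has no volume {vol_path}")
        out.append((read_volume(vol_path), _read_boxes_csv(csv_path)))
    if not out:
        raise TrainingError(f"no annotated cases found under {case_dir}")
    return out


def prepare_training_cases(cases, pre_cfg: PreprocessConfig | None = None):
    """Preprocess volumes and map annotation boxes onto the new grid.

    ``cases`` holds ``(Volume, [DetectionBox])`` pairs (or objects with
    ``volume``/``boxes`` attributes, e.g. phantom cases) with boxes in
    original pixel coordinates.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    out = []
    for case in cases:
        if hasattr(case, "volume"):
            vol = case.volume
            boxes = [b for bs in case.boxes.values() for b in bs]
        else:
            vol, boxes = case
        t = inplane_grid_transform(vol.shape, vol.spacing, pre_cfg)
        pre = preprocess(vol, pre_cfg)
        out.append((pre, [transform_box(b, t) for b in boxes]))
    return out
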