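"""Aggregate-channel-features (ACF) detection of reference-tissue rectangles.

A classic grayscale ACF detector: per-pixel feature channels (slice-
normalized intensity, gradient magnitude, six gradient-orientation bins)
are sum-pooled into 4x4 blocks, lightly smoothed, and an AdaBoost ensemble
of depth-2 decision trees scores sliding windows. Two detectors are
trained, one for the bright posterior fat pad and one for the dark levator
ani muscle band; each is restricted to an anatomically motivated focus
region (a row-fraction x slice-fraction sub-volume) so detections cannot
land on unrelated structures.

Training is two-stage: boosting on annotated positives versus random
negatives, then a retrain with hard negatives mined from the stage-1
detector's false positives. Boosting is an exhaustive SAMME AdaBoost over
256-bin-quantized features, so training is deterministic and the fitted
ensemble lives in flat numpy arrays: window scoring reduces to a handful
of shifted-plane comparisons on the aggregated channel image (no window
features are ever materialized at detection time), and serialized models
reload to bitwise-identical scores.

Intensity channels are z-scored per slice, so detector scores are
invariant to global affine intensity changes of the input: the detector
must work *before* normalization, on arbitrary scanner units.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import TrainingError
from .volume_io import Volume

__all__ = [
    "ChannelStack",
    "DetectionBox",
    "DetectorModel",
    "FocusRegion",
    "DetectorConfig",
    "FAT_REGION",
    "MUSCLE_REGION",
    "compute_channels",
    "focus_region_bounds",
    "train_detector",
    "detect",
    "nms",
    "box_iou",
    "slice_level_recall",
]

N_ORIENT = 6
N_CHANNELS = N_ORIENT + 2
AGG = 4  # aggregation block size in pixels
QBINS = 256  # feature quantization bins during boosting


@dataclass(frozen=True)
class DetectionBox:
    """A scored axis-aligned rectangle on one transverse slice.

    Pixel bounds are half-open: the box covers columns ``[x0, x1)`` and
    rows ``[y0, y1)`` of slice ``slice``.
    """

    slice: int
    x0: int
    y0: int
    x1: int
    y1: int
    score: float = 0.0
    tissue: str = "fat"

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass(frozen=True)
class FocusRegion:
    """Row-fraction x slice-fraction bounds restricting a detector."""

    tissue: str
    row_frac: tuple[float, float]
    slice_frac: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.row_frac, self.slice_frac):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"invalid fraction interval ({lo}, {hi})")


#: Fat sits in the posterior half of the image in the inferior 75% of slices.
FAT_REGION = FocusRegion("fat", row_frac=(0.5, 1.0), slice_frac=(0.0, 0.75))
#: Levator ani muscle sits in the middle (posterior-anterior) half of the
#: image in the middle (inferior-superior) half of the slices.
MUSCLE_REGION = FocusRegion("muscle", row_frac=(0.25, 0.75), slice_frac=(0.25, 0.75))


def focus_region_bounds(region: FocusRegion, nz: int, ny: int):
    """Half-open (slice range, row range) index bounds of a focus region.

    Row bounds are exact fractions of ``ny`` (the stated fractions are
    halves and quarters of the fixed 384-pixel grid); slice bounds round
    outward (ceil) so a fractional slice is still searched.
    """
    if nz < 4 or ny < 4:
        raise ValueError("grid too small for focus regions")
    z0 = math.ceil(region.slice_frac[0] * nz)
    z1 = math.ceil(region.slice_frac[1] * nz)
    y0 = int(region.row_frac[0] * ny)
    y1 = int(region.row_frac[1] * ny)
    return (z0, z1), (y0, y1)


# ---------------------------------------------------------------------------
# Channels


@dataclass
class ChannelStack:
    """Per-slice feature channels plus their 4x4 sum-pooled aggregation."""

    channels: np.ndarray  # (8, ny, nx)
    aggregated: np.ndarray  # (ny//AGG, nx//AGG, 8)


def _slice_normalize(img: np.ndarray) -> np.ndarray:
    """Z-score one slice; a flat slice maps to zeros."""
    img = np.asarray(img, dtype=np.float64)
    sd = img.std()
    if sd == 0:
        return np.zeros_like(img)
    return (img - img.mean()) / sd


def _pool(ch: np.ndarray) -> np.ndarray:
    """4x4 sum-pool each channel, then smooth with a small box filter."""
    c, ny, nx = ch.shape
    ny_t, nx_t = ny - ny % AGG, nx - nx % AGG
    ch = ch[:, :ny_t, :nx_t]
    agg = ch.reshape(c, ny_t // AGG, AGG, nx_t // AGG, AGG).sum(axis=(2, 4))
    agg = ndimage.uniform_filter(agg, size=(1, 3, 3), mode="nearest")
    return np.ascontiguousarray(agg.transpose(1, 2, 0))


def compute_channels(slice_image: np.ndarray) -> ChannelStack:
    """Compute the 8 ACF channels of one transverse slice.

    Channels: slice-normalized intensity, gradient magnitude, and six
    orientation channels that split the gradient magnitude by unsigned
    gradient orientation (soft-binned, so they sum per pixel to the
    magnitude).
    """
    img = _slice_normalize(slice_image)
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite values in slice")
    gy, gx = np.gradient(img)
    mag = np.hypot(gy, gx)
    # Unsigned orientation in [0, pi); soft assignment to 2 nearest bins.
    theta = np.mod(np.arctan2(gy, gx), np.pi)
    pos = theta / np.pi * N_ORIENT  # in [0, 6)
    b0 = np.floor(pos).astype(np.intp) % N_ORIENT
    b1 = (b0 + 1) % N_ORIENT
    w1 = pos - np.floor(pos)
    npix = img.size
    pix = np.arange(npix, dtype=np.intp)
    idx = np.concatenate([b0.ravel() * npix + pix, b1.ravel() * npix + pix])
    wts = np.concatenate([(mag * (1.0 - w1)).ravel(), (mag * w1).ravel()])
    orient = np.bincount(idx, weights=wts,
                         minlength=N_ORIENT * npix).reshape((N_ORIENT,)
                                                            + img.shape)
    channels = np.concatenate([img[None], mag[None], orient], axis=0)
    return ChannelStack(channels=channels, aggregated=_pool(channels))


# ---------------------------------------------------------------------------
# Model


@dataclass
class DetectorConfig:
    """Window geometry and boosting hyperparameters for one detector."""

    window: int = 48  # px at the 0.5 mm preprocessed grid
    scales: tuple[float, ...] = (0.75, 1.0, 1.25)
    stride: int = AGG  # one aggregated cell
    n_trees_stage1: int = 128
    n_trees_stage2: int = 256
    shrinkage: float = 0.1
    feature_fraction: float = 0.25  # feature subspace searched per tree
    score_threshold: float = 0.0
    nms_iou: float = 0.5
    neg_per_volume: int = 150
    hard_neg_cap: int = 5000
    neg_iou_max: float = 0.2
    pos_iou_min: float = 0.4  # window counts as positive above this IoU
    pos_per_batch: int = 4  # positives kept per (slice, scale)


@dataclass
class DetectorModel:
    """A trained boosted ensemble for one tissue class.

    The depth-2 trees are stored as flat padded arrays (up to 7 nodes per
    tree): ``feature``/``threshold`` at internal nodes, children indices
    (-1 at leaves) and a +/-1 leaf vote. A window's score is the SAMME
    margin ``sum(alpha_i * vote_i) / sum(alpha)``.

    The window features are the raveled ``(cells, cells, 8)`` block of the
    aggregated channel image, so feature index ``f`` unravels to a cell
    offset and channel, and grid scoring can read shifted planes of the
    aggregated image directly.
    """

    tissue: str
    config: DetectorConfig
    feature: np.ndarray  # (n_trees, 7) int
    threshold: np.ndarray  # (n_trees, 7) float
    child_left: np.ndarray  # (n_trees, 7) int, -1 at leaves
    child_right: np.ndarray  # (n_trees, 7) int
    leaf_vote: np.ndarray  # (n_trees, 7) float, +/-1 at leaves
    alpha: np.ndarray  # (n_trees,) estimator weights
    meta: dict = field(default_factory=dict)
    _cc: tuple | None = field(default=None, init=False, repr=False, compare=False)

    @property
    def cells(self) -> int:
        return self.config.window // AGG

    @property
    def n_features(self) -> int:
        return self.cells * self.cells * N_CHANNELS

    def _compiled(self):
        """Branchless per-tree constants for vectorized evaluation.

        Each depth-2 tree reduces to three tests ``V_i <= t_i`` and four
        leaf votes; absent splits get a +inf threshold so their left
        branch is always taken and carries the parent's vote.
        """
        if self._cc is None:
            cl, lv = self.child_left, self.leaf_vote
            root_leaf = cl[:, 0] < 0
            n1_leaf = root_leaf | (cl[:, 1] < 0)
            n2_leaf = root_leaf | (cl[:, 2] < 0)
            f = np.stack([self.feature[:, 0],
                          np.where(n1_leaf, 0, self.feature[:, 1]),
                          np.where(n2_leaf, 0, self.feature[:, 2])])
            t = np.stack([np.where(root_leaf, np.inf, self.threshold[:, 0]),
                          np.where(n1_leaf, np.inf, self.threshold[:, 1]),
                          np.where(n2_leaf, np.inf, self.threshold[:, 2])])
            vleft = np.where(root_leaf, lv[:, 0], lv[:, 1])
            vLL = np.where(n1_leaf, vleft, lv[:, 3])
            vLR = np.where(n1_leaf, vleft, lv[:, 4])
            vRL = np.where(n2_leaf, lv[:, 2], lv[:, 5])
            vRR = np.where(n2_leaf, lv[:, 2], lv[:, 6])
            self._cc = (f, t, np.stack([vLL, vLR, vRL, vRR]))
        return self._cc

    @staticmethod
    def _combine(d0, d1, d2, votes):
        vLL, vLR, vRL, vRR = votes[:, :, None]
        return np.where(d0, np.where(d1, vLL, vLR), np.where(d2, vRL, vRR))

    def score(self, X: np.ndarray) -> np.ndarray:
        """Ensemble margin for explicit feature rows ``X`` (n, n_features)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        f, t, votes = self._compiled()
        d0, d1, d2 = (X[:, f[i]].T <= t[i][:, None] for i in range(3))
        margins = self._combine(d0, d1, d2, votes)
        return self.alpha @ margins / self.alpha.sum()

    def score_positions(self, agg: np.ndarray, iy: np.ndarray,
                        ix: np.ndarray) -> np.ndarray:
        """Margins of selected window positions of an aggregated image.

        ``agg`` has shape ``(gy, gx, 8)``; ``(iy[k], ix[k])`` is the
        top-left aggregated cell of window ``k``. Equivalent to
        :meth:`score` on explicitly gathered windows, but each tree only
        reads the three feature planes it tests, vectorized over all
        trees at once via linear indexing.
        """
        gy, gx, nc = agg.shape
        flat = np.ascontiguousarray(agg).ravel()
        base = (iy.astype(np.int64) * gx + ix.astype(np.int64)) * nc
        f, t, votes = self._compiled()
        cy, cx, ch = np.unravel_index(f, (self.cells, self.cells, nc))
        off = (cy * gx + cx) * nc + ch  # (3, n_trees) flat offsets
        d0, d1, d2 = (flat[base[None, :] + off[i][:, None]] <= t[i][:, None]
                      for i in range(3))
        margins = self._combine(d0, d1, d2, votes)
        return self.alpha @ margins / self.alpha.sum()

    def score_grid(self, agg: np.ndarray) -> np.ndarray:
        """Margins of every window position, shaped like the position grid."""
        cells = self.cells
        npy = agg.shape[0] - cells + 1
        npx = agg.shape[1] - cells + 1
        if npy <= 0 or npx <= 0:
            return np.zeros((max(npy, 0), max(npx, 0)))
        iy, ix = np.meshgrid(np.arange(npy), np.arange(npx), indexing="ij")
        return self.score_positions(agg, iy.ravel(), ix.ravel()).reshape(npy, npx)

    # -- persistence ---------------------------------------------------
    def save(self, path: str) -> None:
        cfg = {"format": "acf-model-v1", "tissue": self.tissue,
               "config": asdict(self.config), "meta": self.meta}
        arrays = {"feature": self.feature, "threshold": self.threshold,
                  "child_left": self.child_left, "child_right": self.child_right,
                  "leaf_vote": self.leaf_vote, "alpha": self.alpha}
        blob = {"header": cfg,
                "arrays": {k: {"dtype": str(v.dtype), "shape": list(v.shape),
                               "data": v.tolist()} for k, v in arrays.items()}}
        payload = zlib.compress(json.dumps(blob, sort_keys=True).encode())
        with open(path, "wb") as fh:
            fh.write(b"ACF1" + payload)

    @classmethod
    def load(cls, path: str) -> "DetectorModel":
        with open(path, "rb") as fh:
            raw = fh.read()
        if not raw.startswith(b"ACF1"):
            raise ValueError(f"{path} is not an ACF model file")
        blob = json.loads(zlib.decompress(raw[4:]).decode())
        hdr = blob["header"]
        cfg = DetectorConfig(**{**hdr["config"],
                                "scales": tuple(hdr["config"]["scales"])})
        arrays = {k: np.array(v["data"], dtype=v["dtype"]).reshape(v["shape"])
                  for k, v in blob["arrays"].items()}
        return cls(tissue=hdr["tissue"], config=cfg, meta=hdr["meta"], **arrays)


# ---------------------------------------------------------------------------
# Exhaustive AdaBoost over quantized features

# Depth-2 node layout: 0 root, 1/2 its children, 3/4 under 1, 5/6 under 2.
_CHILDREN = {0: (1, 2), 1: (3, 4), 2: (5, 6)}


def _quantize(X: np.ndarray):
    """256-bin per-feature quantization with float split thresholds."""
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xq = np.clip(((X - lo) / span * QBINS).astype(np.int32), 0, QBINS - 1)
    return Xq, lo, span


def _node_histograms(flat: np.ndarray, w: np.ndarray, y: np.ndarray, d: int):
    """Weighted per-feature/bin histograms: (all-weight, positive-weight)."""
    idx = (flat + (y[:, None].astype(np.int64) * d * QBINS)).ravel()
    counts = np.bincount(idx, weights=np.repeat(w, d), minlength=2 * d * QBINS)
    neg = counts[:d * QBINS].reshape(d, QBINS)
    pos = counts[d * QBINS:].reshape(d, QBINS)
    return neg + pos, pos


def _best_split(w_all: np.ndarray, w_pos: np.ndarray):
    """Gini-minimizing (feature, bin) split, or None when nothing splits."""
    call = np.cumsum(w_all, axis=1)[:, :-1]
    cpos = np.cumsum(w_pos, axis=1)[:, :-1]
    tot = w_all.sum(axis=1, keepdims=True)
    totp = w_pos.sum(axis=1, keepdims=True)
    nl, pl = call, cpos
    nr, pr = tot - call, totp - cpos
    with np.errstate(invalid="ignore", divide="ignore"):
        gini = 2.0 * (pl * (nl - pl) / nl + pr * (nr - pr) / nr)
    gini = np.where((nl <= 0) | (nr <= 0), np.inf, gini)
    f, b = np.unravel_index(np.argmin(gini), gini.shape)
    if not np.isfinite(gini[f, b]):
        return None
    parent = 2.0 * totp[0, 0] * (tot[0, 0] - totp[0, 0]) / tot[0, 0] \
        if tot[0, 0] > 0 else 0.0
    if gini[f, b] >= parent - 1e-15:
        return None
    return int(f), int(b)


def _fit_adaboost(X: np.ndarray, y: np.ndarray, n_trees: int,
                  shrinkage: float, feature_fraction: float = 1.0,
                  rng: np.random.Generator | None = None):
    """SAMME AdaBoost of exhaustively grown depth-2 trees.

    Split search is exact over the 256-bin quantized feature grid
    (weighted Gini); leaves vote by weighted majority. When
    ``feature_fraction < 1`` each tree searches a random feature subspace
    (drawn from ``rng``), trading a little per-tree strength for speed the
    way randomized boosted detectors commonly do. Deterministic given the
    rng state; ties break toward the lowest feature/bin index.
    """
    n, d = X.shape
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels are single-class")
    rng = rng or np.random.default_rng(0)
    d_sub = max(1, int(round(d * feature_fraction)))
    Xq, lo, span = _quantize(X)
    offs = np.arange(d_sub, dtype=np.int32) * QBINS
    w = np.full(n, 1.0 / n)

    feature = np.zeros((n_trees, 7), dtype=np.int64)
    threshold = np.zeros((n_trees, 7))
    child_left = np.full((n_trees, 7), -1, dtype=np.int64)
    child_right = np.full((n_trees, 7), -1, dtype=np.int64)
    leaf_vote = np.zeros((n_trees, 7))
    alphas = []

    for t in range(n_trees):
        if d_sub < d:
            fsel = np.sort(rng.choice(d, size=d_sub, replace=False))
        else:
            fsel = np.arange(d)
        flat = Xq[:, fsel].astype(np.int32) + offs[None, :d_sub]
        node_of = np.zeros(n, dtype=np.intp)  # sample -> node id
        votes = np.zeros(7)
        for nd in (0, 1, 2):
            mask = node_of == nd
            if nd > 0 and child_left[t, 0] < 0:
                break  # root did not split
            if not mask.any():
                votes[nd] = -1.0
                continue
            w_all, w_pos = _node_histograms(flat[mask], w[mask], y[mask], d_sub)
            votes[nd] = 1.0 if 2.0 * w_pos.sum() > w_all.sum() else -1.0
            split = _best_split(w_all, w_pos)
            if split is None:
                continue
            f, b = split
            f_global = int(fsel[f])
            cl, cr = _CHILDREN[nd]
            feature[t, nd] = f_global
            threshold[t, nd] = lo[f_global] + (b + 1) * span[f_global] / QBINS
            child_left[t, nd], child_right[t, nd] = cl, cr
            goes_left = Xq[mask, f_global] <= b
            sub = np.flatnonzero(mask)
            node_of[sub[goes_left]] = cl
            node_of[sub[~goes_left]] = cr
        # votes at the realized leaves (children of split nodes)
        for nd in range(1, 7):
            mask = node_of == nd
            if mask.any():
                wp = w[mask & (y == 1)].sum()
                votes[nd] = 1.0 if 2.0 * wp > w[mask].sum() else -1.0
        leaf_vote[t] = votes
        pred = votes[node_of]
        y_pm = y * 2.0 - 1.0
        wrong = pred != y_pm
        err = w[wrong].sum() / w.sum()
        if err >= 0.5:
            if not alphas:
                raise TrainingError("first tree no better than chance; "
                                    "degenerate training weights")
            # truncate: this tree is discarded
            break
        # floor the error so perfectly separating trees get a finite
        # weight and boosting continues: the feature-subspace draw keeps
        # later trees diverse, which grades the ensemble margin
        err = max(err, 0.5 / n)
        a = shrinkage * math.log((1.0 - err) / err)
        alphas.append(a)
        w = w * np.exp(a * wrong)
        w /= w.sum()

    k = len(alphas)
    return (feature[:k], threshold[:k], child_left[:k], child_right[:k],
            leaf_vote[:k], np.asarray(alphas))


# ---------------------------------------------------------------------------
# Window feature extraction


@dataclass
class _GridBatch:
    """All window positions of one slice at one scale (lazy features)."""

    z: int
    scale: float
    w: int  # window side in original pixels
    agg: np.ndarray  # (gy, gx, 8) aggregated channels of the scaled slice
    cells: int
    y0: np.ndarray  # (npos,) window top in original pixel coords
    x0: np.ndarray
    grid_iy: np.ndarray  # (npos,) position row in the aggregated grid
    grid_ix: np.ndarray
    keep: np.ndarray  # (npos,) inside-focus-region mask

    def features(self, idxs: np.ndarray) -> np.ndarray:
        c = self.cells
        return np.stack([
            self.agg[self.grid_iy[i]:self.grid_iy[i] + c,
                     self.grid_ix[i]:self.grid_ix[i] + c, :].ravel()
            for i in idxs])

    def scores(self, model: "DetectorModel", idxs: np.ndarray) -> np.ndarray:
        return model.score_positions(self.agg, self.grid_iy[idxs],
                                     self.grid_ix[idxs])


def _candidate_grid(vol: Volume, region: FocusRegion, cfg: DetectorConfig,
                    cache: dict | None = None):
    """Iterate :class:`_GridBatch` over focus-region slices and scales.

    ``cache`` (keyed by ``(z, scale)``) memoizes aggregated channel
    images so repeated passes over one volume share the expensive part.
    """
    nz, ny, nx = vol.shape
    (z0, z1), (ry0, ry1) = focus_region_bounds(region, nz, ny)
    cells = cfg.window // AGG
    for z in range(z0, z1):
        sl = vol.data[z]
        if sl.std() == 0:
            continue  # degenerate slice: no structure to detect
        for scale in cfg.scales:
            agg = cache.get((z, scale)) if cache is not None else None
            if agg is None:
                img = sl
                if scale != 1.0:
                    img = _sk_resize(sl, (int(round(ny / scale)),
                                          int(round(nx / scale))),
                                     order=1, anti_aliasing=False,
                                     preserve_range=True)
                agg = compute_channels(img).aggregated
                if cache is not None:
                    cache[(z, scale)] = agg
            gy, gx = agg.shape[:2]
            npy, npx = gy - cells + 1, gx - cells + 1
            if npy <= 0 or npx <= 0:
                continue
            iy, ix = np.meshgrid(np.arange(npy), np.arange(npx), indexing="ij")
            iy, ix = iy.ravel(), ix.ravel()
            w = int(round(cfg.window * scale))
            y0 = np.round(iy * AGG * scale).astype(int)
            x0 = np.round(ix * AGG * scale).astype(int)
            keep = (y0 >= ry0) & (y0 + w <= ry1) & (x0 + w <= nx)
            yield _GridBatch(z=z, scale=scale, w=w, agg=agg, cells=cells,
                             y0=y0, x0=x0, grid_iy=iy, grid_ix=ix, keep=keep)


# ---------------------------------------------------------------------------
# Box geometry


def box_iou(a: DetectionBox, b: DetectionBox) -> float:
    """Intersection-over-union of two boxes (slice indices ignored)."""
    ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def _max_iou(y0s: np.ndarray, x0s: np.ndarray, w: int, gt_boxes) -> np.ndarray:
    """Max IoU of each square candidate window against a list of boxes."""
    best = np.zeros(len(y0s))
    for g in gt_boxes:
        ix = np.clip(np.minimum(x0s + w, g.x1) - np.maximum(x0s, g.x0), 0, None)
        iy = np.clip(np.minimum(y0s + w, g.y1) - np.maximum(y0s, g.y0), 0, None)
        inter = ix * iy
        best = np.maximum(best, inter / (w * w + g.area - inter))
    return best


def nms(boxes: list[DetectionBox], iou_threshold: float = 0.5) -> list[DetectionBox]:
    """Greedy per-slice non-maximum suppression.

    Keeps the highest-scoring box, discards boxes overlapping it with
    IoU above the threshold, and repeats. Output scores are non-increasing.
    """
    remaining = sorted(boxes, key=lambda b: (-b.score, b.slice, b.y0, b.x0))
    kept: list[DetectionBox] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [b for b in remaining if box_iou(best, b) <= iou_threshold]
    return kept


# ---------------------------------------------------------------------------
# Training


def _truth_by_slice(boxes, tissue: str) -> dict[int, list[DetectionBox]]:
    gt: dict[int, list[DetectionBox]] = {}
    for b in boxes:
        if b.tissue == tissue:
            gt.setdefault(b.slice, []).append(b)
    return gt


def _collect_training_windows(cases, tissue: str, region: FocusRegion,
                              cfg: DetectorConfig, rng: np.random.Generator,
                              caches=None):
    """One grid pass collecting positive and negative window features.

    Positives are candidate windows overlapping a ground-truth box with
    IoU >= ``pos_iou_min`` (the top few per slice and scale), so their
    features come from exactly the path detection uses. Negatives are a
    random in-focus-region draw with IoU < ``neg_iou_max``.
    """
    has_boxes = any(b.tissue == tissue for _, boxes in cases for b in boxes)
    if not has_boxes:
        raise TrainingError(f"no positive {tissue} boxes in the training set")
    pos_rows, neg_rows = [], []
    caches = caches or [None] * len(cases)
    for (vol, boxes), cache in zip(cases, caches):
        gt = _truth_by_slice(boxes, tissue)
        neg_batches = []
        for gb in _candidate_grid(vol, region, cfg, cache):
            ious = _max_iou(gb.y0, gb.x0, gb.w, gt.get(gb.z, ()))
            pos_idx = np.flatnonzero(gb.keep & (ious >= cfg.pos_iou_min))
            if len(pos_idx):
                order = pos_idx[np.argsort(-ious[pos_idx], kind="stable")]
                pos_rows.append(gb.features(order[:cfg.pos_per_batch]))
            neg_idx = np.flatnonzero(gb.keep & (ious < cfg.neg_iou_max))
            if len(neg_idx):
                # a small draw per (slice, scale) batch keeps memory flat
                take = min(len(neg_idx), 8)
                sel = rng.choice(len(neg_idx), size=take, replace=False)
                neg_batches.append(gb.features(neg_idx[np.sort(sel)]))
        if neg_batches:
            pool = np.vstack(neg_batches)
            take = min(cfg.neg_per_volume, len(pool))
            sel = rng.choice(len(pool), size=take, replace=False)
            neg_rows.append(pool[np.sort(sel)])
    if not pos_rows:
        raise TrainingError(
            f"no {tissue} candidate window reaches IoU {cfg.pos_iou_min} "
            "against the annotations; check window size and scales")
    if not neg_rows:
        raise TrainingError("could not sample any negative windows")
    return np.vstack(pos_rows), np.vstack(neg_rows)


def _mine_hard_negatives(model: DetectorModel, cases, region: FocusRegion,
                         cfg: DetectorConfig, caches=None):
    feats_acc, score_acc = [], []
    caches = caches or [None] * len(cases)
    for (vol, boxes), cache in zip(cases, caches):
        gt = _truth_by_slice(boxes, model.tissue)
        for gb in _candidate_grid(vol, region, cfg, cache):
            ok = gb.keep & (_max_iou(gb.y0, gb.x0, gb.w, gt.get(gb.z, ()))
                            < cfg.neg_iou_max)
            idxs = np.flatnonzero(ok)
            if len(idxs) == 0:
                continue
            scores = gb.scores(model, idxs)
            hot = scores > cfg.score_threshold
            if hot.any():
                feats_acc.append(gb.features(idxs[hot]))
                score_acc.append(scores[hot])
        if feats_acc and sum(map(len, score_acc)) > 4 * cfg.hard_neg_cap:
            feats_acc, score_acc = _truncate_hard(feats_acc, score_acc,
                                                  cfg.hard_neg_cap)
    if not feats_acc:
        return np.empty((0, 0))
    feats_acc, _ = _truncate_hard(feats_acc, score_acc, cfg.hard_neg_cap)
    return feats_acc[0]


def _truncate_hard(feats_acc, score_acc, cap: int):
    """Keep the ``cap`` highest-scoring hard negatives (stable order)."""
    feats = np.vstack(feats_acc)
    scores = np.concatenate(score_acc)
    order = np.sort(np.argsort(-scores, kind="stable")[:cap])
    return [feats[order]], [scores[order]]


def _fit_stage(pos: np.ndarray, neg: np.ndarray, n_trees: int,
               shrinkage: float, tissue: str, cfg: DetectorConfig,
               stage: int, seed: int) -> DetectorModel:
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    arrays = _fit_adaboost(X, y, n_trees, shrinkage, cfg.feature_fraction,
                           np.random.default_rng([seed, stage]))
    return DetectorModel(tissue, cfg, *arrays,
                         meta={"stage": stage, "seed": seed,
                               "n_pos": int(len(pos)), "n_neg": int(len(neg))})


def _region_for(tissue: str) -> FocusRegion:
    return FAT_REGION if tissue == "fat" else MUSCLE_REGION


def train_detector(cases, tissue: str, cfg: DetectorConfig | None = None,
                   seed: int = 0) -> DetectorModel:
    """Two-stage ACF training for one tissue class.

    ``cases`` is a sequence of ``(Volume, [DetectionBox])`` pairs, with
    volumes already preprocessed (384x384 in-plane) and ground-truth boxes
    in those pixel coordinates. Stage 1 boosts positives against random
    in-focus-region negatives; stage 2 retrains with hard negatives mined
    from stage-1 false positives. Deterministic for fixed inputs and seed.
    """
    cfg = cfg or DetectorConfig()
    region = _region_for(tissue)
    rng = np.random.default_rng(seed)
    caches = [{} for _ in cases]
    pos, neg = _collect_training_windows(cases, tissue, region, cfg, rng,
                                         caches)
    model1 = _fit_stage(pos, neg, cfg.n_trees_stage1, cfg.shrinkage,
                        tissue, cfg, stage=1, seed=seed)
    hard = _mine_hard_negatives(model1, cases, region, cfg, caches)
    neg2 = np.vstack([neg, hard]) if hard.size else neg
    model = _fit_stage(pos, neg2, cfg.n_trees_stage2, cfg.shrinkage,
                       tissue, cfg, stage=2, seed=seed)
    model.meta["n_hard"] = int(len(hard)) if hard.size else 0
    return model


# ---------------------------------------------------------------------------
# Detection


def detect(v: Volume, model: DetectorModel,
           region: FocusRegion | None = None,
           cache: dict | None = None) -> list[DetectionBox]:
    """Score sliding windows inside the focus region and suppress overlaps.

    The volume must be preprocessed (0.5 mm in-plane grid). Returns the
    surviving boxes of all slices, sorted by score descending; may be
    empty (e.g. on a structureless volume).
    """
    region = region or _region_for(model.tissue)
    if region.tissue != model.tissue:
        raise ValueError(f"model tissue {model.tissue!r} does not match "
                         f"region tissue {region.tissue!r}")
    cfg = model.config
    per_slice: dict[int, list[DetectionBox]] = {}
    for gb in _candidate_grid(v, region, cfg, cache):
        idxs = np.flatnonzero(gb.keep)
        if len(idxs) == 0:
            continue
        scores = gb.scores(model, idxs)
        for j in np.flatnonzero(scores > cfg.score_threshold):
            i = idxs[j]
            per_slice.setdefault(gb.z, []).append(DetectionBox(
                gb.z, int(gb.x0[i]), int(gb.y0[i]), int(gb.x0[i]) + gb.w,
                int(gb.y0[i]) + gb.w, score=float(scores[j]),
                tissue=model.tissue))
    out: list[DetectionBox] = []
    for z in sorted(per_slice):
        out.extend(nms(per_slice[z], cfg.nms_iou))
    out.sort(key=lambda b: (-b.score, b.slice, b.y0, b.x0))
    return out


def slice_level_recall(detections: list[DetectionBox],
                       truth: list[DetectionBox],
                       iou_min: float = 0.3) -> float:
    """Fraction of annotated slices whose top detection hits the truth.

    A slice counts as recalled when the highest-scoring detection on it
    overlaps that slice's ground-truth box with IoU >= ``iou_min``.
    """
    truth_by_slice: dict[int, list[DetectionBox]] = {}
    for b in truth:
        truth_by_slice.setdefault(b.slice, []).append(b)
    if not truth_by_slice:
        raise ValueError("no ground-truth boxes")
    best: dict[int, DetectionBox] = {}
    for d in detections:
        if d.slice not in best or d.score > best[d.slice].score:
            best[d.slice] = d
    hits = 0
    for z, gts in truth_by_slice.items():
        d = best.get(z)
        if d is not None and any(box_iou(d, g) >= iou_min for g in gts):
            hits += 1
    return hits / len(truth_by_slice)
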