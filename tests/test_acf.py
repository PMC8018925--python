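"""ACF channels, focus regions, boosting, detection and serialization."""

import numpy as np
import pytest

from autoref import acf
from autoref.acf import (AGG, DetectionBox, DetectorConfig, FAT_REGION,
                         MUSCLE_REGION, FocusRegion, _fit_adaboost,
                         box_iou, compute_channels, detect,
                         focus_region_bounds, nms, train_detector)
from autoref.errors import TrainingError
from autoref.volume_io import Volume


# -- channels --------------------------------------------------------------

def test_constant_image_has_flat_channels():
    st = compute_channels(np.full((32, 32), 7.0))
    # z-scoring maps a flat slice to zeros; gradients vanish
    np.testing.assert_array_equal(st.channels, 0.0)


def test_vertical_step_edge_energy_lands_in_horizontal_gradient_bin():
    img = np.zeros((8, 8))
    img[:, 4:] = 1.0
    st = compute_channels(img)
    mag = st.channels[1]
    # gradient magnitude concentrated around the step columns 3..4
    edge = mag[:, 3:5].sum()
    assert edge > 0.9 * mag.sum()
    # a horizontal gradient has orientation 0 -> first orientation bin
    orient_energy = st.channels[2:].sum(axis=(1, 2))
    assert np.argmax(orient_energy) == 0
    assert orient_energy[0] > 0.99 * orient_energy.sum()


def test_rotation_permutes_orientation_energies(rng):
    img = rng.uniform(0, 1, (40, 40))
    e = compute_channels(img).channels[2:].sum(axis=(1, 2))
    e_rot = compute_channels(np.rot90(img)).channels[2:].sum(axis=(1, 2))
    # rotating by 90 deg shifts unsigned orientation by pi/2 = 3 of 6 bins
    np.testing.assert_allclose(e_rot, np.roll(e, 3), rtol=0.05)


def test_orientation_channels_sum_to_gradient_magnitude(rng):
    st = compute_channels(rng.uniform(0, 10, (24, 24)))
    np.testing.assert_allclose(st.channels[2:].sum(axis=0), st.channels[1],
                               atol=1e-12)


def test_aggregation_shape_and_layout(rng):
    st = compute_channels(rng.uniform(0, 1, (32, 32)))
    assert st.aggregated.shape == (32 // AGG, 32 // AGG, 8)


# -- focus regions ---------------------------------------------------------

@pytest.mark.parametrize("region,nz,ny,z_exp,y_exp", [
    (FAT_REGION, 40, 384, (0, 30), (192, 384)),
    (MUSCLE_REGION, 40, 384, (10, 30), (96, 288)),
    (FAT_REGION, 4, 4, (0, 3), (2, 4)),
])
def test_focus_region_bounds(region, nz, ny, z_exp, y_exp):
    zr, yr = focus_region_bounds(region, nz, ny)
    assert zr == z_exp and yr == y_exp


def test_focus_region_validation():
    with pytest.raises(ValueError):
        FocusRegion("fat", row_frac=(0.7, 0.2), slice_frac=(0.0, 1.0))


# -- NMS -------------------------------------------------------------------

def test_nms_keeps_highest_of_identical_boxes():
    a = DetectionBox(0, 10, 10, 20, 20, score=5.0)
    b = DetectionBox(0, 10, 10, 20, 20, score=3.0)
    assert nms([a, b], 0.5) == [a]


def test_nms_keeps_disjoint_boxes():
    a = DetectionBox(0, 0, 0, 10, 10, score=2.0)
    b = DetectionBox(0, 20, 20, 30, 30, score=1.0)
    assert nms([a, b], 0.5) == [a, b]


def test_nms_overlap_chain_keeps_ends():
    # A overlaps B, B overlaps C, A and C disjoint, scores A > B > C:
    # greedy keeps A, drops B, then keeps C.
    a = DetectionBox(0, 0, 0, 10, 10, score=3.0)
    b = DetectionBox(0, 5, 0, 15, 10, score=2.0)
    c = DetectionBox(0, 10, 0, 20, 10, score=1.0)
    assert box_iou(a, b) > 0.3 and box_iou(b, c) > 0.3 and box_iou(a, c) == 0.0
    assert nms([a, b, c], 0.3) == [a, c]


def test_nms_scores_non_increasing(rng):
    boxes = [DetectionBox(0, int(x), int(y), int(x) + 12, int(y) + 12,
                          score=float(s))
             for x, y, s in zip(rng.integers(0, 50, 30),
                                rng.integers(0, 50, 30), rng.random(30))]
    out = nms(boxes, 0.5)
    scores = [b.score for b in out]
    assert scores == sorted(scores, reverse=True)


# -- boosting --------------------------------------------------------------

def _split_oracle(X, y, w):
    """Exhaustive weighted-Gini stump search over raw feature values."""
    best = (np.inf, None, None)
    for f in range(X.shape[1]):
        for thr in np.unique(X[:, f])[:-1]:
            left = X[:, f] <= thr
            gini = 0.0
            for side in (left, ~left):
                ws = w[side].sum()
                if ws == 0:
                    gini = np.inf
                    break
                p = w[side & (y == 1)].sum() / ws
                gini += 2.0 * ws * p * (1 - p)
            if gini < best[0] - 1e-12:
                best = (gini, f, thr)
    return best


def test_first_tree_root_split_matches_exhaustive_oracle(rng):
    # integer-valued features make the 256-bin quantization exact
    X = rng.integers(0, 12, size=(60, 4)).astype(float)
    y = (X[:, 2] > 5).astype(float)
    y[:4] = 1 - y[:4]  # label noise so no split is perfect
    w = np.full(len(y), 1.0 / len(y))
    _, f_star, thr_star = _split_oracle(X, y, w)
    feature, threshold, cl, cr, votes, alpha = _fit_adaboost(
        X, y, n_trees=1, shrinkage=0.1)
    assert feature[0, 0] == f_star
    # same partition: threshold falls in the same inter-value gap
    assert (X[:, f_star] <= threshold[0, 0]).sum() == (X[:, f_star] <= thr_star).sum()


def test_boosting_single_class_rejected():
    X = np.random.default_rng(0).random((20, 3))
    with pytest.raises(TrainingError):
        _fit_adaboost(X, np.ones(20), 4, 0.1)


def test_score_and_score_positions_agree(detectors, rng):
    model = detectors["fat"]
    agg = rng.standard_normal((30, 40, 8))
    iy = np.array([0, 3, 11, 17])
    ix = np.array([2, 9, 20, 25])
    c = model.cells
    gathered = np.stack([agg[i:i + c, j:j + c, :].ravel()
                         for i, j in zip(iy, ix)])
    np.testing.assert_allclose(model.score_positions(agg, iy, ix),
                               model.score(gathered), atol=1e-12)


# -- training and detection ------------------------------------------------

_SMALL_CFG = DetectorConfig(n_trees_stage1=16, n_trees_stage2=24,
                            neg_per_volume=60, hard_neg_cap=500)


def test_same_seed_retraining_is_bitwise_identical(train_cases, tmp_path):
    subset = train_cases[:4]
    a = train_detector(subset, "muscle", _SMALL_CFG, seed=5)
    b = train_detector(subset, "muscle", _SMALL_CFG, seed=5)
    for name in ("feature", "threshold", "child_left", "child_right",
                 "leaf_vote", "alpha"):
        np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
    pa, pb = tmp_path / "a.acf", tmp_path / "b.acf"
    a.save(str(pa)), b.save(str(pb))
    assert pa.read_bytes() == pb.read_bytes()


def test_training_without_positive_boxes_fails(train_cases):
    cases = [(vol, [b for b in boxes if b.tissue == "muscle"])
             for vol, boxes in train_cases[:2]]
    with pytest.raises(TrainingError):
        train_detector(cases, "fat", _SMALL_CFG, seed=0)


def test_detections_respect_focus_region(detectors, heldout_cases):
    vol, _ = heldout_cases[0]
    nz, ny, _ = vol.shape
    for tissue, region in (("fat", FAT_REGION), ("muscle", MUSCLE_REGION)):
        (z0, z1), (y0, y1) = focus_region_bounds(region, nz, ny)
        boxes = detect(vol, detectors[tissue])
        assert boxes, "expected detections on a default phantom"
        for b in boxes:
            assert z0 <= b.slice < z1
            assert y0 <= b.y0 and b.y1 <= y1
            assert 0 <= b.x0 and b.x1 <= vol.shape[2]


def test_structureless_volume_yields_no_detections(detectors):
    v = Volume(np.zeros((12, 384, 384)), (3.0, 0.5, 0.5), canonical=True)
    assert detect(v, detectors["fat"]) == []


def test_detector_scores_invariant_to_affine_intensity(detectors, heldout_cases):
    vol, _ = heldout_cases[1]
    shifted = Volume(3.1 * vol.data - 40.0, vol.spacing, canonical=True)
    assert detect(vol, detectors["fat"]) == detect(shifted, detectors["fat"])


def test_model_tissue_region_mismatch_rejected(detectors, heldout_cases):
    with pytest.raises(ValueError):
        detect(heldout_cases[0][0], detectors["fat"], MUSCLE_REGION)


def test_model_serialization_roundtrip_bitwise(detectors, tmp_path, rng):
    model = detectors["muscle"]
    path = str(tmp_path / "m.acf")
    model.save(path)
    back = acf.DetectorModel.load(path)
    X = rng.standard_normal((50, model.n_features))
    np.testing.assert_array_equal(model.score(X), back.score(X))
    assert back.config == model.config


def test_model_load_rejects_foreign_file(tmp_path):
    p = tmp_path / "bogus.acf"
    p.write_bytes(b"not a model")
    with pytest.raises(ValueError):
        acf.DetectorModel.load(str(p))
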