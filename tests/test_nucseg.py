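"""Nuclei segmentation pipeline: preprocessing, seeding, watershed, evaluation."""

import numpy as np
import pytest

from spheroquant import (
    ImageStack,
    LabelVolume,
    SegmentationParams,
    count_nuclei,
    detect_seeds,
    evaluate_segmentation,
    measure_objects,
    preprocess,
    segment_channel,
    watershed_3d,
)
from conftest import sphere_image


def to_stack(vol, pixel_size=1.0, z_step=1.0, name="DRAQ5"):
    return ImageStack(vol[None].astype(np.uint16), z_step, pixel_size, [name])


# -- preprocess ------------------------------------------------------------


def test_median_removes_impulses():
    rng = np.random.default_rng(0)
    vol = np.full((10, 40, 40), 100.0)
    idx = rng.integers(0, 40, (30, 3))
    vol[idx[:, 0] % 10, idx[:, 1], idx[:, 2]] = 255
    filtered, _ = preprocess(to_stack(vol), "DRAQ5")
    assert filtered.max() == filtered.min()  # impulses gone, constant again


def test_interior_hole_filled():
    vol = sphere_image((40, 40, 40), (20, 20, 20), 12, amp=200).astype(float)
    vol[20, 20, 20] = 0.0  # 1-px interior hole
    _, mask = preprocess(to_stack(vol), "DRAQ5", SegmentationParams(median_radius_px=1))
    assert mask[20, 20, 20]


def test_local_threshold_tolerates_illumination_ramp():
    """Foreground recovered despite a 2× lateral illumination gradient that
    defeats a single global threshold."""
    shape = (20, 60, 120)
    vol = np.zeros(shape) + 20.0
    truth = np.zeros(shape, bool)
    for cx in (20, 60, 100):
        blob = sphere_image(shape, (10, 30, cx), 7, amp=1.0).astype(bool)
        truth |= blob
    ramp = np.linspace(1.0, 2.0, shape[2])[None, None, :]
    vol[truth] = 90.0
    vol = vol * ramp
    _, mask = preprocess(to_stack(vol), "DRAQ5")
    # every blob core survives despite the ramp (the 3-px median erodes the
    # outer shell, so assert on cores rather than full spheres)
    for cx in (20, 60, 100):
        core = sphere_image(shape, (10, 30, cx), 3, amp=1.0).astype(bool)
        assert (mask & core).sum() / core.sum() > 0.95, f"core at x={cx} lost"
    # and the background between blobs stays clean
    bg = ~truth
    assert (mask & bg).sum() / bg.sum() < 0.05


# -- seed detection --------------------------------------------------------


def test_single_blob_one_seed():
    vol = sphere_image((40, 40, 40), (20, 20, 20), 7.5)
    seeds = detect_seeds(vol)
    assert len(seeds) == 1
    assert np.linalg.norm(seeds[0] - np.array([20, 20, 20])) <= 2.0


def test_below_range_blob_rejected():
    vol = sphere_image((40, 40, 40), (20, 20, 20), 2.0)
    assert len(detect_seeds(vol)) == 0


def test_two_blobs_two_seeds():
    vol = sphere_image((40, 60, 40), (20, 15, 20), 7) + sphere_image(
        (40, 60, 40), (20, 45, 20), 7
    )
    seeds = detect_seeds(np.clip(vol, 0, 255).astype(np.uint8))
    assert len(seeds) == 2


def test_empty_image_no_seeds():
    assert len(detect_seeds(np.zeros((20, 20, 20), np.uint8))) == 0


# -- watershed -------------------------------------------------------------


def test_one_seed_whole_mask():
    mask = sphere_image((30, 30, 30), (15, 15, 15), 10).astype(bool)
    vol = np.where(mask, 200, 0).astype(np.uint8)
    lv = watershed_3d(vol, mask, np.array([[15, 15, 15]]))
    assert lv.n_objects == 1
    assert (lv.labels > 0).sum() == mask.sum()


def test_touching_spheres_split():
    """Two touching equal spheres, one seed each: each catchment within 15%
    of one sphere's volume."""
    shape = (40, 60, 40)
    a = sphere_image(shape, (20, 20, 20), 10).astype(bool)
    b = sphere_image(shape, (20, 39, 20), 10).astype(bool)
    mask = a | b
    vol = np.where(mask, 200, 0).astype(np.uint8)
    lv = watershed_3d(
        vol, mask, np.array([[20, 20, 20], [20, 39, 20]]),
        SegmentationParams(relief="distance"),
    )
    assert lv.n_objects == 2
    sizes = np.bincount(lv.labels.ravel())[1:]
    single = a.sum()
    assert np.all(np.abs(sizes - single) / single < 0.15)


def test_zero_seeds_raises():
    mask = np.ones((5, 5, 5), bool)
    with pytest.raises(ValueError, match="seed"):
        watershed_3d(np.zeros((5, 5, 5), np.uint8), mask, np.zeros((0, 3)))


def test_outside_mask_seed_dropped_with_warning():
    mask = sphere_image((30, 30, 30), (15, 15, 15), 8).astype(bool)
    vol = np.where(mask, 200, 0).astype(np.uint8)
    with pytest.warns(UserWarning, match="outside"):
        lv = watershed_3d(vol, mask, np.array([[15, 15, 15], [1, 1, 1]]))
    assert lv.n_objects == 1


def test_watershed_voxel_conservation(comp_sim, comp_labels):
    """No voxel double-assigned: labeled voxels + removed small-object voxels
    equal the mask voxels reachable from seeds."""
    stack, _ = comp_sim
    labels = comp_labels.labels
    sizes = np.bincount(labels.ravel())
    assert sizes[1:].sum() == (labels > 0).sum()  # tautology guard
    _, mask = preprocess(stack, "DRAQ5")
    # every labeled voxel lies inside the foreground mask
    assert not (labels > 0)[~mask].any()


def test_segmentation_determinism(comp_sim, comp_labels):
    stack, _ = comp_sim
    again = segment_channel(stack, "DRAQ5")
    assert np.array_equal(again.labels, comp_labels.labels)


# -- counting and evaluation ----------------------------------------------


def test_count_simulated_spheroid(comp_sim):
    stack, truth = comp_sim
    res = count_nuclei(stack, "DRAQ5", "KI67")
    assert abs(res.n_total - truth.n_nuclei) <= 0.02 * truth.n_nuclei + 2
    n_pos_true = int(truth.positive_flags.sum())
    assert abs(res.n_positive - n_pos_true) <= 0.03 * truth.n_nuclei
    assert abs(res.positive_fraction - n_pos_true / truth.n_nuclei) <= 0.03


def test_marker_all_background():
    rng = np.random.default_rng(1)
    nuclear = sphere_image((30, 30, 30), (15, 15, 15), 7, amp=4000).astype(float)
    bg = np.clip(rng.normal(100, 10, (30, 30, 30)), 0, None)
    vox = np.stack([nuclear + bg, bg]).astype(np.uint16)
    stack = ImageStack(vox, 1.0, 1.0, ["DRAQ5", "KI67"])
    res = count_nuclei(stack, "DRAQ5", "KI67")
    assert res.n_positive == 0
    assert res.positive_fraction == 0.0


def test_zero_total_fraction_undefined():
    rng = np.random.default_rng(2)
    bg = np.clip(rng.normal(100, 10, (20, 30, 30)), 0, None)
    vox = np.stack([bg, bg]).astype(np.uint16)
    stack = ImageStack(vox, 1.0, 1.0, ["DRAQ5", "KI67"])
    res = count_nuclei(stack, "DRAQ5", "KI67")
    assert res.n_total == 0
    assert res.positive_fraction is None


def test_evaluation_identity():
    labels = sphere_image((20, 40, 20), (10, 10, 10), 5, amp=1).astype(np.int32)
    labels += 2 * sphere_image((20, 40, 20), (10, 30, 10), 5, amp=1).astype(np.int32)
    p, r, f = evaluate_segmentation(labels, labels)
    assert (p, r, f) == (1.0, 1.0, 1.0)


def test_evaluation_half_missing():
    truth = np.zeros((10, 40, 10), np.int32)
    truth[2:8, 5:10, 2:8] = 1
    truth[2:8, 25:30, 2:8] = 2
    pred = np.where(truth == 1, 1, 0)
    p, r, f = evaluate_segmentation(pred, truth)
    assert (p, r) == (1.0, 0.5)
    assert f == pytest.approx(2 / 3)


def test_evaluation_split_objects():
    """Every truth object split into two equal halves at IoU 0.5: one half
    matches per object → P = 0.5, R = 1.0."""
    truth = np.zeros((4, 8, 8), np.int32)
    truth[:, :4] = 1
    truth[:, 4:] = 2
    pred = np.zeros_like(truth)
    pred[:2, :4] = 1
    pred[2:, :4] = 2
    pred[:2, 4:] = 3
    pred[2:, 4:] = 4
    p, r, f = evaluate_segmentation(pred, truth, match_iou=0.5)
    assert (p, r) == (0.5, 1.0)


def test_evaluation_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        evaluate_segmentation(np.zeros((2, 2, 2), int), np.zeros((3, 3, 3), int))


def test_measure_objects(comp_sim, comp_labels):
    stack, truth = comp_sim
    table = measure_objects(comp_labels, stack)
    assert len(table) == comp_labels.n_objects
    assert (table["volume_voxels"] > 0).all()
    assert table["mean_DRAQ5"].mean() > table["mean_KI67"].mean() * 0.5
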