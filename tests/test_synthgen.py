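"""Simulator physics and ground-truth contracts."""

import numpy as np
import pytest

from spheroquant import SimulationConfig, generate_protocol_panel, generate_spheroid
from spheroquant.synthgen import matched_zcomp_slope


def small_cfg(**kw):
    base = dict(
        diameter=60.0,
        n_nuclei=30,
        pixel_size=1.5,
        seed=42,
        attenuation_length=(100.0, 100.0),
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_seed_determinism():
    s1, t1 = generate_spheroid(small_cfg())
    s2, t2 = generate_spheroid(small_cfg())
    assert np.array_equal(s1.voxels, s2.voxels)
    assert np.array_equal(t1.label_volume, t2.label_volume)
    assert np.array_equal(t1.positive_flags, t2.positive_flags)


def test_truth_invariants():
    _, truth = generate_spheroid(small_cfg())
    labels = np.unique(truth.label_volume)
    assert len(labels[labels > 0]) == truth.config.n_nuclei
    cfg = truth.config
    rel = truth.centers - truth.centers.mean(axis=0)  # approx sphere center
    # positives are on the rim and counted as round(rim_fraction * n_rim)
    radius = cfg.diameter / 2 * cfg.shrink_factor
    dist = np.linalg.norm(rel, axis=1)
    n_rim = int((radius - dist <= cfg.rim_thickness * cfg.shrink_factor + 5).sum())
    assert truth.positive_flags.sum() <= n_rim


def test_rim_positive_count_exact():
    """Positives lie in the rim shell and number round(rim_fraction · n_rim)."""
    cfg = small_cfg(rim_fraction=0.5, rim_thickness=15.0)
    _, truth = generate_spheroid(cfg)
    radius = cfg.diameter / 2 * cfg.shrink_factor
    _, ny, nx = truth.label_volume.shape
    center = np.array(
        [cfg.margin + radius, ny * cfg.pixel_size / 2, nx * cfg.pixel_size / 2]
    )
    dist = np.linalg.norm(truth.centers - center, axis=1)
    rim = radius - dist <= cfg.rim_thickness * cfg.shrink_factor
    assert truth.positive_flags.sum() == round(cfg.rim_fraction * rim.sum())
    assert np.all(rim[truth.positive_flags])


def test_no_attenuation_limit():
    """Blur-free, noise-free, no attenuation: every voxel at a nucleus center
    equals amplitude + background."""
    cfg = small_cfg(
        attenuation_length=(None, None),
        background_sigma=0.0,
        psf_sigma=(0.0, 0.0, 0.0),
    )
    stack, truth = generate_spheroid(cfg)
    vol = stack.channel("DRAQ5")
    inside = truth.label_volume > 0
    expected = cfg.amplitude[0] + cfg.background_offset
    assert np.all(vol[inside] == expected)
    assert np.all(vol[~inside] == cfg.background_offset)


def test_shrink_geometry():
    """shrink 0.5 on a 300 μm spheroid: truth extent 150 μm ± 1 voxel."""
    cfg = SimulationConfig(
        diameter=300.0, n_nuclei=0, shrink_factor=0.5, pixel_size=1.5, seed=0,
        channel_names=("TRACKER",), channel_kinds=("volume",),
        attenuation_length=(None,), amplitude=(1000.0,),
        background_sigma=0.0, psf_sigma=(0, 0, 0),
    )
    stack, _ = generate_spheroid(cfg)
    vol = stack.channel("TRACKER")
    fg = vol > cfg.background_offset
    ys = np.nonzero(fg.any(axis=(0, 2)))[0]
    extent = (ys[-1] - ys[0] + 1) * cfg.pixel_size
    assert abs(extent - 150.0) <= cfg.pixel_size + 1e-9


def test_attenuation_law_on_nuclei():
    """Mean in-nucleus intensity at depth d over depth 0 follows exp(-d/L)
    within 3% relative for noise-free stacks."""
    L = 100.0
    cfg = small_cfg(
        attenuation_length=(L, L), background_offset=0.0,
        background_sigma=0.0, psf_sigma=(0, 0, 0), n_nuclei=60,
        overlap_tolerance=0.7,
    )
    stack, truth = generate_spheroid(cfg)
    vol = stack.channel("DRAQ5").astype(float)
    inside = truth.label_volume > 0
    z_idx = np.nonzero(inside)[0]
    depths = z_idx * cfg.z_step
    vals = vol[inside]
    ref = cfg.amplitude[0]
    expected = ref * np.exp(-depths / L)
    assert np.all(np.abs(vals - expected) / expected < 0.03 + 1.0 / np.maximum(expected, 1))


def test_matched_zcomp_cancels_attenuation():
    """Slope exp(z_step/L)-1 keeps in-nucleus slice means depth-constant
    (drift < 5%)."""
    L = 60.0
    cfg = small_cfg(
        attenuation_length=(L, L), zcomp_slope=matched_zcomp_slope(L, 1.5),
        background_offset=0.0, background_sigma=1.0, psf_sigma=(0, 0, 0),
        n_nuclei=60, overlap_tolerance=0.7,
    )
    stack, truth = generate_spheroid(cfg)
    vol = stack.channel("DRAQ5").astype(float)
    means = []
    for k in range(stack.n_slices):
        m = truth.label_volume[k] > 0
        if m.sum() > 50:
            means.append(vol[k][m].mean())
    means = np.array(means)
    assert np.ptp(means) / means.mean() < 0.05


def test_marker_channel_only_in_positive_nuclei():
    cfg = small_cfg(background_offset=0.0, background_sigma=0.0, psf_sigma=(0, 0, 0))
    stack, truth = generate_spheroid(cfg)
    ki67 = stack.channel("KI67")
    neg_labels = np.flatnonzero(~truth.positive_flags) + 1
    neg_mask = np.isin(truth.label_volume, neg_labels)
    assert ki67[neg_mask].max() == 0
    pos_labels = np.flatnonzero(truth.positive_flags) + 1
    if len(pos_labels):
        assert ki67[np.isin(truth.label_volume, pos_labels)].max() > 0


def test_unplaceable_raises():
    with pytest.raises(RuntimeError, match="placed only"):
        generate_spheroid(small_cfg(diameter=20.0, n_nuclei=500))


def test_config_validation():
    with pytest.raises(ValueError):
        small_cfg(shrink_factor=0.0)
    with pytest.raises(ValueError):
        small_cfg(attenuation_length=(-5.0, 100.0))
    with pytest.raises(ValueError):
        small_cfg(channel_kinds=("nuclear",))


def test_config_yaml_roundtrip(tmp_path):
    cfg = small_cfg()
    cfg.to_yaml(tmp_path / "c.yaml")
    assert SimulationConfig.from_yaml(tmp_path / "c.yaml") == cfg


# -- protocol panel --------------------------------------------------------


def test_panel_identical_protocols_identical_stacks():
    base = small_cfg()
    panel = generate_protocol_panel(
        base, [("a", 1.0, 100.0, 1.0), ("b", 1.0, 100.0, 1.0)]
    )
    assert np.array_equal(panel[0][1].voxels, panel[1][1].voxels)


def test_panel_attenuation_monotonicity():
    """Shorter attenuation length → strictly dimmer mean intensity at depth."""
    base = SimulationConfig(
        diameter=300.0, n_nuclei=0, pixel_size=3.0, seed=7,
        channel_names=("TRACKER",), channel_kinds=("volume",),
        attenuation_length=(100.0,), amplitude=(10000.0,),
        background_sigma=0.0, psf_sigma=(0, 0, 0),
    )
    panel = generate_protocol_panel(
        base, [("short", 1.0, 60.0, 1.0), ("long", 1.0, 300.0, 1.0)]
    )
    k = int(150.0 / base.z_step)
    short = panel[0][1].voxels[0, k].mean()
    long = panel[1][1].voxels[0, k].mean()
    assert short < long


def test_panel_order_and_duplicates():
    base = small_cfg()
    protos = [(f"p{i}", 1.0, 100.0, 1.0) for i in range(6)]
    panel = generate_protocol_panel(base, protos)
    assert [name for name, _, _ in panel] == [p[0] for p in protos]
    with pytest.raises(ValueError, match="duplicate"):
        generate_protocol_panel(base, [("x", 1, 100, 1), ("x", 1, 100, 1)])
    with pytest.raises(ValueError, match="at least one"):
        generate_protocol_panel(base, [])
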