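"""Shared fixtures: synthetic stacks sized for a single-CPU test run.

The segmentation stacks are session-scoped because generating and
segmenting a 3D spheroid is the most expensive step in the suite; the
z-compensated and uncompensated pair share geometry (same seed) so
differences are attributable to the depth-gain alone.
"""

import numpy as np
import pytest

from spheroquant import SimulationConfig, generate_spheroid, segment_channel
from spheroquant.synthgen import matched_zcomp_slope

SEG_L = 50.0  # attenuation length (μm), well under half the stack depth


def seg_config(zcomp: bool, seed: int = 5) -> SimulationConfig:
    """Scaled-down spheroid used for segmentation tests: 200 nuclei,
    0.8 μm pixels (nucleus diameter ≈ 10 px, inside the 9–25 px seed range)."""
    return SimulationConfig(
        diameter=130.0,
        n_nuclei=200,
        pixel_size=0.8,
        seed=seed,
        attenuation_length=(SEG_L, SEG_L),
        zcomp_slope=matched_zcomp_slope(SEG_L, 1.5) if zcomp else 0.0,
    )


@pytest.fixture(scope="session")
def comp_sim():
    return generate_spheroid(seg_config(zcomp=True))


@pytest.fixture(scope="session")
def uncomp_sim():
    return generate_spheroid(seg_config(zcomp=False))


@pytest.fixture(scope="session")
def comp_labels(comp_sim):
    stack, _ = comp_sim
    return segment_channel(stack, "DRAQ5")


@pytest.fixture(scope="session")
def uncomp_labels(uncomp_sim):
    stack, _ = uncomp_sim
    return segment_channel(stack, "DRAQ5")


def sphere_image(shape, center, radius, amp=255.0, dtype=np.uint8):
    """Hard-sphere blob in a 3D volume (z, y, x)."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return np.where(d2 <= radius**2, amp, 0.0).astype(dtype)


def decay_oracle_config(L, seed=1, diameter=1000.0, pixel_size=3.0):
    """Noiseless uniformly stained hemisphere imaged from its equator:
    the central-ROI profile is exactly amplitude · exp(-depth/L)."""
    return SimulationConfig(
        diameter=diameter,
        n_nuclei=0,
        channel_names=("TRACKER",),
        channel_kinds=("volume",),
        attenuation_length=(L,),
        amplitude=(40000.0,),
        background_offset=0.0,
        background_sigma=0.0,
        psf_sigma=(0.0, 0.0, 0.0),
        center_depth=0.0,
        margin=0.0,
        pixel_size=pixel_size,
        seed=seed,
    )
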