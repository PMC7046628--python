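"""Depth-resolved signal-to-noise ratio and the Rose-criterion cutoff.

SNR per optical section is defined as μ_SIGNAL / σ_BACKGROUND: the mean
intensity inside an automatically thresholded nuclear mask, divided by the
standard deviation of background intensity. σ_BACKGROUND is a single scalar
estimated from shallow ("upper") sections, where scattering has not yet
contaminated the background. The Rose criterion holds while SNR > 5; the
cutoff depth is where an uninterrupted prefix of sections satisfying it
ends, and is censored when the criterion holds through the whole stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import median as median_filter
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .depthprofile import roi_mask
from .morphometry import max_projection, _foreground_mask, normalize_depth
from .stackio import ImageStack

ROSE_THRESHOLD = 5.0


@dataclass
class SNRProfile:
    """Per-slice μ_signal, the scalar σ_background, and their ratio.

    ``snr`` is NaN where the nuclear mask of a section is empty (undefined,
    not zero).
    """

    channel: str
    depths_um: np.ndarray
    normalized_depths_um: np.ndarray
    mu_signal: np.ndarray
    sigma_background: float
    snr: np.ndarray
    rose_threshold: float = ROSE_THRESHOLD

    def __post_init__(self) -> None:
        if self.sigma_background <= 0:
            raise ValueError("sigma_background must be positive")

    @property
    def max_snr(self) -> float:
        return float(np.nanmax(self.snr))


@dataclass
class RoseCutoff:
    """Largest normalized depth with SNR > 5 on an uninterrupted prefix.

    ``censored`` mirrors table entries like "> 332 μm": the criterion held
    through the deepest acquired section.
    """

    depth_um: float
    censored: bool

    def __str__(self) -> str:
        return f"> {self.depth_um:.0f} um" if self.censored else f"{self.depth_um:.0f} um"


def background_stats(
    stack: ImageStack,
    channel: str | int,
    background_slices: slice | None = None,
) -> tuple[float, float]:
    """Mean and standard deviation of background intensity.

    Background voxels are those below an automatic (Otsu) threshold in the
    designated shallow sections — by default the first 10% of the stack
    (at least one section). The σ returned is the single scalar reused for
    every section's SNR.
    """
    vol = stack.channel(channel)
    if background_slices is None:
        background_slices = slice(0, max(1, vol.shape[0] // 10))
    sub = vol[background_slices]
    if sub.size == 0:
        raise ValueError("designated background slices are empty")
    if sub.max() == sub.min():
        raise ValueError("degenerate background: designated slices are constant")
    bg = sub[sub < threshold_otsu(sub)]
    if bg.size == 0:
        raise ValueError("empty background mask")
    sigma = float(bg.std(ddof=1))
    if sigma == 0:
        raise ValueError("degenerate background: zero variance")
    return float(bg.mean()), sigma


def signal_mask(slice_image: np.ndarray) -> np.ndarray:
    """Binary nuclear mask of one optical section.

    Median filter (radius 1) then Otsu threshold; voxels above threshold are
    signal. A constant section returns an empty mask (SNR undefined
    downstream, never a crash).
    """
    img = np.asarray(slice_image)
    filtered = median_filter(img, disk(1))
    if filtered.max() == filtered.min():
        return np.zeros(img.shape, dtype=bool)
    return filtered > threshold_otsu(filtered)


def snr_profile(
    stack: ImageStack,
    channel: str | int,
    size_ratio: float = 1.0,
    roi_center: tuple[float, float] | None = None,
    roi_diameter_um: float = 100.0,
    background_slices: slice | None = None,
) -> SNRProfile:
    """SNR = μ_SIGNAL / σ_BACKGROUND per optical section in a central ROI.

    μ_SIGNAL is the mean intensity within the per-section automatic nuclear
    mask, restricted to the fixed circular ROI; σ_BACKGROUND comes from
    :func:`background_stats`. Sections with an empty mask get NaN.
    """
    vol = stack.channel(channel)
    nz, ny, nx = vol.shape
    _, sigma = background_stats(stack, channel, background_slices)
    if roi_center is None:
        fg = _foreground_mask(max_projection(stack, channel))
        roi_center = tuple(c.mean() for c in np.nonzero(fg))
    r_px = roi_diameter_um / 2 / stack.pixel_size
    disk_mask = roi_mask((ny, nx), roi_center, max(r_px, 0.5))
    mu = np.full(nz, np.nan)
    for k in range(nz):
        section = vol[k]
        mask = signal_mask(section) & disk_mask
        if mask.any():
            mu[k] = float(section[mask].mean())
    depths = stack.depths_um()
    name = channel if isinstance(channel, str) else stack.channel_names[channel]
    return SNRProfile(
        channel=name,
        depths_um=depths,
        normalized_depths_um=normalize_depth(depths, size_ratio),
        mu_signal=mu,
        sigma_background=sigma,
        snr=mu / sigma,
    )


def rose_cutoff(profile: SNRProfile, smooth_window: int = 0) -> RoseCutoff:
    """Depth up to which the Rose criterion (SNR > 5) is met.

    The qualifying prefix is anchored at the shallowest section with
    SNR > 5, so sections above the sample surface (not yet containing
    signal) are skipped; from there, an undefined (NaN) section or a single
    dip to SNR ≤ 5 ends the prefix. When every following section qualifies
    the result is censored at the deepest normalized depth. The crossing
    depth is linearly interpolated between the last qualifying and the
    first failing section.
    """
    snr = profile.snr.astype(float)
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        snr = np.convolve(snr, kernel, mode="same")
    depths = profile.normalized_depths_um
    if len(snr) == 0:
        raise ValueError("empty SNR profile")
    thr = profile.rose_threshold
    qualifying = np.flatnonzero(snr > thr)
    if len(qualifying) == 0:
        return RoseCutoff(0.0, censored=False)
    for k in range(int(qualifying[0]) + 1, len(snr)):
        if not (snr[k] > thr):
            if np.isnan(snr[k]) or snr[k - 1] <= snr[k]:
                return RoseCutoff(float(depths[k - 1]), censored=False)
            f = (snr[k - 1] - thr) / (snr[k - 1] - snr[k])
            f = min(max(f, 0.0), 1.0)
            return RoseCutoff(
                float(depths[k - 1] + f * (depths[k] - depths[k - 1])), censored=False
            )
    return RoseCutoff(float(depths[-1]), censored=True)
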