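"""Calibrated multi-channel 3D image stacks and tabular results.

The package-wide data model is :class:`ImageStack`: a 4-D voxel array in
``(channel, z, y, x)`` order with physical calibration in micrometres.
Slice index 0 is the shallowest (first-acquired) optical section, so the
physical depth of slice ``k`` is ``k * z_step``.

Stacks are stored as OME-TIFF via :mod:`tifffile`; results as CSV.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: metric names allowed in a ResultTable
METRIC_VOCABULARY = frozenset(
    {
        "diameter_um",
        "rel_change_pct",
        "d50_um",
        "d90_um",
        "rose_cutoff_um",
        "n_nuclei",
        "n_positive",
        "positive_fraction",
        "max_snr",
    }
)

RESULT_COLUMNS = ["sample_id", "protocol", "channel", "metric_name", "value", "units"]


@dataclass
class ImageStack:
    """A calibrated multi-channel confocal z-stack.

    Parameters
    ----------
    voxels
        4-D non-negative intensity array ordered ``(channel, z, y, x)``.
    z_step
        Axial distance between optical sections, μm.
    pixel_size
        Lateral pixel edge length, μm.
    channel_names
        Ordered channel labels, e.g. ``["DRAQ5", "KI67"]``.
    bit_depth
        8 or 16; intensities must fit ``[0, 2**bit_depth - 1]``.
    """

    voxels: np.ndarray
    z_step: float
    pixel_size: float
    channel_names: list[str] = field(default_factory=list)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be 4-D (c, z, y, x), got {self.voxels.ndim}-D")
        if self.z_step <= 0 or self.pixel_size <= 0:
            raise ValueError("z_step and pixel_size must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not self.channel_names:
            self.channel_names = [f"C{i}" for i in range(self.voxels.shape[0])]
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels"
            )
        if self.voxels.size:
            lo = self.voxels.min()
            hi = self.voxels.max()
            if lo < 0:
                raise ValueError("negative intensities")
            if hi > 2**self.bit_depth - 1:
                raise ValueError(
                    f"intensity {hi} exceeds bit depth {self.bit_depth} maximum"
                )

    # -- convenience -------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def depths_um(self) -> np.ndarray:
        """Physical depth of every slice (slice 0 at depth 0)."""
        return np.arange(self.n_slices) * self.z_step

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise KeyError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"unknown channel {channel!r}; have {self.channel_names}"
            ) from None

    def channel(self, channel: str | int) -> np.ndarray:
        """3-D ``(z, y, x)`` view of one channel."""
        return self.voxels[self.channel_index(channel)]

    @property
    def dtype_for_bit_depth(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile series with axis string ``axes`` to (C, Z, Y, X).

    Missing C/Z axes are inserted with length 1; T/S axes of length 1 are
    squeezed. Normalization is idempotent: CZYX input maps to itself.
    """
    axes = axes.upper()
    if len(axes) != data.ndim:
        raise ValueError(f"axis string {axes!r} does not match {data.ndim}-D data")
    # squeeze singleton axes we do not model
    for ax in "TSQI":
        while ax in axes:
            i = axes.index(ax)
            if data.shape[i] != 1:
                raise ValueError(f"cannot handle non-singleton {ax!r} axis")
            data = np.squeeze(data, axis=i)
            axes = axes[:i] + axes[i + 1 :]
    if "Y" not in axes or "X" not in axes:
        raise ValueError(f"undeterminable axis order {axes!r}")
    if "C" not in axes:
        data = data[np.newaxis]
        axes = "C" + axes
    if "Z" not in axes:
        i = axes.index("C")
        data = np.expand_dims(data, axis=i + 1)
        axes = axes[: i + 1] + "Z" + axes[i + 1 :]
    order = [axes.index(a) for a in "CZYX"]
    return np.transpose(data, order)


def _guess_axes(shape: tuple[int, ...]) -> str:
    """Heuristic axis order when metadata is absent.

    2-D → YX; 3-D → ZYX unless the leading axis is small (≤ 5: treated as
    channel); 4-D → CZYX unless the second axis is the smaller (then ZCYX).
    """
    if len(shape) == 2:
        return "YX"
    if len(shape) == 3:
        if shape[0] <= 5 and shape[0] < min(shape[1:]):
            logger.warning("3-D stack: treating leading axis of %d as channels", shape[0])
            return "CYX"
        return "ZYX"
    if len(shape) == 4:
        if shape[1] < shape[0] and shape[1] <= 5:
            logger.warning("4-D stack: treating second axis as channels (ZCYX)")
            return "ZCYX"
        return "CZYX"
    raise ValueError(f"cannot infer axes for {len(shape)}-D data")


_OME_FLOAT = re.compile(r'PhysicalSize([XZ])="([0-9.eE+-]+)"')
_OME_CHANNEL = re.compile(r'<Channel[^>]*Name="([^"]+)"')


def read_stack(
    path: str | os.PathLike,
    z_step: float | None = None,
    pixel_size: float | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    Calibration and channel names are taken from OME/ImageJ metadata when
    present; the ``z_step`` / ``pixel_size`` arguments are fallbacks only and
    metadata wins on conflict. Raises if neither source provides calibration.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    meta_z = meta_px = None
    names: list[str] = []
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        if not axes or any(a not in "CZYXTSQI" for a in axes.upper()):
            axes = _guess_axes(data.shape)
        if tif.ome_metadata:
            for ax, val in _OME_FLOAT.findall(tif.ome_metadata):
                if ax == "X":
                    meta_px = float(val)
                else:
                    meta_z = float(val)
            names = _OME_CHANNEL.findall(tif.ome_metadata)
        elif tif.imagej_metadata:
            meta_z = tif.imagej_metadata.get("spacing")
            labels = tif.imagej_metadata.get("Labels")
            if labels:
                names = list(labels)
    try:
        voxels = _normalize_axes(data, axes)
    except ValueError:
        # unlabelled page axis (e.g. 'Q') — fall back to the shape heuristic
        voxels = _normalize_axes(data, _guess_axes(data.shape))
    z = meta_z if meta_z is not None else z_step
    px = meta_px if meta_px is not None else pixel_size
    if z is None or px is None:
        raise ValueError(
            f"{path}: no calibration in metadata and none supplied as arguments"
        )
    bit_depth = 8 if voxels.dtype == np.uint8 else 16
    if len(names) != voxels.shape[0]:
        names = []
    return ImageStack(voxels, float(z), float(px), names, bit_depth)


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with embedded calibration."""
    parent = os.path.dirname(os.fspath(path)) or "."
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory {parent} does not exist")
    data = stack.voxels.astype(stack.dtype_for_bit_depth, copy=False)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def write_labels(labels: np.ndarray, path: str | os.PathLike) -> None:
    """Write an integer 3-D label volume as TIFF."""
    labels = np.asarray(labels)
    dtype = np.uint16 if labels.max(initial=0) < 2**16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))


# -- result tables ---------------------------------------------------------


def make_result_table(rows: list[dict] | pd.DataFrame) -> pd.DataFrame:
    """Validate rows of (sample_id, protocol, channel, metric_name, value, units)."""
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if table.empty:
        raise ValueError("empty result table")
    bad = set(table["metric_name"]) - METRIC_VOCABULARY
    if bad:
        raise ValueError(f"unknown metric names: {sorted(bad)}")
    key = ["sample_id", "channel", "metric_name"]
    if table.duplicated(subset=key).any():
        dupes = table[table.duplicated(subset=key, keep=False)]
        raise ValueError(f"duplicate (sample, channel, metric) rows:\n{dupes}")
    return table


def write_results(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a validated result table as CSV with a header row."""
    table = make_result_table(table)
    table.to_csv(path, index=False)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    return make_result_table(pd.read_csv(path))
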