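"""Reading and writing multi-channel 3D TIFF stacks and integer label volumes.

All volumes in this package use a fixed internal axis order: intensity
stacks are ``(channel, z, y, x)`` and label/mask volumes are ``(z, y, x)``,
0-based. Voxel spacing is carried alongside the arrays as ``(z, y, x)``
edge lengths in micrometres; it never alters grid adjacency, only
physical-size reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "LabelVolume",
    "read_stack",
    "read_labels",
    "write_labels",
    "write_stack",
]


def _check_spacing(spacing_um: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_um)
    if len(spacing) != 3:
        raise ValueError(f"spacing_um must have 3 components (z, y, x), got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing_um components must be positive and finite, got {spacing}")
    return spacing  # type: ignore[return-value]


@dataclass
class ImageStack:
    """Multi-channel 3D intensity volume with anisotropic voxel spacing.

    Parameters
    ----------
    data
        4D array indexed ``(channel, z, y, x)``; non-negative intensities.
        Native integer types are preserved — densities downstream are these
        raw intensities, never rescaled.
    spacing_um
        Voxel edge lengths ``(z, y, x)`` in micrometres, all positive.
    channel_names
        Optional human-readable names, one per channel.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"stack data must be 4D (channel, z, y, x), got ndim={self.data.ndim}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("stack needs at least 1 channel and 1 z-plane")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")
        self.spacing_um = _check_spacing(self.spacing_um)
        if self.channel_names is not None and len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match number of channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, index: int) -> np.ndarray:
        return self.data[index]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))


@dataclass
class LabelVolume:
    """3D non-negative integer instance labeling; 0 is background."""

    labels: np.ndarray
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label volume must be 3D (z, y, x), got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError(f"labels must be an integer array, got dtype={self.labels.dtype}")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing_um = _check_spacing(self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))

    def ids(self) -> np.ndarray:
        """Sorted nonzero instance ids present in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]


def _load_tiff_zcyx(path: Path) -> np.ndarray:
    """Load a TIFF and normalize to (channel, z, y, x).

    The channel axis is detected from the tifffile axes metadata when
    present ('C'); otherwise a trailing small axis (≤ 8) on 4D data is
    taken as channels-last per page, and 3D data is treated as a
    single-channel z-stack.
    """
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = series.axes  # e.g. 'ZCYX', 'CZYX', 'ZYX', 'ZYXS'

    axes = axes.replace("S", "C")  # samples-per-pixel acts as channels
    if arr.ndim == 2:
        arr = arr[None, None]  # (y, x) -> (c=1, z=1, y, x)
        return arr
    if arr.ndim == 3:
        if "C" in axes and "Z" not in axes:
            # single-plane multi-channel
            order = [axes.index(a) for a in ("C", "Y", "X") if a in axes]
            arr = np.transpose(arr, order)
            return arr[:, None]
        return arr[None]  # (z, y, x) -> (1, z, y, x)
    if arr.ndim == 4:
        if "C" in axes and "Z" in axes:
            order = [axes.index(a) for a in "CZYX"]
            return np.transpose(arr, order)
        # heuristic: smallest trailing/leading axis is the channel axis
        shape = arr.shape
        if shape[-1] <= 8:
            return np.transpose(arr, (3, 0, 1, 2))
        if shape[1] <= 8:
            return np.transpose(arr, (1, 0, 2, 3))
        return np.transpose(arr, (0, 1, 2, 3))
    raise ValueError(f"unsupported TIFF dimensionality: {arr.ndim}")


def read_stack(
    path: str | Path,
    nuclei_channel: int,
    cells_channel: int,
    spacing_um: tuple[float, float, float],
    channel_names: list[str] | None = None,
) -> ImageStack:
    """Read a two-channel stack, returning channels ordered (nuclei, cells).

    Parameters
    ----------
    path
        Multi-page TIFF whose pages are z-planes.
    nuclei_channel, cells_channel
        0-based channel indices in the file for the nuclear stain and the
        cell-marker stain.
    spacing_um
        Voxel spacing ``(z, y, x)`` in micrometres (TIFFs rarely carry
        trustworthy spacing, so it is explicit).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    arr = _load_tiff_zcyx(path)
    n_ch = arr.shape[0]
    for name, idx in (("nuclei_channel", nuclei_channel), ("cells_channel", cells_channel)):
        if not (0 <= idx < n_ch):
            raise IndexError(f"{name}={idx} out of range for file with {n_ch} channel(s)")
    data = np.stack([arr[nuclei_channel], arr[cells_channel]])
    names = channel_names if channel_names is not None else ["nuclei", "cells"]
    return ImageStack(data=data, spacing_um=spacing_um, channel_names=list(names))


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write an ImageStack as a (z, c, y, x) multi-page TIFF."""
    arr = np.transpose(stack.data, (1, 0, 2, 3))  # ZCYX: pages are z-planes
    tifffile.imwrite(str(path), arr, photometric="minisblack", metadata={"axes": "ZCYX"})


def read_labels(path: str | Path, spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> LabelVolume:
    """Read an integer-label TIFF into a LabelVolume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"label TIFF must be a 3D z-stack, got ndim={arr.ndim}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(f"label TIFF must hold integers, got {arr.dtype}")
    return LabelVolume(labels=arr, spacing_um=spacing_um)


def write_labels(path: str | Path, vol: LabelVolume) -> None:
    """Write labels as uint16 TIFF, widening to uint32 above 65535."""
    labels = vol.labels
    if labels.size and labels.max() > np.iinfo(np.uint16).max:
        out = labels.astype(np.uint32)
    else:
        out = labels.astype(np.uint16)
    tifffile.imwrite(str(path), out, photometric="minisblack", metadata={"axes": "ZYX"})
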