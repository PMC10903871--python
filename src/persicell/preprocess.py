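"""Foreground extraction and the nuclei×cells channel product.

Otsu's threshold is computed globally over the whole 3D volume (never
per-slice) with a 256-bin histogram over the observed min–max range.
The foreground rule is at-or-above: a voxel equal to the threshold is
foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["BinaryVolume", "otsu_threshold", "foreground_mask", "channel_product"]


@dataclass
class BinaryVolume:
    """3D boolean foreground mask with voxel spacing."""

    mask: np.ndarray
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.mask.ndim}")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


def otsu_threshold(channel: np.ndarray, n_bins: int = 256) -> float:
    """Global Otsu threshold of a 3D intensity volume.

    Maximizes between-class variance over an ``n_bins``-bin histogram of
    the whole volume. Deterministic for fixed input and bin count.

    Raises
    ------
    ValueError
        If the volume is constant (no threshold separates two classes).
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty volume")
    if np.all(channel == channel.flat[0]):
        raise ValueError("constant volume: Otsu threshold is undefined")
    return float(threshold_otsu(channel, nbins=int(n_bins)))


def foreground_mask(
    channel: np.ndarray,
    threshold: float,
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> BinaryVolume:
    """Binary mask of voxels with intensity >= threshold."""
    channel = np.asarray(channel)
    return BinaryVolume(mask=channel >= threshold, spacing_um=spacing_um)


def channel_product(nuclei_channel: np.ndarray, cells_channel: np.ndarray) -> np.ndarray:
    """Voxel-wise product of the two channels in a wide accumulator.

    Highlights candidate cell regions containing a nucleus: the product is
    nonzero only where both stains are. Integer inputs are widened so
    e.g. uint16 * uint16 cannot overflow; float inputs go to float64.
    """
    a = np.asarray(nuclei_channel)
    b = np.asarray(cells_channel)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if np.issubdtype(a.dtype, np.integer) and np.issubdtype(b.dtype, np.integer):
        wide = np.int64 if (a.dtype.kind == "i" or b.dtype.kind == "i") else np.uint64
    else:
        wide = np.float64
    return a.astype(wide) * b.astype(wide)
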