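"""Synthetic two-channel stacks of ramified cells with exact ground truth.

Scenes emulate a confocal z-stack of branched cells (a spherical soma
with random-walk processes) over a nuclear stain: the cell-marker
channel has a plateau intensity with a centerline-peaked ramp (deepest
voxels brightest, so each cell carries one dominant density peak at its
soma), the nuclear channel has bright spheres strictly inside the
somata. Optical blur is a Gaussian PSF; noise is additive Gaussian with
optional Poisson resampling. Ground-truth instance labels for cells and
nuclei are returned voxel-exact, before blur and noise.

A fraction of cells can be generated as physically touching pairs:
their somata share at least one adjacent voxel pair but no voxel, the
scenario where segmentation without nuclear information fuses two cells
into one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_volumes import ImageStack, LabelVolume

__all__ = ["SynthParams", "SynthScene", "generate_scene", "scene_manifest"]


@dataclass
class SynthParams:
    """Scene geometry, optics and noise.

    Defaults model a small confocal field of view: 64 planes of
    128×128 voxels at 1.0×0.5×0.5 μm spacing, 5 cells with 3–5 μm
    somata, 3–6 processes of 10–25 μm, 2 μm nuclei, 0.5 μm PSF, and
    additive Gaussian noise with sd equal to 5% of the plateau.
    """

    shape: tuple[int, int, int] = (64, 128, 128)
    spacing_um: tuple[float, float, float] = (1.0, 0.5, 0.5)
    n_cells: int = 5
    soma_radius_um: tuple[float, float] = (3.0, 5.0)
    n_branches: tuple[int, int] = (3, 6)
    branch_length_um: tuple[float, float] = (10.0, 25.0)
    branch_radius_um: float = 0.8
    tortuosity: float = 0.3
    nucleus_radius_um: float = 2.0
    touching_pair_fraction: float = 0.0
    psf_sigma_um: float = 0.5
    background: float = 10.0
    plateau: float = 100.0
    intensity_gain_per_um: float = 20.0
    nucleus_intensity: float = 200.0
    gaussian_sd: float = 5.0
    poisson: bool = False
    seed: int = 0
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.soma_radius_um[0] <= 0 or self.nucleus_radius_um <= 0:
            raise ValueError("radii must be positive")
        if self.nucleus_radius_um >= self.soma_radius_um[0]:
            raise ValueError("nucleus radius must be smaller than the smallest soma radius")
        if not (0.0 <= self.touching_pair_fraction <= 1.0):
            raise ValueError("touching_pair_fraction must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")


@dataclass
class SynthScene:
    """A generated stack plus its exact instance ground truth."""

    stack: ImageStack                 # channels (nuclei, cells)
    gt_cells: LabelVolume
    gt_nuclei: LabelVolume
    n_branches: dict[int, int]
    params: SynthParams


class PlacementError(RuntimeError):
    """Could not place the requested cells without overlap."""


def _sphere_mask(shape, spacing, center_um, radius_um) -> tuple[tuple, np.ndarray]:
    """Voxel indices of a sphere, as a (slices, local bool mask) pair."""
    sp = np.asarray(spacing)
    lo = np.maximum(0, np.floor((np.asarray(center_um) - radius_um) / sp).astype(int))
    hi = np.minimum(np.asarray(shape), np.ceil((np.asarray(center_um) + radius_um) / sp).astype(int) + 1)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    grids = np.meshgrid(*[np.arange(s.start, s.stop) for s in sl], indexing="ij")
    d2 = sum(((g * s - c) ** 2 for g, s, c in zip(grids, sp, center_um)))
    return sl, d2 <= radius_um ** 2


def _stamp(vol: np.ndarray, sl, local_mask, value) -> None:
    vol[sl][local_mask] = value


def _masks_touch(a: np.ndarray, b: np.ndarray) -> bool:
    """26-adjacency (or overlap) between two boolean volumes."""
    return bool((ndimage.binary_dilation(a, np.ones((3, 3, 3), bool)) & b).any())


def _place_soma_pair(rng, params: SynthParams, r1: float, r2: float, occupied: np.ndarray):
    """Find centers for two somata that touch but do not overlap."""
    shape = np.asarray(params.shape)
    sp = np.asarray(params.spacing_um)
    extent = shape * sp
    if np.any(extent < 2 * (max(r1, r2) + 1.0)):
        raise PlacementError("soma pair does not fit in the volume extent")
    for _ in range(params.max_retries):
        c1 = np.array([
            rng.uniform(r1 + 1.0, e - r1 - 1.0) for e in extent
        ])
        axis = np.zeros(3)
        axis[rng.integers(1, 3)] = 1.0  # touch along y or x (in-plane)
        found = None
        for d in np.arange(r1 + r2 - 1.0, r1 + r2 + 3.0, sp.min() / 4):
            c2 = c1 + axis * d
            if np.any(c2 - r2 < 1.0) or np.any(c2 + r2 > extent - 1.0):
                continue
            m1 = np.zeros(params.shape, bool)
            m2 = np.zeros(params.shape, bool)
            sl1, loc1 = _sphere_mask(params.shape, sp, c1, r1)
            sl2, loc2 = _sphere_mask(params.shape, sp, c2, r2)
            m1[sl1] = loc1
            m2[sl2] = loc2
            if not (m1 & m2).any() and _masks_touch(m1, m2):
                found = (c2, m1, m2)
                break
        if found is None:
            continue
        c2, m1, m2 = found
        pair = m1 | m2
        # keep a clear gap to everything already placed
        if not (pair & ndimage.binary_dilation(occupied > 0, np.ones((3, 3, 3), bool))).any():
            return c1, c2, m1, m2
    raise PlacementError("could not place a touching soma pair")


def _place_solo_soma(rng, params: SynthParams, r: float, occupied: np.ndarray):
    shape = np.asarray(params.shape)
    sp = np.asarray(params.spacing_um)
    extent = shape * sp
    if np.any(extent < 2 * (r + 1.0)):
        raise PlacementError("soma does not fit in the volume extent")
    for _ in range(params.max_retries):
        c = np.array([rng.uniform(r + 1.0, e - r - 1.0) for e in extent])
        m = np.zeros(params.shape, bool)
        sl, loc = _sphere_mask(params.shape, sp, c, r)
        m[sl] = loc
        if not (m & ndimage.binary_dilation(occupied > 0, np.ones((3, 3, 3), bool))).any():
            return c, m
    raise PlacementError("could not place a soma without contact")


def _grow_branches(rng, params: SynthParams, cell_mask: np.ndarray,
                   center_um: np.ndarray, r_soma: float,
                   forbidden: np.ndarray) -> int:
    """Random-walk tube processes from the soma surface; returns branch count."""
    sp = np.asarray(params.spacing_um)
    extent = np.asarray(params.shape) * sp
    n_br = int(rng.integers(params.n_branches[0], params.n_branches[1] + 1))
    step = sp.min()
    grown = 0
    for _ in range(n_br):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pos = center_um + d * max(r_soma - params.branch_radius_um, 0.5 * r_soma)
        length = rng.uniform(*params.branch_length_um)
        placed_any = False
        for _ in range(int(length / step)):
            pos = pos + d * step
            d = d + params.tortuosity * rng.normal(size=3)
            d /= np.linalg.norm(d)
            if np.any(pos < 0) or np.any(pos >= extent):
                break
            sl, loc = _sphere_mask(params.shape, sp, pos, params.branch_radius_um)
            if (forbidden[sl] & loc).any():
                break  # would touch another cell: truncate here
            cell_mask[sl] |= loc
            placed_any = True
        if placed_any:
            grown += 1
    return grown


def generate_scene(params: SynthParams) -> SynthScene:
    """Generate a deterministic scene for a fixed seed.

    Raises
    ------
    PlacementError
        If ``n_cells`` somata cannot be placed without overlap within
        ``max_retries`` attempts.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.shape
    sp = np.asarray(params.spacing_um)

    n_pairs = int(round(params.touching_pair_fraction * params.n_cells / 2))
    radii = [rng.uniform(*params.soma_radius_um) for _ in range(params.n_cells)]

    gt = np.zeros(shape, dtype=np.int64)
    centers: list[np.ndarray] = [None] * params.n_cells  # type: ignore[list-item]
    soma_masks: list[np.ndarray] = [None] * params.n_cells  # type: ignore[list-item]

    # somata first: touching pairs, then solitary cells
    idx = 0
    for _ in range(n_pairs):
        c1, c2, m1, m2 = _place_soma_pair(rng, params, radii[idx], radii[idx + 1], gt)
        centers[idx], centers[idx + 1] = c1, c2
        soma_masks[idx], soma_masks[idx + 1] = m1, m2
        gt[m1] = idx + 1
        gt[m2] = idx + 2
        idx += 2
    while idx < params.n_cells:
        c, m = _place_solo_soma(rng, params, radii[idx], gt)
        centers[idx] = c
        soma_masks[idx] = m
        gt[m] = idx + 1
        idx += 1

    # branches: each cell's processes stop short of every other cell
    n_branches: dict[int, int] = {}
    for i in range(params.n_cells):
        label = i + 1
        others = (gt > 0) & (gt != label)
        forbidden = ndimage.binary_dilation(others, np.ones((3, 3, 3), bool))
        cell_mask = gt == label
        n_branches[label] = _grow_branches(
            rng, params, cell_mask, centers[i], radii[i], forbidden
        )
        gt[cell_mask] = label

    # nuclei: concentric spheres strictly inside the somata
    gt_nuc = np.zeros(shape, dtype=np.int64)
    for i in range(params.n_cells):
        sl, loc = _sphere_mask(shape, sp, centers[i], params.nucleus_radius_um)
        gt_nuc[sl][loc] = i + 1

    # intensities: per-cell centerline-peaked ramp over a plateau
    cells_img = np.full(shape, params.background, dtype=np.float64)
    for i in range(params.n_cells):
        label = i + 1
        obj = ndimage.find_objects((gt == label).astype(np.int8))[0]
        sub = gt[obj] == label
        depth = ndimage.distance_transform_edt(sub, sampling=sp)
        cells_img[obj][sub] = params.plateau + params.intensity_gain_per_um * depth[sub]
    nuc_img = np.full(shape, params.background, dtype=np.float64)
    nuc_img[gt_nuc > 0] = params.nucleus_intensity

    sigma_vox = params.psf_sigma_um / sp
    for img in (cells_img, nuc_img):
        if params.psf_sigma_um > 0:
            img[...] = ndimage.gaussian_filter(img, sigma=sigma_vox)
        if params.poisson:
            img[...] = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if params.gaussian_sd > 0:
            img += rng.normal(0.0, params.gaussian_sd, size=img.shape)
        np.clip(img, 0, None, out=img)

    stack = ImageStack(
        data=np.stack([nuc_img, cells_img]).astype(np.float32),
        spacing_um=tuple(params.spacing_um),
        channel_names=["nuclei", "cells"],
    )
    return SynthScene(
        stack=stack,
        gt_cells=LabelVolume(gt, tuple(params.spacing_um)),
        gt_nuclei=LabelVolume(gt_nuc, tuple(params.spacing_um)),
        n_branches=n_branches,
        params=params,
    )


def scene_manifest(scene: SynthScene) -> pd.DataFrame:
    """Per-cell ground truth: centroid (voxels), voxel count, volume, branches."""
    rows = []
    gt = scene.gt_cells.labels
    voxel_um3 = scene.gt_cells.voxel_volume_um3
    for label in scene.gt_cells.ids():
        mask = gt == label
        n_vox = int(mask.sum())
        centroid = [float(v) for v in np.argwhere(mask).mean(axis=0)]
        rows.append({
            "cell_id": int(label),
            "centroid_z": centroid[0],
            "centroid_y": centroid[1],
            "centroid_x": centroid[2],
            "voxels": n_vox,
            "volume_um3": n_vox * voxel_um3,
            "n_branches": scene.n_branches.get(int(label), 0),
        })
    return pd.DataFrame(
        rows,
        columns=["cell_id", "centroid_z", "centroid_y", "centroid_x",
                 "voxels", "volume_um3", "n_branches"],
    )
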