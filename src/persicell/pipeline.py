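"""End-to-end segmentation workflow: threshold → cluster → refine.

This is the library entry point the CLI wraps: it runs Otsu foreground
extraction on the cell-marker channel, persistence-based clustering of
the foreground intensities, nuclear segmentation (or ingestion of
external nuclear labels), and the nucleus-driven refinement, returning
every intermediate product plus a machine-readable run report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_volumes import ImageStack, LabelVolume
from .nuclei_refine import CellSegmentation, RefineParams, refine, segment_nuclei_simple
from .pbc_core import ClusterHierarchy, PBCParams, build_voxel_graph, cut_hierarchy, tomato_cluster
from .preprocess import channel_product, foreground_mask, otsu_threshold

__all__ = ["SegmentationResult", "segment_stack"]


@dataclass
class SegmentationResult:
    """All artifacts of one segmentation run."""

    hierarchy: ClusterHierarchy
    cells: CellSegmentation
    nuclei: LabelVolume
    coarse_labels: LabelVolume
    fine_labels: LabelVolume
    otsu_threshold: float
    report: dict


def segment_stack(
    stack: ImageStack,
    pbc: PBCParams,
    nuclei_labels: LabelVolume | None = None,
    refine_params: RefineParams | None = None,
    nuclei_min_voxels: int = 1,
    nuclei_channel: int = 0,
    cells_channel: int = 1,
) -> SegmentationResult:
    """Segment a two-channel stack into nucleus-anchored cells.

    Parameters
    ----------
    stack
        Two-channel volume, channels ordered (nuclei, cells) by default.
    pbc
        Persistence-clustering parameters; ``pbc.delta`` is in the raw
        intensity units of the cell-marker channel.
    nuclei_labels
        Precomputed nuclear instance labels (e.g. from an external
        deep-learning segmenter). When omitted, the simple
        threshold+components fallback runs on the nuclear channel.
    """
    nuc = stack.channel(nuclei_channel)
    cells = stack.channel(cells_channel)

    thr = otsu_threshold(cells)
    mask = foreground_mask(cells, thr, stack.spacing_um)
    graph = build_voxel_graph(mask, cells, pbc.connectivity)
    hierarchy = tomato_cluster(graph, pbc)

    if nuclei_labels is None:
        nuclei_labels = segment_nuclei_simple(
            nuc, min_voxels=nuclei_min_voxels, spacing_um=stack.spacing_um
        )
    seg = refine(hierarchy, nuclei_labels, refine_params)

    # candidate flagging: which coarse clusters contain nuclei-bright voxels
    product = channel_product(nuc, cells)
    coarse_vol = cut_hierarchy(hierarchy, "coarse", drop_noise=True)
    fine_vol = cut_hierarchy(hierarchy, "fine")
    flagged = np.unique(coarse_vol.labels[product > np.percentile(product, 99.0)])
    report = {
        "otsu_threshold": float(thr),
        "n_foreground_voxels": int(mask.n_foreground),
        "n_fine_clusters": hierarchy.n_fine,
        "n_coarse_clusters": hierarchy.n_coarse,
        "n_noise_clusters": len(hierarchy.noise_coarse),
        "n_nuclei": int(len(nuclei_labels.ids())),
        "n_cells": seg.n_cells,
        "candidate_clusters": sorted(int(c) for c in flagged if c > 0),
        "params": {
            "delta": pbc.delta,
            "connectivity": pbc.connectivity,
            "min_cluster_voxels": pbc.min_cluster_voxels,
            "min_overlap_voxels": (refine_params or RefineParams()).min_overlap_voxels,
        },
    }
    return SegmentationResult(
        hierarchy=hierarchy,
        cells=seg,
        nuclei=nuclei_labels,
        coarse_labels=coarse_vol,
        fine_labels=fine_vol,
        otsu_threshold=float(thr),
        report=report,
    )
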