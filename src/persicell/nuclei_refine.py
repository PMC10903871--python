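"""Nucleus-driven refinement of candidate cell clusters.

Nuclear labels (from an external segmenter, or the simple fallback
here) anchor cell identity: a real cell contains exactly one nucleus.
Three rules turn the raw coarse clusters into cells:

* R1 — clusters overlapping no nucleus are removed (incomplete cells or
  artifacts);
* R3 — clusters overlapping two or more nuclei are split, one piece per
  nucleus, by seeded geodesic propagation inside the cluster;
* R2 — clusters (and split pieces) overlapping the same single nucleus
  are merged into one cell.

Rules are applied in the order R1 → R3 → R2, which yields a one-to-one
cell ↔ nucleus correspondence and makes the whole refinement
idempotent. Geodesic distances use the physical voxel spacing, so an
anisotropic z-step costs its true length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra

from .io_volumes import LabelVolume
from .pbc_core import ClusterHierarchy, VoxelGraph, build_voxel_graph, connectivity_offsets, cut_hierarchy
from .preprocess import BinaryVolume, otsu_threshold

__all__ = [
    "OverlapTable",
    "CellSegmentation",
    "RefineParams",
    "segment_nuclei_simple",
    "overlap_table",
    "split_multinucleate",
    "refine",
    "refine_labels",
]


@dataclass
class RefineParams:
    """min_overlap_voxels: intersection size below which an overlap is ignored."""

    min_overlap_voxels: int = 1
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.min_overlap_voxels < 1:
            raise ValueError("min_overlap_voxels must be >= 1")


@dataclass
class OverlapTable:
    """Shared-voxel counts for geometrically intersecting (cluster, nucleus) pairs."""

    entries: dict[tuple[int, int], int]

    def nuclei_of_cluster(self, cluster_id: int) -> list[int]:
        return sorted(n for (c, n) in self.entries if c == cluster_id)

    def clusters_of_nucleus(self, nucleus_id: int) -> list[int]:
        return sorted(c for (c, n) in self.entries if n == nucleus_id)


@dataclass
class CellSegmentation:
    """Instance labeling where every cell is bound to exactly one nucleus.

    ``labels`` is the voxel-level truth; ``cells`` records which fine
    clusters compose each cell (a fine cluster cut in two by a split is
    listed under the cell holding the majority of its voxels);
    ``nucleus_of`` is the cell → nucleus bijection.
    """

    labels: LabelVolume
    cells: dict[int, set[int]]
    nucleus_of: dict[int, int]

    def __post_init__(self) -> None:
        nuc = list(self.nucleus_of.values())
        if len(set(nuc)) != len(nuc):
            raise ValueError("nucleus_of must be injective (one cell per nucleus)")
        if set(self.nucleus_of) != set(self.cells):
            raise ValueError("every cell needs a nucleus assignment")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def segment_nuclei_simple(
    nuclei_channel: np.ndarray,
    threshold: float | None = None,
    min_voxels: int = 1,
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabelVolume:
    """Threshold + connected components as a fallback nuclear segmenter.

    Intended for well-separated nuclei (synthetic scenes, quick looks);
    real data with touching nuclei should use an external segmenter and
    enter through :func:`persicell.io_volumes.read_labels`.
    """
    nuclei_channel = np.asarray(nuclei_channel)
    if threshold is None:
        threshold = otsu_threshold(nuclei_channel)
    mask = nuclei_channel >= threshold
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n and min_voxels > 1:
        sizes = np.bincount(labeled.ravel())
        drop = np.nonzero(sizes < min_voxels)[0]
        labeled[np.isin(labeled, drop)] = 0
    # relabel survivors 1..N in ascending original order
    ids = np.unique(labeled)
    ids = ids[ids > 0]
    remap = np.zeros(int(labeled.max()) + 1, dtype=np.int64)
    remap[ids] = np.arange(1, len(ids) + 1)
    return LabelVolume(labels=remap[labeled], spacing_um=spacing_um)


def overlap_table(
    clusters: LabelVolume,
    nuclei: LabelVolume,
    min_overlap_voxels: int = 1,
) -> OverlapTable:
    """Exact shared-voxel counts for every (cluster, nucleus) pair."""
    if clusters.shape != nuclei.shape:
        raise ValueError(f"shape mismatch: {clusters.shape} vs {nuclei.shape}")
    both = (clusters.labels > 0) & (nuclei.labels > 0)
    pairs, counts = np.unique(
        np.stack([clusters.labels[both], nuclei.labels[both]]), axis=1, return_counts=True
    )
    return OverlapTable(entries={
        (int(c), int(n)): int(k)
        for (c, n), k in zip(pairs.T, counts)
        if k >= min_overlap_voxels
    })


def _subgraph_csr(graph: VoxelGraph, node_idx: np.ndarray) -> sparse.csr_matrix:
    """Weighted adjacency of a node subset; weights are physical step lengths."""
    pos = -np.ones(graph.n_nodes, dtype=np.int64)
    pos[node_idx] = np.arange(len(node_idx))
    sp = np.asarray(graph.spacing_um)
    rows, cols, weights = [], [], []
    coords = graph.coords
    for j in range(graph.neighbors.shape[1]):
        nb = graph.neighbors[node_idx, j]
        ok = nb >= 0
        ok[ok] &= pos[nb[ok]] >= 0
        src = node_idx[ok]
        dst = nb[ok]
        step = (coords[dst] - coords[src]) * sp
        rows.append(pos[src])
        cols.append(pos[dst])
        weights.append(np.sqrt((step ** 2).sum(axis=1)))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    m = len(node_idx)
    return sparse.csr_matrix((weights, (rows, cols)), shape=(m, m))


def split_multinucleate(
    cluster_nodes: np.ndarray,
    seeds_by_nucleus: dict[int, np.ndarray],
    graph: VoxelGraph,
) -> dict[int, np.ndarray]:
    """Partition a multi-nucleus cluster by nearest-seed geodesic distance.

    ``cluster_nodes`` are graph node indices of one connected cluster;
    ``seeds_by_nucleus`` maps each overlapping nucleus id to the node
    indices where the cluster intersects that nucleus. Every voxel goes
    to the nucleus whose seed set is geodesically nearest (edge length =
    Euclidean step scaled by the voxel spacing); exact distance ties go
    to the smaller nucleus id. Each piece contains its seeds and stays
    connected; the pieces partition the cluster.
    """
    cluster_nodes = np.asarray(cluster_nodes)
    nucleus_ids = sorted(seeds_by_nucleus)
    for nid in nucleus_ids:
        if len(seeds_by_nucleus[nid]) == 0:
            raise ValueError(f"nucleus {nid} has no seed voxels inside the cluster")
    if len(nucleus_ids) == 1:
        return {nucleus_ids[0]: cluster_nodes.copy()}

    csr = _subgraph_csr(graph, cluster_nodes)
    pos = {int(v): i for i, v in enumerate(cluster_nodes)}
    dists = np.empty((len(nucleus_ids), len(cluster_nodes)))
    for row, nid in enumerate(nucleus_ids):
        seeds = [pos[int(v)] for v in seeds_by_nucleus[nid]]
        dists[row] = dijkstra(csr, directed=False, indices=seeds, min_only=True)
    if np.isinf(dists.min(axis=0)).any():
        raise ValueError("cluster is not connected: some voxel unreachable from every seed")
    assign = np.argmin(dists, axis=0)  # first minimum -> smallest nucleus id on ties
    return {
        nid: cluster_nodes[assign == row]
        for row, nid in enumerate(nucleus_ids)
    }


def _cells_from_node_labels(
    graph: VoxelGraph,
    node_cell: np.ndarray,
    nucleus_of: dict[int, int],
    fine_labels: np.ndarray | None,
) -> CellSegmentation:
    vol = np.zeros(graph.shape, dtype=np.int64)
    vol[tuple(graph.coords.T)] = node_cell
    cells: dict[int, set[int]] = {cid: set() for cid in nucleus_of}
    if fine_labels is not None:
        # a fine cluster belongs to the cell owning most of its voxels
        for f in np.unique(fine_labels):
            members = np.nonzero(fine_labels == f)[0]
            owners, counts = np.unique(node_cell[members], return_counts=True)
            nz = owners > 0
            if nz.any():
                owners, counts = owners[nz], counts[nz]
                best = owners[np.lexsort((owners, -counts))][0]
                cells[int(best)].add(int(f))
    return CellSegmentation(
        labels=LabelVolume(labels=vol, spacing_um=graph.spacing_um),
        cells=cells,
        nucleus_of=dict(nucleus_of),
    )


def _refine_on_graph(
    graph: VoxelGraph,
    node_cluster: np.ndarray,
    nuclei: LabelVolume,
    params: RefineParams,
    fine_labels: np.ndarray | None,
) -> CellSegmentation:
    nuc_at_node = nuclei.labels[tuple(graph.coords.T)]

    # overlap tally on nodes
    entries: dict[tuple[int, int], int] = {}
    both = (node_cluster > 0) & (nuc_at_node > 0)
    if both.any():
        pairs, counts = np.unique(
            np.stack([node_cluster[both], nuc_at_node[both]]), axis=1, return_counts=True
        )
        entries = {
            (int(c), int(nid)): int(k)
            for (c, nid), k in zip(pairs.T, counts)
            if k >= params.min_overlap_voxels
        }

    nuclei_of_cluster: dict[int, list[int]] = {}
    for (c, nid) in entries:
        nuclei_of_cluster.setdefault(c, []).append(nid)

    # R1: clusters with no nucleus vanish; R3: multi-nucleus clusters split.
    node_nucleus = np.zeros(graph.n_nodes, dtype=np.int64)  # owning nucleus per node
    for c, nids in nuclei_of_cluster.items():
        members = np.nonzero(node_cluster == c)[0]
        if len(nids) == 1:
            node_nucleus[members] = nids[0]
            continue
        seeds = {
            nid: members[nuc_at_node[members] == nid] for nid in sorted(nids)
        }
        for nid, part in split_multinucleate(members, seeds, graph).items():
            node_nucleus[part] = nid

    # R2: all clusters/pieces with the same nucleus fuse into one cell.
    matched_nuclei = sorted(int(n) for n in np.unique(node_nucleus) if n > 0)
    cell_of_nucleus = {nid: i + 1 for i, nid in enumerate(matched_nuclei)}
    node_cell = np.zeros(graph.n_nodes, dtype=np.int64)
    for nid, cid in cell_of_nucleus.items():
        node_cell[node_nucleus == nid] = cid
    nucleus_of = {cid: nid for nid, cid in cell_of_nucleus.items()}
    return _cells_from_node_labels(graph, node_cell, nucleus_of, fine_labels)


def refine(
    h: ClusterHierarchy,
    nuclei: LabelVolume,
    params: RefineParams | None = None,
) -> CellSegmentation:
    """Apply R1 → R3 → R2 to the coarse clusters of a hierarchy.

    The number of cells equals the number of nuclei sharing at least
    ``min_overlap_voxels`` voxels with the surviving foreground.
    """
    params = params or RefineParams()
    if h.graph.shape != nuclei.shape:
        raise ValueError(f"grid mismatch: {h.graph.shape} vs {nuclei.shape}")
    coarse = h.coarse_labels.copy()
    if h.noise_coarse:
        coarse[np.isin(coarse, list(h.noise_coarse))] = 0
    return _refine_on_graph(h.graph, coarse, nuclei, params, h.fine_labels)


def refine_labels(
    clusters: LabelVolume,
    nuclei: LabelVolume,
    params: RefineParams | None = None,
) -> CellSegmentation:
    """Refinement on a bare cluster label volume (no hierarchy).

    Used to re-run the rules on an existing instance labeling — e.g. to
    verify idempotence, or to refine clusters produced elsewhere.
    """
    params = params or RefineParams()
    if clusters.shape != nuclei.shape:
        raise ValueError(f"shape mismatch: {clusters.shape} vs {nuclei.shape}")
    mask = BinaryVolume(mask=clusters.labels > 0, spacing_um=clusters.spacing_um)
    graph = build_voxel_graph(mask, clusters.labels.astype(np.float64), params.connectivity)
    node_cluster = clusters.labels[tuple(graph.coords.T)]
    return _refine_on_graph(graph, node_cluster, nuclei, params, None)
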