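"""Persistence-based clustering of foreground voxels (ToMATo-style).

The cell-marker intensity is treated as a density on the grid of
foreground voxels. Sweeping a threshold from the maximum intensity
downward (the superlevel-set filtration), connected components of
``{intensity >= threshold}`` are born at local maxima and die when they
meet a component with a higher peak. The lifespan (prominence) of a peak
is birth minus death; peaks whose lifespan exceeds the persistence
threshold ``delta`` found their own cluster, while less prominent peaks
are merged into the adjacent cluster they meet.

Two levels are kept: *fine* clusters, one per local-maximum basin (the
atomic units for mask editing), and *coarse* clusters, the delta-merged
putative cells. The persistence diagram (one birth/death pair per fine
cluster) is computed from the ungated filtration, so recorded deaths do
not depend on delta.

Processing order is strictly deterministic: voxels by decreasing
density, ties broken lexicographically by (z, y, x); the same rule
orders peak comparisons, so identical inputs always yield identical
labelings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_volumes import LabelVolume
from .preprocess import BinaryVolume

__all__ = [
    "VoxelGraph",
    "PBCParams",
    "PersistencePair",
    "ClusterHierarchy",
    "connectivity_offsets",
    "build_voxel_graph",
    "tomato_cluster",
    "persistence_diagram",
    "cut_hierarchy",
    "diagram_to_csv",
]


def connectivity_offsets(connectivity: int) -> np.ndarray:
    """Neighbor offsets (including both signs) for 6/18/26 connectivity."""
    if connectivity not in (6, 18, 26):
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    max_manhattan = {6: 1, 18: 2, 26: 3}[connectivity]
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                s = abs(dz) + abs(dy) + abs(dx)
                if 0 < s <= max_manhattan:
                    offs.append((dz, dy, dx))
    return np.array(offs, dtype=np.int64)


@dataclass
class VoxelGraph:
    """Foreground voxels as graph nodes with densities and grid adjacency.

    ``neighbors`` is an (N, K) int64 array of node indices padded with -1;
    row i lists the foreground grid-neighbors of node i at the chosen
    connectivity. Node order is lexicographic (z, y, x) over the mask.
    """

    coords: np.ndarray              # (N, 3) int64 voxel coordinates (z, y, x)
    density: np.ndarray             # (N,) float64, finite, >= 0
    neighbors: np.ndarray           # (N, K) int64, -1 = no neighbor
    shape: tuple[int, int, int]
    spacing_um: tuple[float, float, float]
    connectivity: int

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return int((self.neighbors >= 0).sum()) // 2

    def edge_list(self) -> list[tuple[int, int]]:
        """Undirected edges as sorted (u, v) pairs with u < v."""
        i = np.repeat(np.arange(self.n_nodes), self.neighbors.shape[1])
        j = self.neighbors.ravel()
        keep = (j >= 0) & (i < j)
        return list(zip(i[keep].tolist(), j[keep].tolist()))


@dataclass
class PBCParams:
    """Parameters of persistence-based clustering.

    delta
        Prominence threshold in raw intensity units; peaks with lifespan
        below delta are merged into an adjacent, more prominent cluster.
    connectivity
        Grid adjacency (6, 18 or 26 neighbors). Voxel spacing never
        changes adjacency.
    min_cluster_voxels
        Coarse clusters smaller than this are flagged noise (1 disables).
    """

    delta: float
    connectivity: int = 26
    min_cluster_voxels: int = 1

    def __post_init__(self) -> None:
        if not (self.delta >= 0):
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")


@dataclass
class PersistencePair:
    """Birth/death of one density peak under the superlevel filtration."""

    peak_node: tuple[int, int, int]
    birth: float
    death: float
    is_global: bool = False  # survives to the component minimum

    @property
    def lifespan(self) -> float:
        return self.birth - self.death


@dataclass
class ClusterHierarchy:
    """Two-level clustering: fine basins nested inside coarse cells.

    ``fine_labels`` / ``coarse_labels`` are per-node ids (1-based,
    ordered by descending peak density); ``parent`` maps each fine id to
    its coarse id. ``noise_coarse`` lists coarse ids flagged as noise
    (below the size floor). ``diagram`` has one PersistencePair per fine
    cluster, sorted by descending lifespan.
    """

    graph: VoxelGraph
    fine_labels: np.ndarray         # (N,) int64, 1-based
    coarse_labels: np.ndarray       # (N,) int64, 1-based
    parent: dict[int, int]
    diagram: list[PersistencePair]
    noise_coarse: frozenset[int]
    params: PBCParams

    @property
    def n_fine(self) -> int:
        return len(self.parent)

    @property
    def n_coarse(self) -> int:
        return len(set(self.parent.values()))

    def fine_members(self) -> dict[int, np.ndarray]:
        """Map fine id -> array of node indices."""
        order = np.argsort(self.fine_labels, kind="stable")
        sorted_labels = self.fine_labels[order]
        bounds = np.searchsorted(sorted_labels, np.arange(1, self.n_fine + 2))
        return {f: order[bounds[f - 1]:bounds[f]] for f in range(1, self.n_fine + 1)}


def build_voxel_graph(
    mask: BinaryVolume,
    density_channel: np.ndarray,
    connectivity: int = 26,
) -> VoxelGraph:
    """Build the adjacency graph of foreground voxels.

    Nodes are the True voxels of ``mask``; edges join voxels within one
    grid step at the stated connectivity. Density is the raw intensity.
    """
    m = mask.mask
    density_channel = np.asarray(density_channel)
    if m.shape != density_channel.shape:
        raise ValueError(f"mask shape {m.shape} != channel shape {density_channel.shape}")
    coords = np.argwhere(m).astype(np.int64)  # lexicographic (z, y, x)
    if coords.shape[0] == 0:
        raise ValueError("empty foreground mask")

    index_vol = np.full(m.shape, -1, dtype=np.int64)
    index_vol[tuple(coords.T)] = np.arange(coords.shape[0])

    offs = connectivity_offsets(connectivity)
    n, k = coords.shape[0], offs.shape[0]
    neighbors = np.full((n, k), -1, dtype=np.int64)
    shape = np.array(m.shape, dtype=np.int64)
    for j, off in enumerate(offs):
        nb = coords + off
        inside = np.all((nb >= 0) & (nb < shape), axis=1)
        idx = np.full(n, -1, dtype=np.int64)
        idx[inside] = index_vol[tuple(nb[inside].T)]
        neighbors[:, j] = idx

    dens = density_channel[tuple(coords.T)].astype(np.float64)
    if not np.all(np.isfinite(dens)) or (dens.size and dens.min() < 0):
        raise ValueError("densities must be finite and non-negative")
    return VoxelGraph(
        coords=coords,
        density=dens,
        neighbors=neighbors,
        shape=m.shape,
        spacing_um=mask.spacing_um,
        connectivity=connectivity,
    )


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:  # path compression
            p[x], x = root, p[x]
        return root

    def union_into(self, child: int, parent: int) -> None:
        self.parent[child] = parent


def tomato_cluster(graph: VoxelGraph, params: PBCParams) -> ClusterHierarchy:
    """Mode-seeking clustering with prominence-gated merging.

    Voxels are processed in order of decreasing density (lexicographic
    tie-break). A voxel with no processed neighbor founds a fine cluster
    (a new peak, birth = its density); otherwise it joins the fine
    cluster of its highest-density processed neighbor. When clusters
    meet at a voxel v, the one whose peak is within delta of f(v) is
    absorbed into the more prominent one; if both peaks clear delta the
    clusters stay separate. Deaths for the persistence diagram are
    recorded from the ungated filtration, so the diagram is the plain
    0-dimensional superlevel persistence of the density.
    """
    n = graph.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    dens = graph.density
    coords = graph.coords

    # rank order: descending density, then lexicographic (z, y, x).
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], -dens))
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)

    # Predecessor lists (neighbors already processed), in rank space.
    nbrs = graph.neighbors
    valid = nbrs >= 0
    nbr_rank = np.where(valid, rank[np.where(valid, nbrs, 0)], n)
    preds_of = [
        nbrs[i][valid[i] & (nbr_rank[i] < rank[i])].tolist() for i in range(n)
    ]

    fine_of = np.full(n, -1, dtype=np.int64)
    peak_node: list[int] = []      # founding node of each fine cluster
    births: list[float] = []
    deaths: dict[int, float] = {}  # fine id -> death (ungated)
    gated = _UnionFind(0)
    ungated = _UnionFind(0)
    # per gated/ungated ROOT, the fine id of its highest peak; peak order
    # is compared by rank of the founding node (smaller rank = higher
    # peak, lex tie-break built in).
    rank_list = rank.tolist()
    dens_list = dens.tolist()

    def peak_rank(fine_id: int) -> int:
        return rank_list[peak_node[fine_id]]

    delta = float(params.delta)
    for i in order.tolist():
        preds = preds_of[i]
        if not preds:
            c = len(peak_node)
            peak_node.append(i)
            births.append(dens_list[i])
            gated.parent.append(c)
            ungated.parent.append(c)
            fine_of[i] = c
            continue
        # highest-density processed neighbor = smallest rank
        u_best = min(preds, key=lambda u: rank_list[u])
        fi = fine_of[u_best]
        fine_of[i] = fi
        fv = dens_list[i]

        # --- ungated merges (persistence diagram bookkeeping) ---
        uv = ungated.find(fi)
        for u in preds:
            ru = ungated.find(fine_of[u])
            if ru != uv:
                if peak_rank(ru) < peak_rank(uv):
                    ru, uv = uv, ru      # ru is the lower peak: it dies
                deaths[ru] = fv
                ungated.union_into(ru, uv)
        # --- gated merges: when several clusters meet at v, every
        # cluster whose peak is within delta of f(v) is absorbed into
        # the highest-peak cluster present (canonical merge order).
        roots = sorted({gated.find(fine_of[u]) for u in preds}, key=peak_rank)
        survivor = roots[0]
        for r in roots[1:]:
            if dens_list[peak_node[r]] - fv < delta:
                gated.union_into(r, survivor)
            # else: prominent at this saddle; stays separate

    n_fine = len(peak_node)
    # deaths of surviving ungated roots: minimum density of the component
    ung_root = np.fromiter(
        (ungated.find(int(f)) for f in fine_of), dtype=np.int64, count=n
    )
    comp_min = {}
    for r, d in zip(ung_root.tolist(), dens_list):
        if r not in comp_min or d < comp_min[r]:
            comp_min[r] = d
    globals_: set[int] = set()
    for c in range(n_fine):
        if c not in deaths:
            deaths[c] = comp_min[ungated.find(c)]
            globals_.add(c)

    # relabel fine and coarse ids 1..F / 1..C by descending peak order
    fine_order = sorted(range(n_fine), key=peak_rank)
    fine_new = {old: i + 1 for i, old in enumerate(fine_order)}
    gat_roots = sorted({gated.find(c) for c in range(n_fine)}, key=peak_rank)
    coarse_new = {old: i + 1 for i, old in enumerate(gat_roots)}

    fine_labels = np.fromiter((fine_new[int(f)] for f in fine_of), dtype=np.int64, count=n)
    parent = {fine_new[c]: coarse_new[gated.find(c)] for c in range(n_fine)}
    coarse_labels = np.fromiter((parent[int(f)] for f in fine_labels), dtype=np.int64, count=n)

    noise: set[int] = set()
    if params.min_cluster_voxels > 1:
        sizes = np.bincount(coarse_labels, minlength=len(coarse_new) + 1)
        noise = {int(c) for c in np.nonzero(sizes[1:] < params.min_cluster_voxels)[0] + 1}

    diagram = [
        PersistencePair(
            peak_node=tuple(int(v) for v in coords[peak_node[c]]),
            birth=births[c],
            death=deaths[c],
            is_global=c in globals_,
        )
        for c in fine_order
    ]
    diagram.sort(key=lambda p: (-p.lifespan, p.peak_node))

    return ClusterHierarchy(
        graph=graph,
        fine_labels=fine_labels,
        coarse_labels=coarse_labels,
        parent=parent,
        diagram=diagram,
        noise_coarse=frozenset(noise),
        params=params,
    )


def persistence_diagram(h: ClusterHierarchy) -> list[PersistencePair]:
    """Persistence pairs (one per fine cluster), by descending lifespan."""
    return list(h.diagram)


def cut_hierarchy(
    h: ClusterHierarchy,
    level: str = "coarse",
    drop_noise: bool = False,
) -> LabelVolume:
    """Materialize the fine or coarse labeling as a LabelVolume."""
    if level not in ("fine", "coarse"):
        raise ValueError(f"level must be 'fine' or 'coarse', got {level!r}")
    labels = h.fine_labels if level == "fine" else h.coarse_labels
    if drop_noise and h.noise_coarse:
        keep = ~np.isin(h.coarse_labels, list(h.noise_coarse))
        labels = np.where(keep, labels, 0)
    vol = np.zeros(h.graph.shape, dtype=np.int64)
    vol[tuple(h.graph.coords.T)] = labels
    return LabelVolume(labels=vol, spacing_um=h.graph.spacing_um)


def diagram_to_csv(h: ClusterHierarchy, path) -> None:
    """Export the persistence diagram as CSV (peak coords, birth, death, lifespan)."""
    import pandas as pd

    rows = [
        {
            "peak_z": p.peak_node[0],
            "peak_y": p.peak_node[1],
            "peak_x": p.peak_node[2],
            "birth": p.birth,
            "death": p.death,
            "lifespan": p.lifespan,
            "is_global": p.is_global,
        }
        for p in h.diagram
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
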