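"""Deliberately simple reference clustering for validation.

This module re-derives the prominence-gated clustering straight from its
definition: sweep the density values from high to low as superlevel-set
thresholds, hold every cluster as an explicit set of voxels, re-scan all
clusters for adjacency at each step, and decide each merge from the
exhaustively tracked peak values. It shares no code with the union-find
implementation in :mod:`persicell.pbc_core`; property tests assert that
the two agree, as partitions, on random grids.

It is O(n^2) or worse and only meant for small inputs (a few hundred
foreground voxels).
"""

from __future__ import annotations

import numpy as np

from .pbc_core import VoxelGraph

__all__ = ["reference_coarse_partition", "partitions_equal"]


def reference_coarse_partition(graph: VoxelGraph, delta: float) -> list[set[int]]:
    """Coarse clusters of the prominence-gated superlevel sweep.

    Returns the clustering as a list of node-index sets (order
    irrelevant). Rules, applied literally:

    * thresholds sweep the node densities in decreasing order
      (lexicographic (z, y, x) tie-break, matching the main code's
      declared determinism contract);
    * a node touching no existing cluster starts one (a peak is born);
    * a node touching clusters joins the one holding its
      highest-density processed neighbor;
    * when clusters become adjacent through the new node v, every one
      whose peak is less than ``delta`` above f(v) is absorbed into the
      highest-peak cluster present at v (equal peaks: the
      lexicographically smaller peak coordinate wins); prominent
      clusters persist side by side.
    """
    n = graph.n_nodes
    dens = graph.density
    coords = graph.coords
    nbr_sets = [set(int(u) for u in row[row >= 0]) for row in graph.neighbors]

    def node_key(i: int):
        return (-dens[i], tuple(coords[i]))

    order = sorted(range(n), key=node_key)

    clusters: list[dict] = []  # {'nodes': set, 'peak': node index}
    alive: list[bool] = []

    def adjacent_clusters(v: int) -> list[int]:
        out = []
        for ci, c in enumerate(clusters):
            if alive[ci] and nbr_sets[v] & c["nodes"]:
                out.append(ci)
        return out

    for v in order:
        touching = adjacent_clusters(v)
        if not touching:
            clusters.append({"nodes": {v}, "peak": v})
            alive.append(True)
            continue
        processed_nbrs = [u for u in nbr_sets[v] if any(
            alive[ci] and u in clusters[ci]["nodes"] for ci in touching)]
        u_best = min(processed_nbrs, key=node_key)
        home = next(ci for ci in touching if u_best in clusters[ci]["nodes"])
        clusters[home]["nodes"].add(v)
        fv = dens[v]
        # highest peak present at v survives; sub-delta peaks are absorbed
        by_peak = sorted(touching, key=lambda ci: node_key(clusters[ci]["peak"]))
        survivor = by_peak[0]
        for ci in by_peak[1:]:
            if dens[clusters[ci]["peak"]] - fv < delta:
                clusters[survivor]["nodes"] |= clusters[ci]["nodes"]
                alive[ci] = False
            # else both peaks clear delta: clusters stay separate

    return [c["nodes"] for ci, c in enumerate(clusters) if alive[ci]]


def partitions_equal(parts_a: list[set[int]], labels_b: np.ndarray) -> bool:
    """True if a list-of-sets partition equals a label-array partition."""
    by_label: dict[int, set[int]] = {}
    for i, lab in enumerate(np.asarray(labels_b).tolist()):
        by_label.setdefault(lab, set()).add(i)
    sets_b = sorted((frozenset(s) for s in by_label.values()), key=lambda s: min(s))
    sets_a = sorted((frozenset(s) for s in parts_a), key=lambda s: min(s))
    return sets_a == sets_b
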