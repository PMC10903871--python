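"""Headless cluster-level editing of a cell segmentation.

Edits move whole fine clusters (the atomic basins of the persistence
hierarchy) between cells — never single voxels — and every edit is
appended to an operation log, so a session can be saved, reloaded and
replayed deterministically to refine a previous segmentation.

Session files are a JSON manifest (schema version, ops log, cell ↔
nucleus table) plus TIFF label volumes for the base state.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_volumes import LabelVolume, read_labels, write_labels
from .nuclei_refine import CellSegmentation
from .pbc_core import ClusterHierarchy

__all__ = ["EditSession", "SessionError", "add_cluster", "remove_cluster", "save_session", "load_session"]

SESSION_VERSION = 1


class SessionError(RuntimeError):
    """Corrupt, incompatible or inconsistent session data."""


@dataclass
class EditSession:
    """A segmentation plus an ordered, replayable log of cluster edits.

    ``fine_volume`` is the immutable fine-cluster labeling of the base
    hierarchy; ``base_cells`` / ``base_nucleus_of`` freeze the starting
    segmentation; ``cells`` / ``nucleus_of`` / ``labels`` are the
    current state, always equal to the base state with the log
    replayed.
    """

    fine_volume: LabelVolume
    base_labels: LabelVolume
    base_cells: dict[int, set[int]]
    base_nucleus_of: dict[int, int]
    cells: dict[int, set[int]]
    nucleus_of: dict[int, int]
    labels: LabelVolume
    ops_log: list[dict] = field(default_factory=list)
    version: int = SESSION_VERSION

    @classmethod
    def from_segmentation(cls, h: ClusterHierarchy, seg: CellSegmentation) -> "EditSession":
        from .pbc_core import cut_hierarchy

        fine_vol = cut_hierarchy(h, "fine")
        return cls(
            fine_volume=fine_vol,
            base_labels=LabelVolume(seg.labels.labels.copy(), seg.labels.spacing_um),
            base_cells={c: set(s) for c, s in seg.cells.items()},
            base_nucleus_of=dict(seg.nucleus_of),
            cells={c: set(s) for c, s in seg.cells.items()},
            nucleus_of=dict(seg.nucleus_of),
            labels=LabelVolume(seg.labels.labels.copy(), seg.labels.spacing_um),
        )

    def cluster_mask(self, fine_id: int) -> np.ndarray:
        return self.fine_volume.labels == fine_id

    def owner_of(self, fine_id: int) -> int | None:
        for cid, members in self.cells.items():
            if fine_id in members:
                return cid
        return None


def _clusters_adjacent(session: EditSession, cell_id: int, fine_id: int) -> bool:
    """Does any voxel of the fine cluster touch the cell (26-neighborhood)?"""
    from scipy import ndimage

    cell_mask = session.labels.labels == cell_id
    dilated = ndimage.binary_dilation(cell_mask, structure=np.ones((3, 3, 3), dtype=bool))
    return bool((dilated & session.cluster_mask(fine_id)).any())


def _apply(session: EditSession, op: dict) -> None:
    """Apply one logged op to the current state (no validation)."""
    fine_id = op["cluster"]
    cell_id = op["cell"]
    cmask = session.cluster_mask(fine_id)
    if op["op"] == "add":
        prev = session.owner_of(fine_id)
        if prev is not None:
            session.cells[prev].discard(fine_id)
            if not session.cells[prev]:
                del session.cells[prev]
                del session.nucleus_of[prev]
        session.cells.setdefault(cell_id, set()).add(fine_id)
        session.labels.labels[cmask] = cell_id
    elif op["op"] == "remove":
        session.cells[cell_id].discard(fine_id)
        session.labels.labels[cmask & (session.labels.labels == cell_id)] = 0
        if not session.cells[cell_id]:
            # last cluster gone: the cell is deleted outright
            del session.cells[cell_id]
            del session.nucleus_of[cell_id]
            session.labels.labels[session.labels.labels == cell_id] = 0
    else:
        raise SessionError(f"unknown op kind {op['op']!r}")


def add_cluster(session: EditSession, cell_id: int, fine_id: int, force: bool = False) -> EditSession:
    """Assign a fine cluster to a cell (stealing it from a prior owner).

    Unless ``force``, the cluster must share at least one grid edge with
    the target cell's current voxels.
    """
    if cell_id not in session.cells:
        raise KeyError(f"unknown cell id {cell_id}")
    if not session.cluster_mask(fine_id).any():
        raise KeyError(f"unknown fine cluster id {fine_id}")
    if session.owner_of(fine_id) == cell_id:
        raise ValueError(f"cluster {fine_id} already belongs to cell {cell_id}")
    if not force and not _clusters_adjacent(session, cell_id, fine_id):
        raise ValueError(
            f"cluster {fine_id} is not adjacent to cell {cell_id} (use force to override)"
        )
    op = {"op": "add", "cell": int(cell_id), "cluster": int(fine_id), "time": time.time()}
    _apply(session, op)
    session.ops_log.append(op)
    return session


def remove_cluster(session: EditSession, cell_id: int, fine_id: int) -> EditSession:
    """Detach a fine cluster from a cell; removing the last cluster deletes the cell."""
    if cell_id not in session.cells:
        raise KeyError(f"unknown cell id {cell_id}")
    if fine_id not in session.cells[cell_id]:
        raise ValueError(f"cluster {fine_id} does not belong to cell {cell_id}")
    op = {"op": "remove", "cell": int(cell_id), "cluster": int(fine_id), "time": time.time()}
    _apply(session, op)
    session.ops_log.append(op)
    return session


def replay(session: EditSession) -> LabelVolume:
    """Recompute the current labels by replaying the log on the base state."""
    fresh = EditSession(
        fine_volume=session.fine_volume,
        base_labels=session.base_labels,
        base_cells={c: set(s) for c, s in session.base_cells.items()},
        base_nucleus_of=dict(session.base_nucleus_of),
        cells={c: set(s) for c, s in session.base_cells.items()},
        nucleus_of=dict(session.base_nucleus_of),
        labels=LabelVolume(session.base_labels.labels.copy(), session.base_labels.spacing_um),
    )
    for op in session.ops_log:
        _apply(fresh, op)
    return fresh.labels


def save_session(session: EditSession, path: str | Path) -> None:
    """Write manifest JSON + base/fine label TIFFs next to it."""
    path = Path(path)
    stem = path.with_suffix("")
    fine_path = stem.parent / (stem.name + "_fine.tif")
    base_path = stem.parent / (stem.name + "_base.tif")
    write_labels(fine_path, session.fine_volume)
    write_labels(base_path, session.base_labels)
    manifest = {
        "format": "persicell-session",
        "version": session.version,
        "spacing_um": list(session.labels.spacing_um),
        "fine_labels": fine_path.name,
        "base_labels": base_path.name,
        "base_cells": {str(c): sorted(s) for c, s in session.base_cells.items()},
        "base_nucleus_of": {str(c): n for c, n in session.base_nucleus_of.items()},
        "ops_log": session.ops_log,
    }
    path.write_text(json.dumps(manifest, indent=2))


def load_session(path: str | Path) -> EditSession:
    """Load a session and replay its log to restore the current state."""
    path = Path(path)
    try:
        manifest = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise SessionError(f"cannot read session manifest: {e}") from e
    if manifest.get("format") != "persicell-session":
        raise SessionError("not a persicell session file")
    if manifest.get("version") != SESSION_VERSION:
        raise SessionError(
            f"session version {manifest.get('version')} unsupported (expected {SESSION_VERSION})"
        )
    spacing = tuple(manifest["spacing_um"])
    fine_vol = read_labels(path.parent / manifest["fine_labels"], spacing)
    base_vol = read_labels(path.parent / manifest["base_labels"], spacing)
    base_cells = {int(c): set(s) for c, s in manifest["base_cells"].items()}
    base_nucleus_of = {int(c): int(n) for c, n in manifest["base_nucleus_of"].items()}
    session = EditSession(
        fine_volume=fine_vol,
        base_labels=base_vol,
        base_cells={c: set(s) for c, s in base_cells.items()},
        base_nucleus_of=dict(base_nucleus_of),
        cells={c: set(s) for c, s in base_cells.items()},
        nucleus_of=dict(base_nucleus_of),
        labels=LabelVolume(base_vol.labels.copy(), spacing),
        ops_log=[],
    )
    for op in manifest["ops_log"]:
        _apply(session, op)
        session.ops_log.append(op)
    return session
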