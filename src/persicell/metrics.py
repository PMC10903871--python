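"""Voxel-wise evaluation of an instance segmentation against ground truth.

Each predicted cell is paired with a ground-truth cell (greedy matching
on shared voxel count) and scored with F1/Dice, Jaccard and the percent
of false-positive / false-negative voxels. Percentages are relative to
the ground-truth cell's voxel count, so a grossly oversized prediction
can exceed 100% false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_volumes import LabelVolume

__all__ = ["EvalReport", "match_cells", "cell_scores", "error_map", "evaluate_segmentation"]

TP_CODE, FP_CODE, FN_CODE = 1, 2, 3


@dataclass
class EvalReport:
    """Per-cell scores plus unmatched instance ids on both sides."""

    rows: pd.DataFrame               # pred_id, gt_id, tp, fp, fn, f1, jaccard, fp_pct, fn_pct
    unmatched_pred: list[int]
    unmatched_gt: list[int]

    def summary(self) -> dict[str, float]:
        """Mean ± SD across cells, each matched cell one data point."""
        out: dict[str, float] = {"n_matched": float(len(self.rows))}
        for col in ("f1", "jaccard", "fp_pct", "fn_pct"):
            vals = self.rows[col].to_numpy(dtype=float)
            out[f"{col}_mean"] = float(vals.mean()) if vals.size else float("nan")
            out[f"{col}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out["n_unmatched_pred"] = float(len(self.unmatched_pred))
        out["n_unmatched_gt"] = float(len(self.unmatched_gt))
        return out


def _overlap_counts(pred: np.ndarray, gt: np.ndarray) -> dict[tuple[int, int], int]:
    both = (pred > 0) & (gt > 0)
    pairs, counts = np.unique(
        np.stack([pred[both], gt[both]]), axis=1, return_counts=True
    )
    return {
        (int(p), int(g)): int(c)
        for (p, g), c in zip(pairs.T, counts)
    }


def match_cells(pred: LabelVolume, gt: LabelVolume) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of predicted to ground-truth cells.

    Candidate pairs are ranked by descending shared-voxel count, ties by
    (gt id, pred id); each id is used at most once and zero-overlap
    pairs are never matched. Returns (pred_id, gt_id) pairs.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    overlaps = _overlap_counts(pred.labels, gt.labels)
    ranked = sorted(overlaps.items(), key=lambda kv: (-kv[1], kv[0][1], kv[0][0]))
    used_pred: set[int] = set()
    used_gt: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for (p, g), _ in ranked:
        if p in used_pred or g in used_gt:
            continue
        pairs.append((p, g))
        used_pred.add(p)
        used_gt.add(g)
    return pairs


def cell_scores(pred_mask: np.ndarray, gt_mask: np.ndarray) -> tuple[float, float, float, float]:
    """(f1, jaccard, fp_pct, fn_pct) for one predicted/true voxel mask pair.

    f1 = 2TP/(2TP+FP+FN); jaccard = TP/(TP+FP+FN);
    fp_pct = 100·FP/|gt|; fn_pct = 100·FN/|gt|.
    """
    pred_mask = np.asarray(pred_mask, dtype=bool)
    gt_mask = np.asarray(gt_mask, dtype=bool)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(f"shape mismatch: {pred_mask.shape} vs {gt_mask.shape}")
    n_gt = int(gt_mask.sum())
    if n_gt == 0:
        raise ValueError("empty ground-truth mask")
    tp = int((pred_mask & gt_mask).sum())
    fp = int((pred_mask & ~gt_mask).sum())
    fn = int((~pred_mask & gt_mask).sum())
    f1 = 2 * tp / (2 * tp + fp + fn)
    jaccard = tp / (tp + fp + fn)
    return f1, jaccard, 100.0 * fp / n_gt, 100.0 * fn / n_gt


def error_map(pred: LabelVolume, gt: LabelVolume) -> LabelVolume:
    """Voxel codes over pred ∪ gt: 1 = TP, 2 = FP, 3 = FN (0 elsewhere)."""
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    p = pred.labels > 0
    g = gt.labels > 0
    out = np.zeros(p.shape, dtype=np.uint8)
    out[p & g] = TP_CODE
    out[p & ~g] = FP_CODE
    out[~p & g] = FN_CODE
    return LabelVolume(labels=out.astype(np.int64), spacing_um=gt.spacing_um)


def evaluate_segmentation(pred: LabelVolume, gt: LabelVolume) -> EvalReport:
    """Match instances then score every matched pair voxel-wise."""
    pairs = match_cells(pred, gt)
    rows = []
    for p, g in pairs:
        pm = pred.labels == p
        gm = gt.labels == g
        tp = int((pm & gm).sum())
        fp = int((pm & ~gm).sum())
        fn = int((~pm & gm).sum())
        f1, jac, fp_pct, fn_pct = cell_scores(pm, gm)
        rows.append(
            {"pred_id": p, "gt_id": g, "tp": tp, "fp": fp, "fn": fn,
             "f1": f1, "jaccard": jac, "fp_pct": fp_pct, "fn_pct": fn_pct}
        )
    df = pd.DataFrame(
        rows,
        columns=["pred_id", "gt_id", "tp", "fp", "fn", "f1", "jaccard", "fp_pct", "fn_pct"],
    )
    matched_pred = {p for p, _ in pairs}
    matched_gt = {g for _, g in pairs}
    return EvalReport(
        rows=df,
        unmatched_pred=sorted(int(i) for i in pred.ids() if int(i) not in matched_pred),
        unmatched_gt=sorted(int(i) for i in gt.ids() if int(i) not in matched_gt),
    )
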