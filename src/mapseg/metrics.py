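"""Segmentation evaluation: Jaccard similarity and label matching."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["jaccard_similarity", "match_labels", "per_region_jaccard"]


def jaccard_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """JS(A, B) = |A ∩ B| / |A ∪ B| for two binary masks.

    1 means perfect overlap; two empty masks compare as identical (1).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def match_labels(predicted: np.ndarray, truth: np.ndarray) -> dict[int, int]:
    """Best one-to-one mapping from predicted labels to truth labels.

    Segmentation output carries no intrinsic region identity (level-set
    phases are exchangeable), so regions are matched to ground truth by
    maximising total overlap (Hungarian assignment on the contingency
    table).  Label 0 (excluded pixels) is ignored on both sides.
    """
    pred_ids = [p for p in np.unique(predicted) if p != 0]
    true_ids = [t for t in np.unique(truth) if t != 0]
    overlap = np.zeros((len(pred_ids), len(true_ids)))
    for i, p in enumerate(pred_ids):
        pm = predicted == p
        for j, t in enumerate(true_ids):
            overlap[i, j] = np.logical_and(pm, truth == t).sum()
    rows, cols = linear_sum_assignment(-overlap)
    return {int(pred_ids[i]): int(true_ids[j]) for i, j in zip(rows, cols)}


def per_region_jaccard(predicted: np.ndarray, truth: np.ndarray) -> dict[int, float]:
    """Jaccard per ground-truth region after optimal label matching.

    Keys are truth labels; a truth region that no predicted region was
    assigned to scores 0.
    """
    mapping = match_labels(predicted, truth)
    out = {int(t): 0.0 for t in np.unique(truth) if t != 0}
    for p, t in mapping.items():
        out[t] = jaccard_similarity(predicted == p, truth == t)
    return out
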