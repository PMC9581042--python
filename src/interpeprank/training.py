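"""Training targets, dataset balancing, and scorer-evaluation metrics.

The regression target is a normalized LRMSD in (0, 1],

    LRMSD_norm = 1 / (1 + (LRMSD / 4.0)^2),

which maps 0 Å to 1, the 4 Å correctness threshold to 0.5, and large
deviations toward 0.  Training is cast as classification over bins of
LRMSD_norm evenly spread in [0, 1]; with two bins the boundary coincides
with the 4 Å correct/incorrect threshold.

Evaluation follows the decoy-ranking convention: ROC curves over the
correct/incorrect label (FPR = FP/N, TPR = TP/P), trapezoidal AUC,
precision-recall, and Spearman rank correlation between predicted score
and LRMSD_norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .structure_io import CORRECT_LRMSD_CUTOFF

#: LRMSD scale (Å) of the normalization; also the correctness threshold.
LRMSD_NORM_SCALE = 4.0


def normalize_lrmsd(lrmsd):
    """Map LRMSD (Å) to (0, 1]: ``1 / (1 + (LRMSD/4)^2)``."""
    lrmsd = np.asarray(lrmsd, dtype=float)
    if np.any(lrmsd < 0):
        raise ValueError("LRMSD must be non-negative")
    out = 1.0 / (1.0 + (lrmsd / LRMSD_NORM_SCALE) ** 2)
    return float(out) if out.ndim == 0 else out


def assign_bin(lrmsd_norm, n_bins: int):
    """Bin index of LRMSD_norm with ``n_bins`` even, right-closed bins.

    Bin *i* covers (i/n, (i+1)/n], so a perfect decoy (norm = 1.0) lands in
    the top bin and exactly 4.0 Å (norm = 0.5) falls in the lower bin with
    two bins — consistent with the strict LRMSD < 4 Å correctness rule.
    """
    if n_bins not in (2, 3, 4):
        raise ValueError(f"n_bins must be 2, 3 or 4, got {n_bins}")
    norm = np.asarray(lrmsd_norm, dtype=float)
    if np.any(norm <= 0) or np.any(norm > 1):
        raise ValueError("lrmsd_norm must be in (0, 1]")
    idx = np.ceil(norm * n_bins).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    return int(idx) if idx.ndim == 0 else idx


def is_correct(lrmsd) -> np.ndarray | bool:
    """Correct-decoy flag: LRMSD strictly below 4.0 Å."""
    lrmsd = np.asarray(lrmsd, dtype=float)
    out = lrmsd < CORRECT_LRMSD_CUTOFF
    return bool(out) if out.ndim == 0 else out


@dataclass
class LabeledDecoy:
    """A decoy graph reference with its training label and grouping."""

    graph_ref: str
    target_id: str
    group_id: str
    lrmsd: float
    lrmsd_norm: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.lrmsd_norm is None:
            self.lrmsd_norm = normalize_lrmsd(self.lrmsd)

    @property
    def is_correct(self) -> bool:
        return bool(self.lrmsd < CORRECT_LRMSD_CUTOFF)

    def bin_index(self, n_bins: int) -> int:
        return assign_bin(self.lrmsd_norm, n_bins)


def balance_dataset(decoys: list[LabeledDecoy], seed: int = 0) -> list[LabeledDecoy]:
    """Class- and group-balance a labeled decoy set (seeded, labels untouched).

    Per target, the majority correctness class is down-sampled to the
    minority count so each target contributes equally many correct and
    incorrect decoys.  Then any homology group whose total exceeds the
    median group total is down-sampled to that median, so large groups do
    not dominate training.  The output order is deterministically shuffled.
    """
    if not decoys:
        raise ValueError("empty decoy list")
    rng = np.random.default_rng(seed)

    by_target: dict[str, list[LabeledDecoy]] = {}
    for d in decoys:
        by_target.setdefault(d.target_id, []).append(d)

    kept: list[LabeledDecoy] = []
    for tid in sorted(by_target):
        ds = by_target[tid]
        pos = [d for d in ds if d.is_correct]
        neg = [d for d in ds if not d.is_correct]
        k = min(len(pos), len(neg))
        for side in (pos, neg):
            if len(side) > k:
                idx = rng.choice(len(side), size=k, replace=False)
                kept.extend(side[i] for i in sorted(idx))
            else:
                kept.extend(side)

    by_group: dict[str, list[LabeledDecoy]] = {}
    for d in kept:
        by_group.setdefault(d.group_id, []).append(d)
    sizes = [len(v) for v in by_group.values()]
    cap = int(np.median(sizes))
    final: list[LabeledDecoy] = []
    for gid in sorted(by_group):
        ds = by_group[gid]
        if len(ds) > cap:
            idx = rng.choice(len(ds), size=cap, replace=False)
            ds = [ds[i] for i in sorted(idx)]
        final.extend(ds)

    order = rng.permutation(len(final))
    return [final[i] for i in order]


def grouped_split(
    decoys: list[LabeledDecoy],
    fractions: tuple[float, ...] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> list[list[LabeledDecoy]]:
    """Split decoys into disjoint-group partitions (by ``group_id``).

    Groups (e.g. homology superfamilies) are shuffled and assigned whole to
    partitions sized as close to ``fractions`` of the group count as
    possible, so no group spans two partitions.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    groups = sorted({d.group_id for d in decoys})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    shuffled = [groups[i] for i in order]
    n = len(shuffled)
    counts = [max(1, round(f * n)) for f in fractions]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n:
        counts[int(np.argmin(counts))] += 1
    parts, start = [], 0
    for c in counts:
        chunk = set(shuffled[start : start + c])
        parts.append([d for d in decoys if d.group_id in chunk])
        start += c
    return parts


# ---------------------------------------------------------------------------
# evaluation metrics


@dataclass
class RocResult:
    """ROC curve: thresholds swept over unique scores, trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores, labels) -> RocResult:
    """ROC over correct/incorrect labels; ties grouped at one threshold.

    FPR = FP/N and TPR = TP/P at every unique score threshold (prediction
    positive iff score >= threshold); AUC by the trapezoid rule.  Requires
    at least one positive and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-d arrays")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # keep the last index of each tied-score run
    last = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    thresholds = np.r_[np.inf, s[last]]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def precision_recall(scores, labels):
    """Precision-recall series over the threshold sweep.

    Returns (thresholds, precision, recall).  With no positives, recall is
    defined as 1.0 everywhere (nothing to recall) and precision as usual.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    last = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    n_pos = int(labels.sum())
    precision = tp[last] / (tp[last] + fp[last])
    recall = tp[last] / n_pos if n_pos else np.ones_like(precision)
    return s[last], precision, recall


def precision_recall_at(scores, labels, threshold: float = 0.5):
    """(precision, recall, F1) treating score >= threshold as positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def spearman(scores, values) -> float:
    """Spearman rank correlation (average-rank ties) between two series."""
    scores = np.asarray(scores, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least two observations")
    rho = stats.spearmanr(scores, values).statistic
    return float(rho)


def per_target_auc(scores, labels, target_ids) -> dict[str, float]:
    """ROC AUC computed separately within each target's decoy set.

    Targets whose decoys are all one class are skipped (AUC undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    target_ids = np.asarray(target_ids)
    out = {}
    for tid in np.unique(target_ids):
        m = target_ids == tid
        if labels[m].all() or not labels[m].any():
            continue
        out[str(tid)] = roc_curve(scores[m], labels[m]).auc
    return out


# ---------------------------------------------------------------------------
# refinement selection


#: Score threshold that keeps refinement yield while shrinking the decoy pool.
REFINEMENT_SCORE_CUTOFF = 0.47


def select_for_refinement(
    scored: list[tuple[str, float]],
    mode: str = "cutoff",
    value: float = REFINEMENT_SCORE_CUTOFF,
) -> list[tuple[str, float]]:
    """Pick decoys worth refining, by top-N or by score cutoff.

    ``top_n`` keeps the ``value`` highest-scoring decoys (ties broken by
    decoy id); ``cutoff`` keeps every decoy with score >= ``value``
    (boundary inclusive).  Returns (decoy_id, score) pairs sorted by
    descending score then id.
    """
    ranked = sorted(scored, key=lambda t: (-t[1], t[0]))
    if mode == "top_n":
        n = int(value)
        if n <= 0:
            raise ValueError("top_n requires a positive n")
        return ranked[:n]
    if mode == "cutoff":
        return [t for t in ranked if t[1] >= value]
    raise ValueError(f"unknown selection mode '{mode}'")
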