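"""Target-decoy error-rate accounting and score evaluation.

Decoy hits calibrate the error rate among accepted targets: with FP the
number of accepted decoys and TP + FP the number of accepted targets,
the estimated false discovery rate is FDR = 2 * FP / (FP + TP).  The
factor 2 reflects that a random incorrect match is equally likely to
hit the target or the decoy database, so the decoy count estimates only
half of the incorrect accepted matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .psm_io import PSMCollection

__all__ = [
    "AcceptanceReport",
    "ROCPoint",
    "fdr_at_threshold",
    "select_at_fdr",
    "roc_points",
    "roc_auc",
    "overlap_sets",
]


@dataclass
class AcceptanceReport:
    """Accounting of PSMs accepted at a score threshold."""

    threshold: float
    n_accepted_targets: int  # the TP + FP column
    n_accepted_decoys: int   # the FP estimate
    tp_estimate: int
    fdr: float
    digest_breakdown: dict = field(default_factory=dict)
    warning: str | None = None


@dataclass(frozen=True)
class ROCPoint:
    threshold: float
    tpr: float
    fpr: float


def fdr_at_threshold(scores: np.ndarray, coll: PSMCollection, t: float) -> AcceptanceReport:
    """Accept every PSM scoring >= t and estimate the FDR among targets."""
    scores = np.asarray(scores, dtype=float)
    accepted = scores >= t
    is_decoy = coll.is_decoy
    fp = int(np.sum(accepted & is_decoy))
    n_targets = int(np.sum(accepted & ~is_decoy))
    tp = n_targets - fp
    fdr = 0.0 if n_targets == 0 else 2.0 * fp / n_targets
    breakdown = {}
    digest = coll.frame["digest_type"].to_numpy()
    for cat in ("full", "half", "none"):
        breakdown[cat] = int(np.sum(accepted & ~is_decoy & (digest == cat)))
    return AcceptanceReport(
        threshold=float(t),
        n_accepted_targets=n_targets,
        n_accepted_decoys=fp,
        tp_estimate=tp,
        fdr=fdr,
        digest_breakdown=breakdown,
    )


def select_at_fdr(scores: np.ndarray, coll: PSMCollection, level: float) -> AcceptanceReport:
    """Most permissive threshold whose estimated FDR stays within ``level``.

    Scans every distinct observed score, descending.  Accepting nothing
    trivially has FDR 0, so the scan looks for the most permissive
    threshold that accepts at least one target within the level; if no
    such threshold exists, the strictest threshold's report is returned
    with a warning flag.
    """
    if not (0 < level <= 1):
        raise ValueError("level must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    best = None
    for t in np.unique(scores)[::-1]:
        rep = fdr_at_threshold(scores, coll, t)
        if rep.fdr <= level and rep.n_accepted_targets > 0:
            best = rep
    if best is None:
        best = fdr_at_threshold(scores, coll, float(np.max(scores)))
        best.warning = f"no threshold accepts any target at FDR <= {level}"
    return best


def roc_points(
    scores: np.ndarray, positives: np.ndarray, negatives: np.ndarray
) -> list[ROCPoint]:
    """TPR/FPR at every distinct score threshold, descending.

    With simulated data the positives are the planted-correct targets
    and the negatives the planted-incorrect targets plus decoys; with
    real data, targets vs decoys.
    """
    positives = np.asarray(positives, dtype=int)
    negatives = np.asarray(negatives, dtype=int)
    if positives.size == 0 or negatives.size == 0:
        raise ValueError("both positive and negative sets must be nonempty")
    scores = np.asarray(scores, dtype=float)
    pts = []
    for t in np.unique(np.concatenate([scores[positives], scores[negatives]]))[::-1]:
        tp = int(np.sum(scores[positives] >= t))
        fp = int(np.sum(scores[negatives] >= t))
        pts.append(
            ROCPoint(
                threshold=float(t),
                tpr=tp / positives.size,
                fpr=fp / negatives.size,
            )
        )
    return pts


def roc_auc(scores: np.ndarray, positives: np.ndarray, negatives: np.ndarray) -> float:
    """Area under the ROC curve by trapezoidal integration over (0,0)->(1,1)."""
    pts = roc_points(scores, positives, negatives)
    fpr = np.concatenate([[0.0], [p.fpr for p in pts], [1.0]])
    tpr = np.concatenate([[0.0], [p.tpr for p in pts], [1.0]])
    return float(np.trapezoid(tpr, fpr))


def overlap_sets(**named_sets) -> dict[str, int]:
    """Cardinalities of every region of a 2- or 3-set Venn partition.

    Keys of the result name the exclusive regions by the sets they
    belong to, joined with '&' (e.g. ``"a&b"`` is in a and b but not in
    any other set).
    """
    names = list(named_sets)
    if len(names) not in (2, 3):
        raise ValueError("overlap_sets takes 2 or 3 named sets")
    sets = {n: set(map(int, np.asarray(list(v), dtype=int))) for n, v in named_sets.items()}
    universe = set().union(*sets.values())
    out: dict[str, int] = {}
    from itertools import combinations

    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set(universe)
            for n in combo:
                inside &= sets[n]
            for n in names:
                if n not in combo:
                    inside -= sets[n]
            out["&".join(combo)] = len(inside)
    return out
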