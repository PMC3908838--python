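"""Silhouette cluster-validity indices, classic and fuzzy.

The classic silhouette compares a point's mean within-cluster distance
``a_i`` to its smallest mean distance to another cluster ``b_i``:
``s_i = (b_i - a_i) / max(a_i, b_i)``, in [-1, 1].

The fuzzy variant specialises to the two-group setting used for PSM
rescoring (good targets Omega_1 vs decoys Omega_-1) and weights each
distance by the membership weight theta_j of the reference point:

    beta_i^k = sum_{j in Omega_k, j != i} theta_j d(x_i, x_j)
               / sum_{j in Omega_k, j != i} theta_j,      k in {1, -1}
    s_i      = (beta_i^-1 - beta_i^1) / max(beta_i^-1, beta_i^1).

A large s_i means the point sits inside the (weighted) good-target
cloud and far from the decoys.  The separation statistic
``sep = (s_bar_1 - s_bar_-1) / 2`` — half the gap between the two
groups' average silhouettes — measures how cleanly the current good set
has pulled away from the decoys.

For large collections the reference sums may run over a seeded
rho-subsample of each group instead of the full group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "SilhouetteConfig",
    "SilhouetteState",
    "classic_silhouette",
    "fuzzy_silhouette",
    "separation",
]


@dataclass
class SilhouetteConfig:
    """Distance metric and subsampling rate for silhouette evaluation."""

    distance: str = "euclidean"
    rho: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.distance != "euclidean":
            raise ValueError(f"unsupported distance {self.distance!r}")
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")


@dataclass
class SilhouetteState:
    """Per-PSM silhouettes and the group summaries derived from them."""

    s: np.ndarray
    beta_pos: np.ndarray
    beta_neg: np.ndarray
    s_bar: dict = field(default_factory=dict)
    sep: float = float("nan")


def classic_silhouette(points: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    """Crisp silhouette value per point for an arbitrary K-group partition.

    A point alone in its cluster has no within-cluster distance; its
    silhouette is defined as 0.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    clusters = np.asarray(clusters)
    labels = np.unique(clusters)
    if labels.size < 2:
        raise ValueError("need at least two clusters")
    D = cdist(points, points)
    n = len(points)
    s = np.zeros(n)
    for i in range(n):
        own = clusters == clusters[i]
        m = int(own.sum())
        if m < 2:
            continue  # singleton: s_i = 0 by convention
        a = D[i, own].sum() / (m - 1)
        b = min(D[i, clusters == lab].mean() for lab in labels if lab != clusters[i])
        s[i] = (b - a) / max(a, b)
    return s


def _group_beta(
    D: np.ndarray,
    theta_ref: np.ndarray,
    ref_indices: np.ndarray,
    group_name: str,
) -> np.ndarray:
    """Weighted mean distance of every row point to the reference group.

    ``D`` is (n, m) distances to the reference points; the j != i
    exclusion is handled by subtracting the self term, which contributes
    0 to the numerator and theta_i to the denominator.
    """
    n = D.shape[0]
    numer = D @ theta_ref
    denom = np.full(n, theta_ref.sum())
    pos_in_ref = {int(j): k for k, j in enumerate(ref_indices)}
    for i in range(n):
        k = pos_in_ref.get(i)
        if k is not None:
            denom[i] -= theta_ref[k]
    if np.any(denom <= 0):
        bad = int(np.flatnonzero(denom <= 0)[0])
        if len(ref_indices) == 1 and bad == int(ref_indices[0]):
            warnings.warn(
                f"group {group_name} is a singleton; its own silhouette is set to 0"
            )
            out = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), np.nan)
            return out
        raise ValueError(f"group {group_name} has zero membership mass")
    return numer / denom


def fuzzy_silhouette(
    X: np.ndarray,
    theta: np.ndarray,
    omega1: np.ndarray,
    omega_neg: np.ndarray,
    cfg: SilhouetteConfig | None = None,
) -> SilhouetteState:
    """Theta-weighted two-group silhouette for every sample.

    Computed for every row of ``X`` (good targets, bad targets and
    decoys alike); the self-exclusion only applies where the point
    belongs to the reference group.  With ``cfg.rho < 1`` each group is
    replaced by a seeded without-replacement subsample.
    """
    cfg = cfg or SilhouetteConfig()
    X = np.asarray(X, dtype=float)
    theta = np.asarray(theta, dtype=float)
    omega1 = np.asarray(omega1, dtype=int)
    omega_neg = np.asarray(omega_neg, dtype=int)
    if omega1.size == 0 or omega_neg.size == 0:
        raise ValueError("both Omega_1 and Omega_-1 must be nonempty")
    if np.intersect1d(omega1, omega_neg).size:
        raise ValueError("Omega_1 and Omega_-1 must be disjoint")

    if cfg.rho < 1.0:
        rng = np.random.default_rng(cfg.seed)
        sub1 = _subsample(omega1, cfg.rho, rng)
        subn = _subsample(omega_neg, cfg.rho, rng)
    else:
        sub1, subn = omega1, omega_neg

    D1 = cdist(X, X[sub1])
    Dn = cdist(X, X[subn])
    beta_pos = _group_beta(D1, theta[sub1], sub1, "Omega_1")
    beta_neg = _group_beta(Dn, theta[subn], subn, "Omega_-1")

    denom = np.maximum(beta_pos, beta_neg)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (beta_neg - beta_pos) / np.where(denom > 0, denom, 1.0), 0.0)
    s = np.where(np.isnan(beta_pos) | np.isnan(beta_neg), 0.0, s)
    return SilhouetteState(s=s, beta_pos=beta_pos, beta_neg=beta_neg)


def _subsample(indices: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    m = max(1, int(round(rho * indices.size)))
    chosen = rng.choice(indices.size, size=m, replace=False)
    return np.sort(indices[chosen])


def separation(
    state: SilhouetteState,
    omega1: np.ndarray,
    omega_neg: np.ndarray,
    omega0: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """Group-average silhouettes and the separation statistic.

    Returns ``(s_bar_1, s_bar_-1, s_bar_0, sep)`` with
    ``sep = (s_bar_1 - s_bar_-1) / 2``.  ``s_bar_0`` is NaN when the
    bad-target set is empty; it is reported for the iteration trace only.
    """
    omega1 = np.asarray(omega1, dtype=int)
    omega_neg = np.asarray(omega_neg, dtype=int)
    if omega1.size == 0:
        raise ValueError("Omega_1 is empty; the good-target set has degenerated")
    s = state.s
    s_bar_1 = float(s[omega1].mean())
    s_bar_neg = float(s[omega_neg].mean())
    s_bar_0 = float("nan")
    if omega0 is not None and len(omega0):
        s_bar_0 = float(s[np.asarray(omega0, dtype=int)].mean())
    sep = (s_bar_1 - s_bar_neg) / 2.0
    state.s_bar = {"omega1": s_bar_1, "omega_neg": s_bar_neg, "omega0": s_bar_0}
    state.sep = sep
    return s_bar_1, s_bar_neg, s_bar_0, sep
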