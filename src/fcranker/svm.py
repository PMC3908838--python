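"""Fuzzy (instance-weighted) linear-programming SVM with an RBF kernel.

The classifier is trained by solving a linear program rather than the
usual quadratic program: maximise a margin variable ``r`` while paying a
per-sample, weight-scaled slack penalty,

    minimise   -r + c * sum_i theta_i * xi_i
    subject to y_i * (sum_j alpha_j y'_j K(x_i, x_j) + b) >= r - xi_i
               -1 <= alpha_j <= 1,   xi_i >= 0,   r >= 0,   b free.

Target PSMs carry a membership weight theta_i in [0, 1] expressing the
possibility that their +1 label is correct; decoys are pinned at
theta = 1 because their -1 labels are known by construction.  theta = 1
everywhere recovers the plain LP-SVM.

For large collections the expansion may be restricted to a random
column subset Omega' of the kernel matrix (a Nystrom-style reduction):
constraints still range over all samples, but only |Omega'| alpha
variables exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

__all__ = [
    "KernelConfig",
    "SVMModel",
    "rbf_kernel",
    "kernel_matrix",
    "sample_columns",
    "fit_fuzzy_lp_svm",
    "discriminant",
]


@dataclass
class KernelConfig:
    """Kernel and LP hyper-parameters.

    sigma : RBF bandwidth (default 2.0).
    c : slack penalty weight (default 1.0).
    column_fraction : fraction of kernel columns kept in the reduced
        problem; 1.0 solves the full problem.
    seed : seed for column sampling.
    """

    kernel: str = "rbf"
    sigma: float = 2.0
    c: float = 1.0
    column_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kernel != "rbf":
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if not (0 < self.column_fraction <= 1):
            raise ValueError("column_fraction must be in (0, 1]")


@dataclass
class SVMModel:
    """Solution of the fuzzy LP-SVM.

    ``alpha`` is indexed by ``column_indices`` (all of Omega in the full
    problem); ``xi`` by the full training set.
    """

    alpha: np.ndarray
    b: float
    r: float
    xi: np.ndarray
    column_indices: np.ndarray
    objective: float
    solver_status: str


def rbf_kernel(x1: np.ndarray, x2: np.ndarray, sigma: float) -> float:
    """Gaussian kernel exp(-||x1 - x2||^2 / (2 sigma^2))."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError(f"dimension mismatch: {x1.shape} vs {x2.shape}")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d2 = float(np.sum((x1 - x2) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def kernel_matrix(
    X: np.ndarray, rows: np.ndarray, cols: np.ndarray, cfg: KernelConfig
) -> np.ndarray:
    """RBF kernel block K[i, j] = k(x_i, x_j) for i in rows, j in cols."""
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    if cols.size == 0:
        raise ValueError("empty column index set")
    d2 = cdist(X[rows], X[cols], metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * cfg.sigma**2))


def sample_columns(omega: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Sample max(1, round(fraction * |omega|)) indices without replacement.

    Deterministic given ``seed``; ``fraction == 1`` returns ``omega``
    unchanged.
    """
    omega = np.asarray(omega, dtype=int)
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return omega
    m = max(1, int(round(fraction * omega.size)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(omega.size, size=m, replace=False)
    return np.sort(omega[chosen])


def fit_fuzzy_lp_svm(
    K: np.ndarray,
    y: np.ndarray,
    y_cols: np.ndarray,
    theta: np.ndarray,
    cfg: KernelConfig,
    column_indices: np.ndarray | None = None,
) -> SVMModel:
    """Solve the weighted-slack LP-SVM.

    Parameters
    ----------
    K : (l, l') kernel block between all training rows and the expansion
        columns.
    y : labels (+-1) for the l rows; y_cols : labels for the l' columns.
    theta : slack weights over rows (targets in [0, 1], decoys at 1).
    column_indices : original indices of the l' columns, recorded on the
        model for later alignment (defaults to 0..l'-1).

    Variable layout is [alpha (l'), b, xi (l), r].  The LP is always
    feasible (the zero solution has objective 0); it is bounded whenever
    c * sum(theta) >= 1, which holds in the intended regime (c >= 1 and
    at least one decoy pinned at theta = 1).  A failed solve raises
    ``RuntimeError`` carrying the solver status.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    y_cols = np.asarray(y_cols, dtype=float)
    theta = np.asarray(theta, dtype=float)
    l, lp = K.shape
    if column_indices is None:
        column_indices = np.arange(lp)

    # objective: -r + c * sum theta_i xi_i
    c_vec = np.concatenate([np.zeros(lp), [0.0], cfg.c * theta, [-1.0]])

    # y_i (sum_j alpha_j y'_j K_ij + b) + xi_i - r >= 0, as A_ub x <= 0
    A = np.empty((l, lp + l + 2))
    A[:, :lp] = -(y[:, None] * K * y_cols[None, :])
    A[:, lp] = -y
    A[:, lp + 1 : lp + 1 + l] = -np.eye(l)
    A[:, -1] = 1.0
    b_ub = np.zeros(l)

    bounds = (
        [(-1.0, 1.0)] * lp + [(None, None)] + [(0.0, None)] * l + [(0.0, None)]
    )
    res = linprog(c_vec, A_ub=A, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LP-SVM solve failed: {res.status} ({res.message})")

    x = res.x
    return SVMModel(
        alpha=x[:lp],
        b=float(x[lp]),
        r=float(x[-1]),
        xi=x[lp + 1 : lp + 1 + l],
        column_indices=np.asarray(column_indices, dtype=int),
        objective=float(res.fun),
        solver_status=str(res.status),
    )


def discriminant(model: SVMModel, K_eval: np.ndarray, y_cols: np.ndarray) -> np.ndarray:
    """Evaluate f(x) = sum_j alpha_j y'_j k(x_j, x) + b per row of K_eval."""
    K_eval = np.asarray(K_eval, dtype=float)
    if K_eval.shape[1] != model.alpha.size:
        raise ValueError(
            f"kernel block has {K_eval.shape[1]} columns but model expects "
            f"{model.alpha.size}"
        )
    return K_eval @ (model.alpha * np.asarray(y_cols, dtype=float)) + model.b
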