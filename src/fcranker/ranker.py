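"""The iterative rescoring loop.

Starting from the view that every target PSM is good, each iteration

1. fits the fuzzy LP-SVM with the current target weights theta and
   evaluates its discriminant f on every PSM;
2. keeps the top n% of the current good set Omega_1 by f;
3. computes theta-weighted silhouettes of every PSM against the pruned
   good set and the decoys, and keeps the top n% of the pruned set by
   silhouette;
4. measures the separation sep between the good-set and decoy average
   silhouettes, blends f and s into per-PSM scores with sep as the
   mixing weight, and refreshes theta from the scores;
5. promotes any discarded target whose discriminant beats the good-set
   mean back into Omega_1;
6. stops when sep reaches its threshold, when Omega_1 has collapsed
   below a minimum size, or at the iteration cap.

The loop is unsupervised with respect to any ground-truth column: only
the target/decoy flags and the feature matrix drive it.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np

from .psm_io import FeatureMatrix, PSMCollection
from .scoring import ScoringConfig, combine_scores, phi_scale, psi_scale, update_weights
from .silhouette import SilhouetteConfig, fuzzy_silhouette, separation
from .svm import KernelConfig, discriminant, fit_fuzzy_lp_svm, kernel_matrix, sample_columns

__all__ = [
    "RankerConfig",
    "IterationState",
    "RankerResult",
    "init_state",
    "top_fraction",
    "refine_sets",
    "promote_by_mean",
    "check_stop",
    "run_fc_ranker",
]

logger = logging.getLogger(__name__)

#: Termination labels.
SEP_REACHED = "sep_reached"
OMEGA1_COLLAPSED = "omega1_collapsed"
MAX_ITERATIONS = "max_iterations"


@dataclass
class RankerConfig:
    """Tunable parameters of the ranking loop.

    n_percent : percentage of the good set retained by each of the two
        per-iteration cuts (default 70).
    p_hat_fraction : the loop stops when |Omega_1| falls to this
        fraction of the target count (default 0.03).
    sep_hat : separation threshold declaring success (default 0.25).
    max_iterations : safety cap with its own termination label.
    seed : master seed; all column sampling and silhouette subsampling
        seeds are derived from it.
    """

    n_percent: float = 70.0
    p_hat_fraction: float = 0.03
    sep_hat: float = 0.25
    max_iterations: int = 100
    seed: int = 0
    kernel: KernelConfig = field(default_factory=KernelConfig)
    silhouette: SilhouetteConfig = field(default_factory=SilhouetteConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def __post_init__(self):
        if not (0 < self.n_percent < 100):
            raise ValueError("n_percent must be in (0, 100)")
        if not (0 < self.p_hat_fraction < 1):
            raise ValueError("p_hat_fraction must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class IterationState:
    """Mutable loop state at an iteration boundary.

    ``omega1`` and ``omega0`` always partition the target set.
    """

    k: int
    omega1: np.ndarray
    omega0: np.ndarray
    theta: np.ndarray
    f: np.ndarray | None = None
    s: np.ndarray | None = None
    sep: float = float("nan")
    score: np.ndarray | None = None


@dataclass
class RankerResult:
    """Final scores plus the full per-iteration trace."""

    final_scores: np.ndarray
    final_omega1: np.ndarray
    final_theta: np.ndarray
    f: np.ndarray
    s: np.ndarray
    trace: list[dict]
    termination: str

    @property
    def n_iterations(self) -> int:
        return len(self.trace)


def init_state(coll: PSMCollection) -> IterationState:
    """All targets start in the good set with full weight everywhere."""
    targets = coll.targets
    decoys = coll.decoys
    if targets.size == 0 or decoys.size == 0:
        raise ValueError("collection must contain at least one target and one decoy")
    return IterationState(
        k=-1,
        omega1=targets.copy(),
        omega0=np.array([], dtype=int),
        theta=np.ones(len(coll)),
    )


def top_fraction(values: np.ndarray, pool: np.ndarray, n_percent: float) -> np.ndarray:
    """Indices of the ceil(n% * |pool|) largest values within ``pool``.

    Ties at the boundary keep the lower original index; the result is
    never empty and is returned sorted ascending.
    """
    pool = np.asarray(pool, dtype=int)
    if pool.size == 0:
        raise ValueError("pool is empty")
    m = max(1, math.ceil(n_percent / 100.0 * pool.size))
    vals = np.asarray(values, dtype=float)[pool]
    order = np.lexsort((pool, -vals))  # primary: value desc; secondary: index asc
    return np.sort(pool[order[:m]])


def refine_sets(
    state: IterationState, f: np.ndarray, s: np.ndarray, cfg: RankerConfig, targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two nested top-n% cuts (by f, then by s) and the discarded remainder."""
    if state.omega1.size == 0:
        raise ValueError("Omega_1 is empty; the loop should already have stopped")
    omega1_third = top_fraction(f, state.omega1, cfg.n_percent)
    omega1_two_thirds = top_fraction(s, omega1_third, cfg.n_percent)
    omega0_partial = np.setdiff1d(targets, omega1_two_thirds)
    return omega1_two_thirds, omega0_partial


def promote_by_mean(
    omega1_two_thirds: np.ndarray,
    omega0_partial: np.ndarray,
    f: np.ndarray,
    targets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Return discarded targets whose f beats the good-set mean to Omega_1."""
    omega1_two_thirds = np.asarray(omega1_two_thirds, dtype=int)
    if omega1_two_thirds.size == 0:
        raise ValueError("good set is empty")
    f = np.asarray(f, dtype=float)
    f_bar = float(f[omega1_two_thirds].mean())
    promoted = omega0_partial[f[omega0_partial] >= f_bar]
    omega1_next = np.union1d(omega1_two_thirds, promoted)
    omega0_next = np.setdiff1d(targets, omega1_next)
    return omega1_next, omega0_next


def check_stop(
    omega1_size: int, sep: float, cfg: RankerConfig, k: int, n_targets: int
) -> str | None:
    """Which termination criterion fires, if any."""
    p_hat = cfg.p_hat_fraction * n_targets
    if omega1_size <= p_hat:
        return OMEGA1_COLLAPSED
    if sep >= cfg.sep_hat:
        return SEP_REACHED
    if k + 1 >= cfg.max_iterations:
        return MAX_ITERATIONS
    return None


def _derived_seed(master: int, *salt: int) -> int:
    return int(np.random.SeedSequence([int(master), *salt]).generate_state(1)[0] % (2**31))


def run_fc_ranker(
    coll: PSMCollection, X: FeatureMatrix | np.ndarray, cfg: RankerConfig | None = None
) -> RankerResult:
    """Run the full iterative rescoring loop on a PSM collection.

    Deterministic given ``cfg.seed``.  Returns the last computed score
    for every PSM, the final good set, and a per-iteration trace of
    (|Omega_1|, group silhouettes, sep, LP objective).
    """
    cfg = cfg or RankerConfig()
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = coll.y.astype(float)
    targets = coll.targets
    decoys = coll.decoys
    omega = coll.omega
    state = init_state(coll)

    # Expansion columns are drawn once per run; the kernel block is fixed.
    col_seed = _derived_seed(cfg.seed, 17)
    omega_cols = sample_columns(omega, cfg.kernel.column_fraction, col_seed)
    K = kernel_matrix(Xv, omega, omega_cols, cfg.kernel)
    y_cols = y[omega_cols]

    trace: list[dict] = []
    termination = MAX_ITERATIONS
    k = -1
    while True:
        k += 1
        t0 = time.perf_counter()

        model = fit_fuzzy_lp_svm(K, y, y_cols, state.theta, cfg.kernel, omega_cols)
        f = discriminant(model, K, y_cols)

        omega1_third = top_fraction(f, state.omega1, cfg.n_percent)

        sil_cfg = SilhouetteConfig(
            distance=cfg.silhouette.distance,
            rho=cfg.silhouette.rho,
            seed=_derived_seed(cfg.seed, 29, k),
        )
        sil = fuzzy_silhouette(Xv, state.theta, omega1_third, decoys, sil_cfg)
        s = sil.s

        omega1_two_thirds = top_fraction(s, omega1_third, cfg.n_percent)
        omega0_partial = np.setdiff1d(targets, omega1_two_thirds)

        omega1_next, omega0_next = promote_by_mean(
            omega1_two_thirds, omega0_partial, f, targets
        )

        # sep is averaged over the promoted good set, not the subset
        # just selected for high silhouette — averaging over the
        # selected subset would inflate sep by construction.
        s_bar_1, s_bar_neg, s_bar_0, sep = separation(
            sil, omega1_next, decoys, omega0_next
        )
        # Early iterations can give slightly negative sep; a negative
        # mixing weight would invert the silhouette evidence, so the mix
        # uses sep clamped to [0, 1].  The raw sep drives the stop rule.
        sep_mix = min(max(sep, 0.0), 1.0)

        phi = phi_scale(f, targets, cfg.scoring)
        psi = psi_scale(s, targets, cfg.scoring)
        score = combine_scores(phi, psi, sep_mix)
        theta = update_weights(score, coll.is_decoy)

        trace.append(
            {
                "iter": k,
                "n_omega1": int(omega1_next.size),
                "s_bar_pos": s_bar_1,
                "s_bar_neg": s_bar_neg,
                "s_bar_0": s_bar_0,
                "sep": sep,
                "objective": model.objective,
            }
        )
        logger.info(
            "iter %d: |Omega_1|=%d sep=%.4f objective=%.4f (%.2fs)",
            k, omega1_next.size, sep, model.objective, time.perf_counter() - t0,
        )

        state = IterationState(
            k=k, omega1=omega1_next, omega0=omega0_next, theta=theta,
            f=f, s=s, sep=sep, score=score,
        )

        decision = check_stop(omega1_next.size, sep, cfg, k, targets.size)
        if decision is not None:
            termination = decision
            break

    return RankerResult(
        final_scores=state.score,
        final_omega1=state.omega1,
        final_theta=state.theta,
        f=state.f,
        s=state.s,
        trace=trace,
        termination=termination,
    )
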