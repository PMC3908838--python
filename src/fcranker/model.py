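"""Model / results interface over the iterative rescorer.

``FCRanker`` is constructed from a PSM collection (or DataFrame, or a
TSV on disk), owns the preprocessing and configuration, and ``fit()``
runs the iterative loop and returns an ``FCRankerResults`` carrying the
per-PSM scores, the final good-target set, the iteration trace and the
evaluation helpers (FDR selection, ROC, summary table).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import evaluation
from .config import make_config
from .psm_io import (
    PreprocessConfig,
    PSMCollection,
    TableDialect,
    build_feature_matrix,
    read_psm_table,
    write_psm_table,
)
from .ranker import RankerConfig, RankerResult, run_fc_ranker

__all__ = ["FCRanker", "FCRankerResults"]


class FCRanker:
    """Confidence rescorer for target PSMs against decoys.

    Parameters
    ----------
    collection : PSMCollection
        The PSM table; must contain at least one target and one decoy.
    preprocess : PreprocessConfig, optional
        Feature selection and attribute weights.
    config : RankerConfig, optional
        Full nested configuration; mutually exclusive with ``**params``.
    **params
        Flat configuration keys (``sigma``, ``c``, ``n_percent``,
        ``sep_hat``, ``seed``, ...), see :func:`fcranker.config.make_config`.
    """

    def __init__(
        self,
        collection: PSMCollection,
        preprocess: PreprocessConfig | None = None,
        config: RankerConfig | None = None,
        **params,
    ):
        if config is not None and params:
            raise ValueError("pass either a RankerConfig or flat keyword parameters")
        self.collection = collection
        self.preprocess = preprocess or PreprocessConfig()
        self.config = config or make_config(**params)
        self.exog = build_feature_matrix(collection, self.preprocess)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "FCRanker":
        return cls(PSMCollection(frame), **kwargs)

    @classmethod
    def from_table(cls, path, dialect: TableDialect | None = None, **kwargs) -> "FCRanker":
        return cls(read_psm_table(path, dialect), **kwargs)

    def fit(self) -> "FCRankerResults":
        """Run the iterative loop to termination."""
        raw = run_fc_ranker(self.collection, self.exog, self.config)
        return FCRankerResults(self, raw)


class FCRankerResults:
    """Scores, set memberships and diagnostics from a fitted rescorer."""

    def __init__(self, model: FCRanker, raw: RankerResult):
        self.model = model
        self._raw = raw

    # -- estimates ----------------------------------------------------
    @property
    def scores(self) -> np.ndarray:
        """Final confidence score per PSM, in score order of the input."""
        return self._raw.final_scores

    @property
    def theta(self) -> np.ndarray:
        """Final fuzzy weights (targets in [0, 1], decoys at 1)."""
        return self._raw.final_theta

    @property
    def omega1(self) -> np.ndarray:
        """Positional indices of the final good-target set."""
        return self._raw.final_omega1

    @property
    def discriminant(self) -> np.ndarray:
        return self._raw.f

    @property
    def silhouettes(self) -> np.ndarray:
        return self._raw.s

    @property
    def termination(self) -> str:
        return self._raw.termination

    @property
    def n_iterations(self) -> int:
        return self._raw.n_iterations

    @property
    def trace(self) -> pd.DataFrame:
        """Per-iteration |Omega_1|, group silhouettes, sep and LP objective."""
        return pd.DataFrame(self._raw.trace)

    @property
    def sep(self) -> float:
        """Separation statistic at the final iteration."""
        return float(self._raw.trace[-1]["sep"])

    # -- evaluation ---------------------------------------------------
    def select_at_fdr(self, level: float = 0.05) -> evaluation.AcceptanceReport:
        return evaluation.select_at_fdr(self.scores, self.model.collection, level)

    def roc(self, use_truth: bool = False) -> list[evaluation.ROCPoint]:
        pos, neg = self._roc_sets(use_truth)
        return evaluation.roc_points(self.scores, pos, neg)

    def auc(self, use_truth: bool = False) -> float:
        pos, neg = self._roc_sets(use_truth)
        return evaluation.roc_auc(self.scores, pos, neg)

    def _roc_sets(self, use_truth: bool) -> tuple[np.ndarray, np.ndarray]:
        coll = self.model.collection
        if use_truth:
            truth = coll.truth
            if truth is None:
                raise ValueError("collection carries no ground-truth column")
            return np.flatnonzero(truth), np.flatnonzero(~truth)
        return coll.targets, coll.decoys

    # -- export -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Input table plus score, theta, f, silhouette and membership."""
        df = self.model.collection.frame.copy()
        df["score"] = self.scores
        df["theta"] = self.theta
        df["f"] = self.discriminant
        df["silhouette"] = self.silhouettes
        in_omega1 = np.zeros(len(df), dtype=int)
        in_omega1[self.omega1] = 1
        df["in_omega1"] = in_omega1
        return df

    def save_scores(self, path) -> None:
        extra = self.to_frame()[["score", "theta", "f", "silhouette", "in_omega1"]]
        write_psm_table(self.model.collection, path, extra_columns=extra)

    def save_trace(self, path) -> None:
        self.trace.assign(termination=self.termination).to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        """Human-readable fit summary."""
        coll = self.model.collection
        rep = self.select_at_fdr(0.05)
        lines = [
            "FC-Ranker results",
            "=" * 50,
            f"PSMs:              {len(coll)} ({coll.targets.size} targets, "
            f"{coll.decoys.size} decoys)",
            f"Iterations:        {self.n_iterations}",
            f"Termination:       {self.termination}",
            f"Final sep:         {self.sep:.4f}",
            f"|Omega_1| (good):  {self.omega1.size}",
            "-" * 50,
            "Acceptance at FDR <= 0.05:",
            f"  threshold:       {rep.threshold:.4f}",
            f"  targets (TP+FP): {rep.n_accepted_targets}",
            f"  decoys (FP):     {rep.n_accepted_decoys}",
            f"  TP estimate:     {rep.tp_estimate}",
            f"  FDR estimate:    {rep.fdr:.4f}",
        ]
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Plot s_bar_1, s_bar_-1 and sep against the iteration index."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tr = self.trace
        ax.plot(tr["iter"], tr["s_bar_pos"], marker="o", label=r"$\bar{s}_1$")
        ax.plot(tr["iter"], tr["s_bar_neg"], marker="s", label=r"$\bar{s}_{-1}$")
        ax.plot(tr["iter"], tr["sep"], marker="^", label="sep")
        ax.set_xlabel("iteration")
        ax.set_ylabel("silhouette / sep")
        ax.legend()
        return ax
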