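"""Score combination and fuzzy-weight updates.

The per-PSM confidence score blends the two lines of evidence —
classifier margin and cluster cohesion — with the current separation
statistic as the mixing weight:

    score(i) = (1 - sep) * phi(f(x_i)) + sep * psi(s_i).

``phi`` squashes the discriminant value through a signed quarter-power
arctangent so that extreme margins saturate smoothly; ``psi`` rescales
the silhouette linearly.  Both are normalised by the largest deviation
observed among the target PSMs, so the extreme target maps to +-0.5
(phi) or 1 (psi).  The fuzzy weight of each target is then the positive
part of its score; decoy weights stay pinned at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScoringConfig",
    "ScoreState",
    "phi_scale",
    "psi_scale",
    "combine_scores",
    "update_weights",
]


@dataclass
class ScoringConfig:
    """Thresholds marking the 'uncertain' point of each scale.

    f0 : discriminant threshold (default 0, the decision boundary).
    s0 : silhouette threshold (default 0, the neutral silhouette).
    """

    f0: float = 0.0
    s0: float = 0.0


@dataclass
class ScoreState:
    phi: np.ndarray
    psi: np.ndarray
    score: np.ndarray
    theta: np.ndarray
    f_max: float = 0.0
    s_max: float = 0.0
    extras: dict = field(default_factory=dict)


def phi_scale(f: np.ndarray, targets: np.ndarray, cfg: ScoringConfig | None = None) -> np.ndarray:
    """Squash discriminant values into (-1, 1).

    phi(f) = (2/pi) * sign(f - f0) * atan((|f - f0| / f_max)^(1/4)),
    with f_max the largest |f - f0| over the target PSMs.  The 1/4
    exponent flattens the map near f0 so mid-range margins keep
    distinct weights.  Degenerate f_max = 0 maps everything to 0.
    """
    cfg = cfg or ScoringConfig()
    f = np.asarray(f, dtype=float)
    targets = np.asarray(targets, dtype=int)
    if targets.size == 0:
        raise ValueError("target index set is empty")
    dev = f - cfg.f0
    f_max = float(np.max(np.abs(dev[targets])))
    if f_max == 0:
        return np.zeros_like(f)
    return (2.0 / np.pi) * np.sign(dev) * np.arctan((np.abs(dev) / f_max) ** 0.25)


def psi_scale(s: np.ndarray, targets: np.ndarray, cfg: ScoringConfig | None = None) -> np.ndarray:
    """Linearly rescale silhouettes: psi(s) = (s - s0) / s_max.

    s_max is the largest |s - s0| over the target PSMs; decoys may land
    outside [-1, 1] and are reported unclamped.
    """
    cfg = cfg or ScoringConfig()
    s = np.asarray(s, dtype=float)
    targets = np.asarray(targets, dtype=int)
    if targets.size == 0:
        raise ValueError("target index set is empty")
    dev = s - cfg.s0
    s_max = float(np.max(np.abs(dev[targets])))
    if s_max == 0:
        return np.zeros_like(s)
    return dev / s_max


def combine_scores(phi: np.ndarray, psi: np.ndarray, sep: float) -> np.ndarray:
    """score = (1 - sep) * phi + sep * psi."""
    if not np.isfinite(sep):
        raise ValueError("sep must be finite")
    return (1.0 - sep) * np.asarray(phi, float) + sep * np.asarray(psi, float)


def update_weights(score: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """theta_i = max(score_i, 0) for targets; 1 for decoys."""
    score = np.asarray(score, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    return np.where(is_decoy, 1.0, np.maximum(score, 0.0))
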