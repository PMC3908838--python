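"""Flat key-value configuration mapped onto the nested config objects."""

from __future__ import annotations

import yaml

from .ranker import RankerConfig
from .scoring import ScoringConfig
from .silhouette import SilhouetteConfig
from .svm import KernelConfig

__all__ = ["make_config", "load_config"]

_TOP = {"n_percent", "p_hat_fraction", "sep_hat", "max_iterations", "seed"}
_KERNEL = {"kernel", "sigma", "c", "column_fraction"}
_SIL = {"distance", "rho"}
_SCORING = {"f0", "s0"}


def make_config(**kwargs) -> RankerConfig:
    """Build a ``RankerConfig`` from flat keys.

    Recognised keys: n_percent, p_hat_fraction, sep_hat,
    max_iterations, seed, kernel, sigma, c, column_fraction, distance,
    rho, f0, s0.  Unknown keys raise ``ValueError``.
    """
    top, kern, sil, scor = {}, {}, {}, {}
    for key, value in kwargs.items():
        if key in _TOP:
            top[key] = value
        elif key in _KERNEL:
            kern[key] = value
        elif key in _SIL:
            sil[key] = value
        elif key in _SCORING:
            scor[key] = value
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    return RankerConfig(
        **top,
        kernel=KernelConfig(**kern),
        silhouette=SilhouetteConfig(**sil),
        scoring=ScoringConfig(**scor),
    )


def load_config(path) -> RankerConfig:
    """Load a flat key-value (YAML) configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration file must contain flat key: value pairs")
    return make_config(**data)
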