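"""Reading, writing and preprocessing of PSM tables.

A PSM (peptide-spectrum match) table is a tab-separated file with one row
per search-engine hit.  Each hit carries the SEQUEST-style quality
attributes used downstream as classifier features (``xcorr``,
``delta_cn``, ``ions``, ``sprank``, ``calc_neutral_pep_mass`` and the
tryptic-digest conformity category ``digest_type``) together with a
target/decoy flag and, for simulated data, a ground-truth flag.

Features are z-scored jointly over targets and decoys and then multiplied
by per-attribute importance weights (2.0 for ``xcorr``, ``delta_cn`` and
``digest_type`` by default, 1.0 otherwise) before any kernel or distance
computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_COLUMNS",
    "DIGEST_CODES",
    "PSMRecord",
    "PSMCollection",
    "TableDialect",
    "PreprocessConfig",
    "FeatureMatrix",
    "encode_digest_type",
    "read_psm_table",
    "write_psm_table",
    "build_feature_matrix",
]

#: Canonical feature columns, in table order.
FEATURE_COLUMNS = (
    "xcorr",
    "delta_cn",
    "ions",
    "sprank",
    "calc_neutral_pep_mass",
    "digest_type",
)

#: Numeric codes for tryptic-digest conformity of the peptide termini.
DIGEST_CODES = {"full": 2, "half": 1, "none": 0}
_CODE_TO_DIGEST = {v: k for k, v in DIGEST_CODES.items()}

_NUMERIC_COLUMNS = ("xcorr", "delta_cn", "ions", "sprank", "calc_neutral_pep_mass")


def encode_digest_type(n_term_conforms: bool, c_term_conforms: bool) -> tuple[str, int]:
    """Classify tryptic conformity of the two peptide termini.

    Returns the category name and its numeric code: both termini conform
    -> ``("full", 2)``, exactly one -> ``("half", 1)``, neither ->
    ``("none", 0)``.
    """
    code = int(bool(n_term_conforms)) + int(bool(c_term_conforms))
    return _CODE_TO_DIGEST[code], code


@dataclass(frozen=True)
class PSMRecord:
    """A single peptide-spectrum match with its raw attributes."""

    psm_id: str
    spectrum_ref: str
    is_decoy: bool
    xcorr: float
    delta_cn: float
    ions: float
    sprank: float
    calc_neutral_pep_mass: float
    digest_type: str
    peptide: str | None = None
    truth: bool | None = None

    @property
    def y(self) -> int:
        """Class label: +1 for target, -1 for decoy."""
        return -1 if self.is_decoy else 1


@dataclass(frozen=True)
class TableDialect:
    """How to interpret a PSM table on disk.

    Decoy status comes either from an explicit 0/1 column
    (``decoy_column``) or, when that column is absent, from an accession
    column whose values start with ``decoy_prefix``.
    """

    sep: str = "\t"
    decoy_column: str = "is_decoy"
    accession_column: str = "protein"
    decoy_prefix: str | None = None


class PSMCollection:
    """An ordered collection of PSMs backed by a DataFrame.

    Exposes the index sets the ranking algorithm works on: ``omega``
    (all rows), ``targets`` and ``decoys`` (positional indices).
    """

    def __init__(self, frame: pd.DataFrame, n_rejected: int = 0):
        if len(frame) == 0:
            raise ValueError("PSM collection is empty")
        self._frame = frame.reset_index(drop=True)
        self.n_rejected = int(n_rejected)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def omega(self) -> np.ndarray:
        return np.arange(len(self._frame))

    @property
    def is_decoy(self) -> np.ndarray:
        return self._frame["is_decoy"].to_numpy(dtype=bool)

    @property
    def targets(self) -> np.ndarray:
        """Positional indices of target PSMs (label +1)."""
        return np.flatnonzero(~self.is_decoy)

    @property
    def decoys(self) -> np.ndarray:
        """Positional indices of decoy PSMs (label -1)."""
        return np.flatnonzero(self.is_decoy)

    @property
    def y(self) -> np.ndarray:
        """Labels in {+1, -1}, row-aligned with the table."""
        return np.where(self.is_decoy, -1, 1)

    @property
    def truth(self) -> np.ndarray | None:
        """Planted ground truth from the simulator, or None for real data."""
        if "truth" not in self._frame.columns:
            return None
        return self._frame["truth"].to_numpy(dtype=bool)

    @property
    def records(self) -> list[PSMRecord]:
        out = []
        has_truth = "truth" in self._frame.columns
        for row in self._frame.itertuples(index=False):
            out.append(
                PSMRecord(
                    psm_id=str(row.psm_id),
                    spectrum_ref=str(row.spectrum_ref),
                    is_decoy=bool(row.is_decoy),
                    xcorr=float(row.xcorr),
                    delta_cn=float(row.delta_cn),
                    ions=float(row.ions),
                    sprank=float(row.sprank),
                    calc_neutral_pep_mass=float(row.calc_neutral_pep_mass),
                    digest_type=str(row.digest_type),
                    peptide=(str(row.peptide) if "peptide" in self._frame.columns else None),
                    truth=(bool(row.truth) if has_truth else None),
                )
            )
        return out


@dataclass
class PreprocessConfig:
    """Feature selection and per-attribute importance weights.

    ``attribute_weights`` multiplies each z-scored column; the defaults
    up-weight the attributes that carry the most discriminative signal.
    """

    attribute_weights: Mapping[str, float] = field(
        default_factory=lambda: {"xcorr": 2.0, "delta_cn": 2.0, "digest_type": 2.0}
    )
    include_columns: Sequence[str] = FEATURE_COLUMNS

    def weight_for(self, column: str) -> float:
        w = float(self.attribute_weights.get(column, 1.0))
        if w <= 0:
            raise ValueError(f"attribute weight for {column!r} must be > 0")
        return w


@dataclass
class FeatureMatrix:
    """Normalized, attribute-weighted features row-aligned with a collection."""

    values: np.ndarray
    column_names: list[str]
    column_means: np.ndarray
    column_sds: np.ndarray
    attribute_weights: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]


def _digest_to_code(values: pd.Series) -> pd.Series:
    def convert(v):
        if isinstance(v, str) and v in DIGEST_CODES:
            return DIGEST_CODES[v]
        code = int(v)
        if code not in _CODE_TO_DIGEST:
            raise ValueError(f"invalid digest_type value {v!r}")
        return code

    return values.map(convert)


def read_psm_table(path, dialect: TableDialect | None = None) -> PSMCollection:
    """Read a PSM table from a delimited text file.

    Rows whose numeric attribute fields fail to parse are dropped; their
    count is reported via a warning and on ``PSMCollection.n_rejected``.
    Raises ``ValueError`` if a mandatory column is missing or the table
    is empty.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype={"psm_id": str})
    missing = [c for c in _NUMERIC_COLUMNS + ("digest_type",) if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table is missing mandatory column(s): {', '.join(missing)}")

    if dialect.decoy_column in df.columns:
        df["is_decoy"] = df[dialect.decoy_column].astype(int).astype(bool)
    elif dialect.decoy_prefix is not None:
        if dialect.accession_column not in df.columns:
            raise ValueError(
                f"PSM table is missing mandatory column(s): {dialect.accession_column}"
            )
        df["is_decoy"] = (
            df[dialect.accession_column].astype(str).str.startswith(dialect.decoy_prefix)
        )
    else:
        raise ValueError(
            f"PSM table is missing mandatory column(s): {dialect.decoy_column}"
        )

    if len(df) == 0:
        raise ValueError("PSM table contains no data rows")

    for col in ("psm_id", "spectrum_ref"):
        if col not in df.columns:
            df[col] = [f"{col}_{i}" for i in range(len(df))]

    coerced = df[list(_NUMERIC_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    n_rejected = int(bad.sum())
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} row(s) with unparseable numeric fields")
        df = df.loc[~bad].reset_index(drop=True)
        coerced = coerced.loc[~bad].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("PSM table contains no parseable data rows")
    df[list(_NUMERIC_COLUMNS)] = coerced

    codes = _digest_to_code(df["digest_type"])
    df["digest_type"] = codes.map(_CODE_TO_DIGEST)
    if "truth" in df.columns:
        df["truth"] = df["truth"].astype(int).astype(bool)
    return PSMCollection(df, n_rejected=n_rejected)


def write_psm_table(coll: PSMCollection, path, extra_columns: pd.DataFrame | None = None) -> None:
    """Write a collection back to TSV; round-trips all canonical fields."""
    df = coll.frame.copy()
    for col in ("is_decoy", "truth"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    if extra_columns is not None:
        for name in extra_columns.columns:
            df[name] = np.asarray(extra_columns[name])
    df.to_csv(path, sep="\t", index=False)


def build_feature_matrix(coll: PSMCollection, cfg: PreprocessConfig | None = None) -> FeatureMatrix:
    """Z-score the selected attributes and apply importance weights.

    Each column is centred and scaled to unit variance (population
    variance, computed over all PSMs — targets and decoys jointly), then
    multiplied by its attribute weight.  Constant columns map to zero.
    """
    cfg = cfg or PreprocessConfig()
    columns = list(cfg.include_columns)
    if not columns:
        raise ValueError("no feature columns selected")

    raw = np.empty((len(coll), len(columns)), dtype=float)
    for j, name in enumerate(columns):
        if name not in coll.frame.columns:
            raise ValueError(f"PSM table is missing mandatory column(s): {name}")
        if name == "digest_type":
            raw[:, j] = _digest_to_code(coll.frame[name]).to_numpy(dtype=float)
        else:
            raw[:, j] = coll.frame[name].to_numpy(dtype=float)

    means = raw.mean(axis=0)
    sds = raw.std(axis=0)  # population (1/N) standard deviation
    weights = np.array([cfg.weight_for(c) for c in columns])

    values = np.zeros_like(raw)
    nonconst = sds > 0
    values[:, nonconst] = (raw[:, nonconst] - means[nonconst]) / sds[nonconst]
    values *= weights
    return FeatureMatrix(
        values=values,
        column_names=columns,
        column_means=means,
        column_sds=sds,
        attribute_weights=weights,
    )
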