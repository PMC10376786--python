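"""Tabular I/O and the shared data model.

The pipeline works on two companion tables: a samples x features abundance
matrix (``FeatureTable``) holding protein concentrations (fmol/uL serum)
and/or TIC-normalized lipid peak areas, and a per-sample clinical table
(``ClinicalTable``) carrying the metastasis label, the regional lymph-node
metastasis count and the usual breast-cancer covariates.  Values are kept on
the raw measurement scale throughout: downstream product terms and logistic
coefficients are only interpretable on that scale.

Missing cells are explicit (NaN), never encoded as zero.  Features missing in
more than ``max_missing_frac`` of samples are dropped at load; the remaining
missing cells are imputed as half the feature's observed minimum, a common
omics convention.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "ClinicalTable",
    "ContingencyTable",
    "FormatError",
    "ValidationError",
    "read_feature_table",
    "write_feature_table",
    "read_clinical_table",
    "write_clinical_table",
    "crosstab",
    "impute_missing",
]

ANALYTE_CLASSES = ("protein", "lipid")
UNITS = ("fmol_per_uL", "intensity_au")
ION_MODES = ("positive", "negative", "na")

GROUP_LEVELS = ("non_metastatic", "metastatic")
SUBTYPE_LEVELS = ("LumA", "LumB-", "LumB+", "Her2+", "TNBC")
GRADE_LEVELS = (1, 2, 3)

#: clinical columns that are treated as categorical by crosstab / screening
CATEGORICAL_COLUMNS = (
    "group",
    "subtype",
    "histotype",
    "grade",
    "multifocality",
    "stage",
    "her2",
)


class FormatError(ValueError):
    """Structurally malformed input (duplicate ids, missing columns...)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant (negative abundance...)."""


@dataclasses.dataclass
class FeatureTable:
    """Samples x features abundance matrix plus per-feature metadata.

    ``values`` is a float ndarray with shape (n_samples, n_features);
    missing entries are NaN.  ``feature_meta`` is a DataFrame indexed by
    feature id with columns ``analyte_class``, ``units`` and ``ion_mode``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.feature_ids, "feature id")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} != "
                f"({len(self.sample_ids)}, {len(self.feature_ids)})"
            )
        neg = np.argwhere(self.values < 0)
        if neg.size:
            cells = ", ".join(
                f"({self.sample_ids[i]}, {self.feature_ids[j]})" for i, j in neg[:10]
            )
            raise ValidationError(f"negative abundance at {cells}")
        if not self.feature_meta.index.equals(pd.Index(self.feature_ids)):
            self.feature_meta = self.feature_meta.reindex(self.feature_ids)
        for col, allowed in (
            ("analyte_class", ANALYTE_CLASSES),
            ("units", UNITS),
            ("ion_mode", ION_MODES),
        ):
            bad = set(self.feature_meta[col].dropna()) - set(allowed)
            if bad:
                raise ValidationError(f"invalid {col} values: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        """Return a new table restricted to ``feature_ids`` (given order)."""
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in idx]
        if missing:
            raise KeyError(f"unknown feature ids: {missing[:5]}")
        cols = [idx[f] for f in feature_ids]
        return FeatureTable(
            sample_ids=list(self.sample_ids),
            feature_ids=list(feature_ids),
            values=self.values[:, cols].copy(),
            feature_meta=self.feature_meta.iloc[cols].copy(),
        )

    def features_of_class(self, analyte_class: str) -> list[str]:
        mask = self.feature_meta["analyte_class"] == analyte_class
        return list(self.feature_meta.index[mask])


@dataclasses.dataclass
class ClinicalTable:
    """Per-sample clinical covariates including the metastasis label."""

    data: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("group", "n_metastases")

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in clinical table")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"clinical table missing required column {col!r}")
        bad_group = set(df["group"].dropna()) - set(GROUP_LEVELS)
        if bad_group:
            raise ValidationError(f"invalid group levels: {sorted(bad_group)}")
        if "subtype" in df.columns:
            bad = set(df["subtype"].dropna()) - set(SUBTYPE_LEVELS)
            if bad:
                raise ValidationError(f"invalid subtype levels: {sorted(bad)}")
        if "grade" in df.columns:
            bad = set(df["grade"].dropna()) - set(GRADE_LEVELS)
            if bad:
                raise ValidationError(f"invalid grade values: {sorted(bad)}")
        nm = df["n_metastases"].to_numpy()
        if np.any(nm < 0) or np.any(nm != np.floor(nm)):
            raise ValidationError("n_metastases must be non-negative integers")
        inconsistent = (df["group"] == "non_metastatic") & (df["n_metastases"] > 0)
        if inconsistent.any():
            ids = list(df.index[inconsistent][:5])
            raise ValidationError(
                f"non_metastatic samples with n_metastases > 0: {ids}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def group(self) -> pd.Series:
        return self.data["group"]

    def binary_labels(self) -> np.ndarray:
        """0/1 vector, 1 = metastatic (the positive class throughout)."""
        return (self.data["group"] == "metastatic").to_numpy(dtype=int)

    def check_companion(self, ft: FeatureTable) -> None:
        missing = set(self.sample_ids) - set(ft.sample_ids)
        if missing:
            raise ValidationError(
                f"clinical samples absent from feature table: {sorted(missing)[:5]}"
            )


@dataclasses.dataclass
class ContingencyTable:
    """r x c table of non-negative integer counts with labelled margins."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValidationError(
                f"contingency table must be at least 2x2, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative counts")
        if self.counts.sum() == 0:
            raise ValidationError("empty contingency table")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


def _default_meta(feature_ids: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "analyte_class": "protein",
            "units": "fmol_per_uL",
            "ion_mode": "na",
        },
        index=pd.Index(feature_ids),
    )


def read_feature_table(
    path: str | Path,
    dialect: str = "csv",
    meta_path: str | Path | None = None,
    max_missing_frac: float = 0.2,
    impute: bool = True,
) -> FeatureTable:
    """Read an abundance CSV/TSV (first column sample id, header feature ids).

    Empty cells and "NA" are flagged missing.  Features missing in more than
    ``max_missing_frac`` of samples are dropped; remaining missing cells are
    imputed as half the feature minimum when ``impute`` is set.  A sidecar
    metadata CSV (feature_id, analyte_class, units, ion_mode) is optional.
    """
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for col in header:  # pandas silently mangles duplicate headers
        if col in seen:
            raise FormatError(f"duplicate feature ids: {col!r}")
        seen.add(col)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=["", "NA"], float_precision="round_trip"
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dupes[:5]}")
    values = df.to_numpy(dtype=float)
    neg = np.argwhere(values < 0)
    if neg.size:
        cells = ", ".join(f"(row {df.index[i]}, column {df.columns[j]})" for i, j in neg[:10])
        raise ValidationError(f"negative abundance at {cells}")

    keep = np.isnan(values).mean(axis=0) <= max_missing_frac
    df = df.loc[:, df.columns[keep]]
    values = values[:, keep]
    if impute:
        values = impute_missing(values)

    if meta_path is not None:
        meta = pd.read_csv(meta_path, index_col=0)
        meta.index = meta.index.astype(str)
        meta = meta.reindex(df.columns)
        for col, default in (
            ("analyte_class", "protein"),
            ("units", "fmol_per_uL"),
            ("ion_mode", "na"),
        ):
            if col not in meta.columns:
                meta[col] = default
            meta[col] = meta[col].fillna(default)
    else:
        meta = _default_meta(df.columns)
    return FeatureTable(
        sample_ids=list(df.index),
        feature_ids=list(df.columns),
        values=values,
        feature_meta=meta[["analyte_class", "units", "ion_mode"]],
    )


def impute_missing(values: np.ndarray) -> np.ndarray:
    """Replace NaN with half the per-feature observed minimum (in place copy)."""
    values = values.copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        mask = np.isnan(col)
        if mask.any():
            observed = col[~mask]
            fill = 0.0 if observed.size == 0 else float(np.min(observed)) / 2.0
            col[mask] = fill
    return values


def write_feature_table(
    ft: FeatureTable,
    path: str | Path,
    dialect: str = "csv",
    meta_path: str | Path | None = None,
) -> None:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = ft.to_frame()
    df.index.name = "sample_id"
    # shortest-repr formatting round-trips float64 bit-for-bit
    df.to_csv(path, sep=sep, float_format=lambda v: repr(float(v)))
    if meta_path is not None:
        meta = ft.feature_meta.copy()
        meta.index.name = "feature_id"
        meta.to_csv(meta_path)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, index_col=0, na_values=["", "NA"])
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical_table(ct: ClinicalTable, path: str | Path) -> None:
    df = ct.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path)


def crosstab(clinical: ClinicalTable, var: str, by: str = "group") -> ContingencyTable:
    """Cross-tabulate two categorical clinical columns (levels x groups)."""
    df = clinical.data
    for col in (var, by):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not in clinical table")
        if col not in CATEGORICAL_COLUMNS and not _looks_categorical(df[col]):
            raise TypeError(f"column {col!r} is not categorical")
    tab = pd.crosstab(df[var], df[by])
    if by == "group":  # fixed display order: non-metastatic first
        order = [g for g in GROUP_LEVELS if g in tab.columns]
        tab = tab[order]
    return ContingencyTable(
        counts=tab.to_numpy(),
        row_labels=[str(x) for x in tab.index],
        col_labels=[str(x) for x in tab.columns],
    )


def _looks_categorical(s: pd.Series) -> bool:
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        return True
    vals = s.dropna().unique()
    return len(vals) <= 10 and np.all(np.asarray(vals, dtype=float) % 1 == 0)
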