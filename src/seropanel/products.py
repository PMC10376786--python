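"""Second-order product-feature expansion.

Panels are fitted on a design space containing every base analyte together
with all pairwise products (including squares): a pair of analytes that
separates the classes only jointly becomes linearly separable through its
product term.  Products are formed on the raw measurement scale; the
magnitude of downstream logistic coefficients reflects this.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .io_tables import FeatureTable

__all__ = ["ExpandedFeatureTable", "expand_products", "product_name"]

SEPARATOR = " × "  # "A × B"


def product_name(a: str, b: str) -> str:
    return f"{a}{SEPARATOR}{b}"


@dataclasses.dataclass
class ExpandedFeatureTable:
    """Base columns followed by all i <= j product columns.

    ``product_index`` lists the (i, j) base-column pairs, in the canonical
    order (0,0), (0,1), ..., (0,p-1), (1,1), ...; product names are
    "A × B" with A before B in base-table order.
    """

    base: FeatureTable
    product_index: list[tuple[int, int]]
    values: np.ndarray
    column_names: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def sample_ids(self) -> list[str]:
        return self.base.sample_ids

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def subset_samples(self, mask: np.ndarray) -> "ExpandedFeatureTable":
        """Row-subset view (new object) keeping the column structure."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        base = FeatureTable(
            sample_ids=[self.base.sample_ids[i] for i in idx],
            feature_ids=list(self.base.feature_ids),
            values=self.base.values[idx],
            feature_meta=self.base.feature_meta,
        )
        return ExpandedFeatureTable(
            base=base,
            product_index=list(self.product_index),
            values=self.values[idx],
            column_names=list(self.column_names),
        )

    def design_matrix(self, term_names: Sequence[str]) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.column_names)}
        missing = [t for t in term_names if t not in idx]
        if missing:
            raise KeyError(f"unknown terms: {missing[:5]}")
        return self.values[:, [idx[t] for t in term_names]]


def expand_products(
    ft: FeatureTable,
    include_squares: bool = True,
    whitelist: Sequence[str] | None = None,
) -> ExpandedFeatureTable:
    """Append all pairwise (and optionally square) products of base features.

    ``whitelist`` restricts the expansion to a feature subset, so protein and
    lipid blocks can be expanded separately.  Missing values must already be
    imputed.
    """
    if whitelist is not None:
        ft = ft.subset_features(list(whitelist))
    X = ft.values
    if np.isnan(X).any():
        raise ValueError(
            "feature table contains missing values; impute before expanding"
        )
    p = X.shape[1]
    names = list(ft.feature_ids)
    pairs: list[tuple[int, int]] = []
    for i in range(p):
        j0 = i if include_squares else i + 1
        for j in range(j0, p):
            pairs.append((i, j))
    if pairs:
        ii = np.fromiter((i for i, _ in pairs), dtype=int)
        jj = np.fromiter((j for _, j in pairs), dtype=int)
        prod = X[:, ii] * X[:, jj]
        values = np.hstack([X, prod])
    else:
        values = X.copy()
    col_names = names + [product_name(names[i], names[j]) for i, j in pairs]
    return ExpandedFeatureTable(
        base=ft, product_index=pairs, values=values, column_names=col_names
    )
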