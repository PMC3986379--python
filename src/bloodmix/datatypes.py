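"""Core containers for the mixing model.

The linear mixing model writes observed whole-blood expression as
``X = W @ H + E``: ``W`` holds per-sample cell-type proportions on the
probability simplex, ``H`` holds cell-type-specific expression, and ``E``
is zero-mean noise.  Every container below is a thin, validated wrapper
around a pandas DataFrame/Series so that feature, sample and cell-type
labels travel with the numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical leukocyte sub-populations of the seven-type whole-blood panel.
CELL_TYPES: tuple[str, ...] = (
    "neutrophils",
    "eosinophils",
    "monocytes",
    "CD4 T cells",
    "CD8 T cells",
    "NK cells",
    "B cells",
)

#: Lymphoid sub-populations whose proportions sum to the lymphocyte fraction
#: reported by a clinical total leukocyte differential.
LYMPHOCYTE_SUBTYPES: tuple[str, ...] = (
    "B cells",
    "CD4 T cells",
    "CD8 T cells",
    "NK cells",
)

#: Compartments measured by a total leukocyte differential.
COMPARTMENTS: tuple[str, ...] = ("neutrophil", "lymphocyte", "monocyte", "eosinophil")

#: Map from granular cell types to differential compartments.
COMPARTMENT_MAP: dict[str, str] = {
    "neutrophils": "neutrophil",
    "eosinophils": "eosinophil",
    "monocytes": "monocyte",
    "B cells": "lymphocyte",
    "CD4 T cells": "lymphocyte",
    "CD8 T cells": "lymphocyte",
    "NK cells": "lymphocyte",
}

VALID_SCALES = ("linear", "log2")


class DimensionError(ValueError):
    """Mismatched labels or shapes between model matrices."""


class ScaleError(ValueError):
    """An operation received data on the wrong measurement scale."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with scale provenance.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
    scale
        ``"linear"`` (non-negative intensities) or ``"log2"``.
    normalized
        Whether quantile normalization has been applied.
    """

    values: pd.DataFrame
    scale: str = "linear"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ScaleError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and arr.size and arr.min() < 0:
            raise ValueError("linear-scale expression values must be >= 0")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class CompositionMatrix:
    """Samples x cell types proportions on the simplex.

    Rows of failed solves may be all-NaN (flagged by the deconvolution
    status vector); valid rows must be non-negative within 1e-8 and sum
    to one within 1e-6.
    """

    weights: pd.DataFrame

    NEG_TOL = 1e-8
    SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        _check_unique(self.weights.index, "sample ids")
        _check_unique(self.weights.columns, "cell types")
        arr = self.weights.to_numpy(dtype=float)
        valid = ~np.isnan(arr).all(axis=1)
        if np.isnan(arr[valid]).any():
            raise ValueError("partially-NaN composition rows are not allowed")
        if valid.any():
            sub = arr[valid]
            if sub.min() < -self.NEG_TOL:
                raise ValueError("composition weights must be >= 0 (tolerance 1e-8)")
            sums = sub.sum(axis=1)
            if np.abs(sums - 1.0).max() > self.SUM_TOL:
                raise ValueError("composition rows must sum to 1 (tolerance 1e-6)")

    @property
    def sample_ids(self) -> pd.Index:
        return self.weights.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.weights.columns)


@dataclass
class BasisMatrix:
    """Marker features x cell types reference expression."""

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ScaleError(f"unknown scale {self.scale!r}")
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "cell types")
        if self.values.shape[1] < 2:
            raise ValueError("a basis matrix needs at least two cell types")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("basis values must be finite")
        zero_cols = self.values.columns[(arr == 0).all(axis=0)].tolist()
        if zero_cols:
            raise ValueError(f"all-zero basis columns: {zero_cols}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[1]


@dataclass
class Differential:
    """Clinical total leukocyte differential fractions per sample.

    Columns are the four :data:`COMPARTMENTS`; each fraction lies in
    [0, 1] and rows sum to at most 1 (the differential need not be
    exhaustive, e.g. basophils are unreported).
    """

    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.fractions.index, "sample ids")
        missing = [c for c in COMPARTMENTS if c not in self.fractions.columns]
        if missing:
            raise ValueError(f"differential missing compartments: {missing}")
        self.fractions = self.fractions.loc[:, list(COMPARTMENTS)].astype(float)
        arr = self.fractions.to_numpy()
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError("differential fractions must lie in [0, 1]")
        if arr.sum(axis=1).max() > 1 + 1e-6:
            raise ValueError("differential fractions must sum to <= 1 per sample")

    @property
    def sample_ids(self) -> pd.Index:
        return self.fractions.index


@dataclass
class GroupDesign:
    """Two-group sample design (e.g. rejection vs non-rejection).

    ``case`` names the group treated as group 1 by contrasts; it defaults
    to the first label in order of appearance.
    """

    labels: pd.Series
    case: str | None = None

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        _check_unique(self.labels.index, "sample ids")
        uniq = list(dict.fromkeys(self.labels))
        if len(uniq) != 2:
            raise ValueError(f"design must have exactly two groups, got {uniq}")
        if self.case is None:
            self.case = uniq[0]
        elif self.case not in uniq:
            raise ValueError(f"case label {self.case!r} not among groups {uniq}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.labels.index

    @property
    def control(self) -> str:
        return next(g for g in dict.fromkeys(self.labels) if g != self.case)

    def group_samples(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]

    def swapped(self) -> "GroupDesign":
        """Same labels with case and control roles exchanged."""
        return GroupDesign(self.labels.copy(), case=self.control)
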