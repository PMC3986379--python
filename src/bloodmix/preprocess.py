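"""Normalization and scale transforms applied before deconvolution.

Reverse deconvolution is most accurate on quantile-normalized,
log2-scale data, while the cell-type-specific regression of the forward
stage runs on linear-scale intensities; both transforms live here and
record their effect on the matrix's provenance flags.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ScaleError

__all__ = ["quantile_normalize", "to_log2", "from_log2"]


def quantile_normalize(X: ExpressionMatrix, reference: np.ndarray | None = None) -> ExpressionMatrix:
    """Force every sample onto a common intensity distribution.

    The target distribution is the row-wise mean of the column-sorted
    matrix (RMA convention); pass ``reference`` (a sorted vector of
    length ``n_features``) to normalize against an external panel's
    distribution instead.  Within-column rank order is preserved; tied
    values within a column receive the mean of the target values for
    their tied ranks.
    """
    if X.n_samples < 2 and reference is None:
        warnings.warn("quantile_normalize: single sample, returned unchanged")
        return ExpressionMatrix(X.values.copy(), scale=X.scale, normalized=X.normalized)
    vals = X.values.to_numpy(dtype=float)
    order = np.argsort(vals, axis=0, kind="stable")
    if reference is None:
        target = np.take_along_axis(vals, order, axis=0).mean(axis=1)
    else:
        target = np.sort(np.asarray(reference, dtype=float))
        if target.size != X.n_features:
            raise ValueError("reference distribution length must equal feature count")
    out = np.empty_like(vals)
    rows = np.arange(vals.shape[0])
    for c in range(vals.shape[1]):
        col = np.empty_like(target)
        col[order[:, c]] = target
        # average the targets over groups of tied input values
        assigned = pd.Series(col, index=rows).groupby(vals[:, c]).transform("mean")
        out[:, c] = assigned.to_numpy()
    df = pd.DataFrame(out, index=X.feature_ids, columns=X.sample_ids)
    return ExpressionMatrix(df, scale=X.scale, normalized=True)


def to_log2(X: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise ``log2(x + pseudocount)``; requires linear input."""
    if X.scale != "linear":
        raise ScaleError("to_log2 requires linear-scale input")
    vals = X.values.to_numpy(dtype=float) + pseudocount
    if vals.min() <= 0:
        raise ValueError(
            "non-positive values after pseudocount; increase the pseudocount"
        )
    df = pd.DataFrame(np.log2(vals), index=X.feature_ids, columns=X.sample_ids)
    return ExpressionMatrix(df, scale="log2", normalized=X.normalized)


def from_log2(X: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Inverse of :func:`to_log2`: ``2**x - pseudocount``."""
    if X.scale != "log2":
        raise ScaleError("from_log2 requires log2-scale input")
    vals = np.exp2(X.values.to_numpy(dtype=float)) - pseudocount
    vals = np.where(np.abs(vals) < 1e-12, 0.0, vals)
    df = pd.DataFrame(vals, index=X.feature_ids, columns=X.sample_ids)
    return ExpressionMatrix(df, scale="linear", normalized=X.normalized)
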