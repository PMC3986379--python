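"""Forward mixing model and prediction-accuracy metrics."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    BasisMatrix,
    CompositionMatrix,
    DimensionError,
    ExpressionMatrix,
    ScaleError,
)

__all__ = ["mix", "rmse", "adjusted_r2"]


def mix(
    W: CompositionMatrix,
    H: BasisMatrix,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Synthesize mixed expression ``X[j, i] = sum_k w_ik * h_kj + e_ij``.

    ``e_ij`` is Gaussian with standard deviation ``noise_sd``; values are
    truncated at zero so the output is a valid linear-scale matrix.  The
    basis must be on the linear scale and its cell types must match the
    composition's cell types in order.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if H.scale != "linear":
        raise ScaleError("mix requires a linear-scale basis")
    if list(W.cell_types) != list(H.cell_types):
        raise DimensionError(
            f"cell types differ between composition {W.cell_types} "
            f"and basis {H.cell_types}"
        )
    values = H.values.to_numpy() @ W.weights.to_numpy().T  # features x samples
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    df = pd.DataFrame(values, index=H.feature_ids, columns=W.sample_ids)
    return ExpressionMatrix(df, scale="linear", normalized=False)


def _as_prop_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size < 1:
        raise ValueError(f"{name} must be non-empty")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} must be finite")
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def rmse(predicted, measured) -> float:
    """Root mean squared error between two proportion vectors."""
    p = _as_prop_vector(predicted, "predicted")
    m = _as_prop_vector(measured, "measured")
    if p.size != m.size:
        raise ValueError(f"length mismatch: {p.size} vs {m.size}")
    return float(np.sqrt(np.mean((p - m) ** 2)))


def adjusted_r2(predicted, measured) -> float:
    """Adjusted R^2 of an OLS fit of ``measured`` on ``predicted``.

    The plain coefficient of determination from the simple regression
    (with intercept) is adjusted for the single predictor:
    ``1 - (1 - R^2) * (n - 1) / (n - 2)``.  Can be negative when the
    predictor carries no information.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    m = np.asarray(measured, dtype=float).ravel()
    if p.size != m.size:
        raise ValueError(f"length mismatch: {p.size} vs {m.size}")
    n = p.size
    if n < 4:
        raise ValueError("adjusted_r2 needs at least 4 points")
    if np.ptp(p) == 0:
        raise ValueError("predicted vector has zero variance")
    r = stats.linregress(p, m)
    r2 = r.rvalue**2
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - 2))
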