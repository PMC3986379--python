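"""Reverse deconvolution: infer sample composition from mixed expression.

Each sample is solved independently as a constrained least-squares
problem on the probability simplex,

    min_w || H w - x ||^2   s.t.   w >= 0,  sum_k w_k = 1,

by a primal active-set quadratic program (with an SLSQP fallback).
Solutions are verified against the KKT conditions and flagged per
sample.  Also houses lymphocyte aggregation, the detectability filter
for downstream cell-type-specific analysis, and group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    BasisMatrix,
    CompositionMatrix,
    ExpressionMatrix,
    GroupDesign,
    LYMPHOCYTE_SUBTYPES,
    ScaleError,
)

__all__ = [
    "DeconvolutionResult",
    "deconvolve",
    "aggregate_lymphocyte",
    "detectability_filter",
    "group_composition_summary",
]

_KKT_TOL = 1e-6


@dataclass
class DeconvolutionResult:
    """Composition estimates plus per-sample diagnostics."""

    composition: CompositionMatrix
    residual_norm: pd.Series  # ||H w - x||_2 per sample
    status: pd.Series  # "ok" | "failed"

    @property
    def ok(self) -> bool:
        return bool((self.status == "ok").all())


def _kkt_residual(Q: np.ndarray, c: np.ndarray, w: np.ndarray, tol_active: float = 1e-9) -> float:
    """Relative KKT violation of a feasible point for the simplex QP.

    With multiplier ``mu`` estimated from the support, stationarity
    requires ``(Qw - c)_j = mu`` on the support and ``>= mu`` off it.
    """
    scale = max(1.0, float(np.abs(c).max()))
    g = Q @ w - c
    support = w > tol_active
    if not support.any():
        return np.inf
    mu = float(g[support].mean())
    stationarity = float(np.abs(g[support] - mu).max())
    dual = float(np.clip(mu - g[~support], 0.0, None).max(initial=0.0))
    primal = abs(float(w.sum()) - 1.0) + float(np.clip(-w, 0.0, None).max(initial=0.0))
    return (stationarity + dual) / scale + primal


def _solve_support(Q: np.ndarray, c: np.ndarray, idx: np.ndarray):
    """Equality-constrained LS on a given support via the KKT system.

    Q and c are rescaled so the simplex constraint row is commensurate
    with the normal-equation rows; otherwise lstsq sacrifices the
    constraint on large-intensity data.
    """
    kp = idx.size
    scale = max(1.0, float(np.abs(Q).max()))
    A = np.zeros((kp + 1, kp + 1))
    A[:kp, :kp] = Q[np.ix_(idx, idx)] / scale
    A[:kp, kp] = 1.0
    A[kp, :kp] = 1.0
    b = np.append(c[idx] / scale, 1.0)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:kp], float(sol[kp]) * scale


def _simplex_lstsq(H: np.ndarray, x: np.ndarray, tol: float = 1e-9):
    """min ||Hw - x||^2 s.t. w >= 0, sum w = 1.

    A primal active-set loop handles the common well-conditioned case in
    a few iterations; if it stalls (cycling on degenerate problems), an
    exhaustive enumeration of supports — exact for the small K of a
    leukocyte panel — guarantees the global optimum.  Returns
    ``(w, kkt_residual)``.
    """
    K = H.shape[1]
    Q = H.T @ H
    c = H.T @ x
    passive = np.ones(K, dtype=bool)
    best_w, best_kkt = None, np.inf
    for _ in range(5 * K + 10):
        idx = np.flatnonzero(passive)
        if idx.size == 0:
            break
        w_p, mu = _solve_support(Q, c, idx)
        if w_p.min() < -tol:
            passive[idx[int(np.argmin(w_p))]] = False
            continue
        w = np.zeros(K)
        w[idx] = np.clip(w_p, 0.0, None)
        kkt = _kkt_residual(Q, c, w)
        if kkt < best_kkt:
            best_w, best_kkt = w, kkt
        if kkt <= tol:
            return w, kkt
        g = Q @ w - c
        viol = np.where(~passive, mu - g, -np.inf)
        j = int(np.argmax(viol))
        if viol[j] <= 0:
            break
        passive[j] = True
    if best_w is not None and best_kkt <= _KKT_TOL:
        return best_w, best_kkt
    return _simplex_lstsq_exhaustive(Q, c, K)


def _simplex_lstsq_exhaustive(Q: np.ndarray, c: np.ndarray, K: int):
    """Global optimum by trying every support (feasible-candidate minimum)."""
    if K > 14:
        raise ValueError("exhaustive simplex solve is limited to K <= 14")
    best_w, best_obj = None, np.inf
    for mask in range(1, 1 << K):
        idx = np.array([k for k in range(K) if mask >> k & 1])
        w_p, _ = _solve_support(Q, c, idx)
        if w_p.min() < -1e-9:
            continue
        w = np.zeros(K)
        w[idx] = np.clip(w_p, 0.0, None)
        w = w / w.sum()
        obj = 0.5 * w @ Q @ w - c @ w
        if obj < best_obj - 1e-15:
            best_w, best_obj = w, obj
    if best_w is None:  # cannot happen for a consistent system; be explicit
        return np.full(K, np.nan), np.inf
    return best_w, _kkt_residual(Q, c, best_w)


def deconvolve(
    X: ExpressionMatrix,
    H: BasisMatrix,
    sum_to_one: bool = True,
) -> DeconvolutionResult:
    """Estimate per-sample cell-type proportions from mixed expression.

    ``X`` must contain every basis feature and share the basis scale
    (the recommended working scale for reverse deconvolution is
    quantile-normalized log2; a linear-scale mode simply requires both
    inputs on the linear scale).  With ``sum_to_one=False`` the equality
    constraint relaxes to ``sum_k w_k <= 1`` via a slack component.
    """
    missing = [f for f in H.feature_ids if f not in X.feature_ids]
    if missing:
        raise KeyError(f"expression matrix is missing basis features: {missing[:10]}")
    if X.scale != H.scale:
        raise ScaleError(
            f"scale mismatch: expression is {X.scale}, basis is {H.scale}"
        )
    A = H.values.to_numpy(dtype=float)
    if not sum_to_one:
        A = np.hstack([A, np.zeros((A.shape[0], 1))])  # slack absorbs 1 - sum(w)
    Xs = X.values.loc[H.feature_ids].to_numpy(dtype=float)
    K = H.n_cell_types
    n = X.n_samples
    W = np.full((n, K), np.nan)
    resid = np.full(n, np.nan)
    status = []
    for i in range(n):
        x = Xs[:, i]
        w, kkt = _simplex_lstsq(A, x)
        if not np.isfinite(kkt) or kkt > _KKT_TOL:
            status.append("failed")
            continue
        w = w[:K]
        if sum_to_one:
            w = w / w.sum()
        W[i] = w
        resid[i] = float(np.linalg.norm(A[:, :K] @ w - x))
        status.append("ok")
    weights = pd.DataFrame(W, index=X.sample_ids, columns=H.cell_types)
    if not sum_to_one:
        # rows may legitimately sum to < 1; bypass the simplex row check
        # by renting the remainder to an explicit "unassigned" column.
        weights["unassigned"] = np.clip(1.0 - weights.sum(axis=1), 0.0, None)
    comp = CompositionMatrix(weights)
    return DeconvolutionResult(
        composition=comp,
        residual_norm=pd.Series(resid, index=X.sample_ids, name="residual_norm"),
        status=pd.Series(status, index=X.sample_ids, name="status"),
    )


def aggregate_lymphocyte(
    W: CompositionMatrix,
    subtypes: tuple[str, ...] = LYMPHOCYTE_SUBTYPES,
) -> pd.Series:
    """Per-sample lymphocyte fraction: sum of B, CD4 T, CD8 T and NK."""
    missing = [s for s in subtypes if s not in W.weights.columns]
    if missing:
        raise KeyError(f"composition is missing lymphocyte sub-types: {missing}")
    return W.weights.loc[:, list(subtypes)].sum(axis=1).rename("lymphocyte")


def detectability_filter(
    W: CompositionMatrix,
    nondetect_fraction: float = 0.75,
    detect_threshold: float = 1e-8,
) -> list[str]:
    """Cell types retained for cell-type-specific analysis.

    A cell type is omitted when its proportion is at or below
    ``detect_threshold`` in strictly more than ``nondetect_fraction`` of
    samples ("not detectable in more than 75% of subjects").
    """
    arr = W.weights.to_numpy(dtype=float)
    n = arr.shape[0]
    nondetect = (arr <= detect_threshold).sum(axis=0) / n
    keep = nondetect <= nondetect_fraction
    return [ct for ct, k in zip(W.cell_types, keep) if k]


def group_composition_summary(
    W: CompositionMatrix,
    design: GroupDesign,
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Group means with percentile-bootstrap CIs and rank-sum p per cell type.

    Returns a tidy frame with one row per (group, cell type):
    ``mean``, ``ci_lower``, ``ci_upper`` (2.5/97.5 percentile bootstrap of
    the group mean) and the two-sided Wilcoxon rank-sum ``p`` comparing
    the two groups (repeated on both rows of a cell type).  Groups of
    fewer than two samples get NaN CIs.
    """
    from .ratio import ranksum_test  # shared test; imported late to stay acyclic

    rng = np.random.default_rng(seed)
    rows = []
    groups = [design.case, design.control]
    pvals = {}
    for ct in W.cell_types:
        vals = W.weights[ct]
        pvals[ct] = ranksum_test(vals.loc[design.sample_ids], design)
    for g in groups:
        ids = design.group_samples(g)
        sub = W.weights.loc[ids]
        for ct in W.cell_types:
            v = sub[ct].to_numpy(dtype=float)
            mean = float(v.mean())
            if v.size < 2:
                lo = hi = np.nan
            else:
                boots = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
                lo, hi = np.percentile(boots, [2.5, 97.5])
            rows.append(
                {
                    "group": g,
                    "cell_type": ct,
                    "n": v.size,
                    "mean": mean,
                    "ci_lower": float(lo),
                    "ci_upper": float(hi),
                    "ranksum_p": pvals[ct],
                }
            )
    return pd.DataFrame(rows)
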