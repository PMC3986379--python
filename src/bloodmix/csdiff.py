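"""Cell-type-specific differential expression (forward deconvolution).

Within each group, expression of every gene is regressed on the sample
composition matrix (no intercept); the coefficients estimate the average
cell-type-specific expression for that group and the group contrast is
tested gene-by-gene with a label-permutation false discovery rate,
separately for the one-tailed up and down hypotheses, as in csSAM.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CompositionMatrix, ExpressionMatrix, GroupDesign, ScaleError

__all__ = [
    "CsFit",
    "FdrCurve",
    "FdrResult",
    "cs_fit",
    "cs_contrast",
    "permutation_fdr",
    "ranking_statistic",
    "export_rnk",
]

DIRECTIONS = ("up", "down")


@dataclass
class CsFit:
    """Group-wise estimated cell-type expression and standard errors.

    ``h_hat[g]`` and ``se[g]`` are cell types x genes frames for group
    label ``g``; ``case`` / ``control`` name the two groups.
    """

    h_hat: dict[str, pd.DataFrame]
    se: dict[str, pd.DataFrame]
    case: str
    control: str

    @property
    def cell_types(self) -> list[str]:
        return list(self.h_hat[self.case].index)

    @property
    def gene_ids(self) -> pd.Index:
        return self.h_hat[self.case].columns


@dataclass
class FdrCurve:
    """FDR as a function of contrast cutoff for one cell type/direction."""

    direction: str
    cell_type: str
    cutoffs: np.ndarray
    observed: np.ndarray
    permuted_mean: np.ndarray
    fdr: np.ndarray
    zero_observed: np.ndarray  # cutoffs where FDR=0 is a convention, not evidence

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "observed": self.observed,
                "permuted_mean": self.permuted_mean,
                "fdr": self.fdr,
                "zero_observed": self.zero_observed,
            }
        )


@dataclass
class FdrResult:
    """Permutation-FDR curves and the call lists at the target FDR."""

    curves: dict[tuple[str, str], FdrCurve]  # (direction, cell type)
    calls: dict[tuple[str, str], list]  # gene ids called at fdr_target
    contrast: pd.DataFrame  # cell types x genes observed contrast
    fdr_target: float
    n_perm: int
    exhaustive: bool

    def call_table(self) -> pd.DataFrame:
        rows = []
        for (direction, ct), genes in self.calls.items():
            for g in genes:
                rows.append(
                    {
                        "cell_type": ct,
                        "direction": direction,
                        "gene": g,
                        "contrast": float(self.contrast.loc[ct, g]),
                    }
                )
        return pd.DataFrame(rows, columns=["cell_type", "direction", "gene", "contrast"])


def _group_fit(Wg: np.ndarray, Xg: np.ndarray, cell_types) -> tuple[np.ndarray, np.ndarray]:
    """OLS of each gene on the composition, no intercept.

    Returns (coefficients, standard errors), both K x p.
    """
    n, K = Wg.shape
    G = Wg.T @ Wg
    if np.linalg.matrix_rank(G) < K:
        corr = np.corrcoef(Wg.T)
        pairs = [
            (cell_types[a], cell_types[b])
            for a in range(K)
            for b in range(a + 1, K)
            if abs(corr[a, b]) > 0.999
        ]
        raise np.linalg.LinAlgError(
            f"rank-deficient composition within a group; collinear cell types: {pairs or cell_types}"
        )
    Ginv = np.linalg.inv(G)
    beta = Ginv @ (Wg.T @ Xg)  # K x p
    resid = Xg - Wg @ beta
    dof = n - K
    if dof <= 0:
        raise ValueError("each group needs more samples than cell types")
    sigma2 = (resid**2).sum(axis=0) / dof  # per gene
    se = np.sqrt(np.outer(np.diag(Ginv), sigma2))
    return beta, se


def cs_fit(
    X: ExpressionMatrix,
    W: CompositionMatrix,
    design: GroupDesign,
) -> CsFit:
    """Fit the mixing model separately within each group.

    ``X`` must be on the linear scale (the regression models raw
    transcript abundance); ``W`` should already be restricted to the
    cell types retained by the detectability filter.
    """
    if X.scale != "linear":
        raise ScaleError("cs_fit runs on linear-scale expression")
    ids = design.sample_ids
    missing = [s for s in ids if s not in X.sample_ids or s not in W.sample_ids]
    if missing:
        raise KeyError(f"samples missing from expression/composition: {missing}")
    cell_types = W.cell_types
    h_hat, se = {}, {}
    for g in (design.case, design.control):
        gids = design.group_samples(g)
        Wg = W.weights.loc[gids].to_numpy(dtype=float)
        Xg = X.values.loc[:, gids].to_numpy(dtype=float).T  # samples x genes
        beta, serr = _group_fit(Wg, Xg, cell_types)
        h_hat[g] = pd.DataFrame(beta, index=cell_types, columns=X.feature_ids)
        se[g] = pd.DataFrame(serr, index=cell_types, columns=X.feature_ids)
    return CsFit(h_hat=h_hat, se=se, case=design.case, control=design.control)


def cs_contrast(fit: CsFit) -> pd.DataFrame:
    """Case-minus-control contrast of estimated cell-type expression."""
    return fit.h_hat[fit.case] - fit.h_hat[fit.control]


def _perm_label_sets(labels: np.ndarray, case: str, n_perm: int, seed, max_exhaustive=10_000):
    """Yield boolean case-membership vectors for the permutation null.

    Enumerates all distinct assignments when their number is at most
    ``max_exhaustive``; otherwise draws ``n_perm`` label shuffles.
    """
    n = labels.size
    n_case = int((labels == case).sum())
    n_distinct = math.comb(n, n_case)
    if n_distinct <= max_exhaustive:
        for pos in itertools.combinations(range(n), n_case):
            mask = np.zeros(n, dtype=bool)
            mask[list(pos)] = True
            yield mask
    else:
        rng = np.random.default_rng(seed)
        base = labels == case
        for _ in range(n_perm):
            yield base[rng.permutation(n)]


def _contrast_for_mask(Wm, Xm, case_mask, cell_types):
    b1, _ = _group_fit(Wm[case_mask], Xm[case_mask], cell_types)
    b2, _ = _group_fit(Wm[~case_mask], Xm[~case_mask], cell_types)
    return b1 - b2


def _tail_counts(values: np.ndarray, cutoffs: np.ndarray, direction: str) -> np.ndarray:
    """#{j : d_j >= c} (up) or #{j : d_j <= -c} (down) for each cutoff c."""
    v = np.sort(values if direction == "up" else -values)
    return v.size - np.searchsorted(v, cutoffs, side="left")


def permutation_fdr(
    X: ExpressionMatrix,
    W: CompositionMatrix,
    design: GroupDesign,
    n_perm: int = 200,
    n_cutoffs: int = 100,
    fdr_target: float = 0.30,
    seed: int | None = None,
    perm_stat: str = "mean",
) -> FdrResult:
    """Permutation FDR for the one-tailed up/down contrast hypotheses.

    Group labels are shuffled over samples while each sample keeps its
    own composition row; the contrast is refit for every permutation.
    For the up direction at cutoff ``c``, per cell type,

        FDR(c) = mean_perm #{j : D_perm[k, j] >= c} / #{j : D_obs[k, j] >= c},

    capped at 1 and monotonized (running minimum from the smallest
    cutoff outward, so FDR never increases with cutoff magnitude).
    Cutoffs where the observed count is zero are recorded as FDR 0 by
    convention and flagged.  Call lists per cell type and direction
    collect genes passing the most permissive cutoff with
    FDR <= ``fdr_target``.
    """
    fit = cs_fit(X, W, design)
    D_obs = cs_contrast(fit)
    cell_types = fit.cell_types
    ids = design.sample_ids
    Wm = W.weights.loc[ids].to_numpy(dtype=float)
    Xm = X.values.loc[:, ids].to_numpy(dtype=float).T
    labels = design.labels.loc[ids].to_numpy()

    cutgrid = {}
    q = np.linspace(0.0, 1.0, n_cutoffs)
    for k, ct in enumerate(cell_types):
        absd = np.abs(D_obs.loc[ct].to_numpy())
        cutgrid[ct] = np.unique(np.quantile(absd, q))

    obs_counts = {
        (d, ct): _tail_counts(D_obs.loc[ct].to_numpy(), cutgrid[ct], d)
        for d in DIRECTIONS
        for ct in cell_types
    }
    perm_counts: dict[tuple[str, str], list[np.ndarray]] = {
        key: [] for key in obs_counts
    }
    n_used = 0
    n_case = int((labels == design.case).sum())
    exhaustive = math.comb(labels.size, n_case) <= 10_000
    for mask in _perm_label_sets(labels, design.case, n_perm, seed):
        Dp = _contrast_for_mask(Wm, Xm, mask, cell_types)
        for k, ct in enumerate(cell_types):
            for d in DIRECTIONS:
                perm_counts[(d, ct)].append(_tail_counts(Dp[k], cutgrid[ct], d))
        n_used += 1

    agg = np.mean if perm_stat == "mean" else np.median
    curves: dict[tuple[str, str], FdrCurve] = {}
    calls: dict[tuple[str, str], list] = {}
    for ct in cell_types:
        d_row = D_obs.loc[ct]
        for d in DIRECTIONS:
            cuts = cutgrid[ct]
            obs = obs_counts[(d, ct)].astype(float)
            pm = agg(np.stack(perm_counts[(d, ct)]), axis=0).astype(float)
            zero_obs = obs == 0
            with np.errstate(divide="ignore", invalid="ignore"):
                fdr = np.where(zero_obs, 0.0, pm / np.where(zero_obs, 1.0, obs))
            fdr = np.minimum(fdr, 1.0)
            fdr = np.minimum.accumulate(fdr)  # cutoffs ascend: FDR non-increasing
            curves[(d, ct)] = FdrCurve(
                direction=d,
                cell_type=ct,
                cutoffs=cuts,
                observed=obs,
                permuted_mean=pm,
                fdr=fdr,
                zero_observed=zero_obs,
            )
            passing = np.flatnonzero((fdr <= fdr_target) & ~zero_obs)
            if passing.size:
                c_star = cuts[passing[0]]
                if d == "up":
                    genes = d_row.index[d_row.to_numpy() >= c_star]
                else:
                    genes = d_row.index[d_row.to_numpy() <= -c_star]
                calls[(d, ct)] = list(genes)
            else:
                calls[(d, ct)] = []
    return FdrResult(
        curves=curves,
        calls=calls,
        contrast=D_obs,
        fdr_target=fdr_target,
        n_perm=n_used,
        exhaustive=exhaustive,
    )


def ranking_statistic(fit: CsFit) -> dict[str, pd.Series]:
    """Signal-to-noise-style per-gene statistic, ranked per cell type.

    ``d_kj = (h1_kj - h2_kj) / sqrt(se1_kj^2 + se2_kj^2)``; genes are
    returned in descending order with deterministic gene-id tie-breaks.
    A zero denominator yields +/-inf for a nonzero difference and 0
    otherwise.
    """
    out = {}
    diff = cs_contrast(fit)
    denom = np.sqrt(fit.se[fit.case] ** 2 + fit.se[fit.control] ** 2)
    for ct in fit.cell_types:
        num = diff.loc[ct].to_numpy(dtype=float)
        den = denom.loc[ct].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = num / den
        d = np.where((den == 0) & (num == 0), 0.0, d)
        s = pd.Series(d, index=fit.gene_ids, name=ct)
        order = sorted(s.index, key=lambda g: (-s[g], str(g)))
        out[ct] = s.loc[order]
    return out


def export_rnk(ranked: pd.Series, path) -> None:
    """Write a two-column tab-separated ranked list (gene, statistic)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene, value in ranked.items():
            fh.write(f"{gene}\t{value:.6g}\n")
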