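"""Lymphocyte-specific up/down ratio signature and rank-sum testing.

The ratio score is built to survive convolution: the mean linear
expression of genes up-regulated in cases within designated cell types,
divided by the mean of genes down-regulated in cases, computed directly
on whole-blood expression.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .datatypes import ExpressionMatrix, GroupDesign

__all__ = ["RatioSignature", "build_ratio_signature", "ratio_score", "ranksum_test"]

log = logging.getLogger(__name__)


@dataclass
class RatioSignature:
    """Disjoint up/down feature sets, optionally mapped across platforms."""

    up_ids: tuple
    down_ids: tuple

    def __post_init__(self) -> None:
        overlap = set(self.up_ids) & set(self.down_ids)
        if overlap:
            raise ValueError(f"up/down signature overlap: {sorted(overlap)[:5]}")
        if not self.up_ids or not self.down_ids:
            raise ValueError("both up and down signature sets must be non-empty")


def _top_calls(calls: list, ranked: pd.Series, top_n: int) -> list:
    """Top-n called genes by |ranking statistic|, id-tie-broken."""
    scored = sorted(calls, key=lambda g: (-abs(ranked.get(g, 0.0)), str(g)))
    return scored[:top_n]


def build_ratio_signature(
    calls: dict[tuple[str, str], list],
    rank_lists: dict[str, pd.Series],
    up_cell_types: list[str],
    down_cell_types: list[str],
    top_n: int = 20,
    platform_map: dict | None = None,
) -> RatioSignature:
    """Assemble the ratio signature from cell-type-specific call lists.

    For every named cell type, take the ``top_n`` FDR-passing calls of
    the required direction ranked by absolute signal-to-noise statistic;
    union them over the up and down cell types respectively.  Ids absent
    from ``platform_map`` are dropped (counted in the log); genes landing
    in both unions are removed from both.
    """
    def collect(cell_types, direction):
        union: list = []
        for ct in cell_types:
            if ct not in rank_lists:
                raise KeyError(f"no ranked list for cell type {ct!r}")
            ct_calls = calls.get((direction, ct), [])
            for g in _top_calls(ct_calls, rank_lists[ct], top_n):
                if g not in union:
                    union.append(g)
        return union

    up = collect(up_cell_types, "up")
    down = collect(down_cell_types, "down")
    if platform_map is not None:
        for name, ids in (("up", up), ("down", down)):
            dropped = [g for g in ids if g not in platform_map]
            if dropped:
                log.info("ratio signature: %d %s ids not in platform map", len(dropped), name)
        up = [platform_map[g] for g in up if g in platform_map]
        down = [platform_map[g] for g in down if g in platform_map]
    both = set(up) & set(down)
    if both:
        log.info("ratio signature: removing %d ids present in both directions", len(both))
        up = [g for g in up if g not in both]
        down = [g for g in down if g not in both]
    if not up or not down:
        raise ValueError("ratio signature has an empty up or down set")
    return RatioSignature(up_ids=tuple(up), down_ids=tuple(down))


def ratio_score(X: ExpressionMatrix, sig: RatioSignature) -> pd.Series:
    """Per-sample mean(up genes) / mean(down genes) on linear expression."""
    missing = [g for g in (*sig.up_ids, *sig.down_ids) if g not in X.feature_ids]
    if missing:
        raise KeyError(f"expression matrix missing signature ids: {missing[:10]}")
    up = X.values.loc[list(sig.up_ids)].mean(axis=0)
    down = X.values.loc[list(sig.down_ids)].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = up / down
    score[down == 0] = np.nan
    return score.rename("ratio")


def ranksum_test(values: pd.Series, design: GroupDesign) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a two-group comparison.

    Exact by enumeration of all rank assignments when the total sample
    size is at most 20 and the data are tie-free; otherwise the normal
    approximation with midranks, tie correction and continuity
    correction.  Completely tied data give p = 1.
    """
    v = pd.Series(values).loc[design.sample_ids].to_numpy(dtype=float)
    g1 = (design.labels.loc[design.sample_ids] == design.case).to_numpy()
    n1, n2 = int(g1.sum()), int((~g1).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    ranks = rankdata(v, method="average")
    w_obs = ranks[g1].sum()
    has_ties = np.unique(v).size < n
    if n <= 20 and not has_ties:
        # exact: enumerate which ranks fall in group 1
        mean_w = n1 * (n + 1) / 2.0
        dev = abs(w_obs - mean_w)
        hits = 0
        total = math.comb(n, n1)
        for combo in itertools.combinations(range(1, n + 1), n1):
            if abs(sum(combo) - mean_w) >= dev - 1e-9:
                hits += 1
        return hits / total
    # normal approximation with tie correction
    _, counts = np.unique(v, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    mean_w = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mean_w)
    z = max(dev - 0.5, 0.0) / math.sqrt(var)  # continuity correction
    return float(min(1.0, 2.0 * stats.norm.sf(z)))
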