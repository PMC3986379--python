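"""Tissue-specific gene-set construction and overlap enrichment.

Tissue sets are thresholded from an enrichment-score matrix (features x
tissues) at a pooled percentile; candidate gene lists are tested against
them by the upper-tail hypergeometric test with Benjamini-Hochberg
correction applied across tissues within each candidate list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentMatrix",
    "GeneSetCollection",
    "build_tissue_sets",
    "hypergeometric_overlap",
    "bh_adjust",
    "median_enrichment_profile",
    "enrichment_table",
    "read_gmt",
    "write_gmt",
]


@dataclass
class EnrichmentMatrix:
    """Features x tissues enrichment scores."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates or self.scores.columns.has_duplicates:
            raise ValueError("enrichment matrix ids and tissue labels must be unique")
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("enrichment scores must be finite")

    @property
    def feature_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def tissues(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, list] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if members is None:
                raise ValueError(f"gene set {name!r} is null")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def build_tissue_sets(
    E: EnrichmentMatrix,
    percentile: float = 99.0,
    per_tissue: bool = False,
) -> GeneSetCollection:
    """One gene set per tissue: features scoring above a percentile threshold.

    The threshold is the given percentile of all matrix entries pooled
    across tissues (linear interpolation between order statistics);
    ``per_tissue=True`` thresholds each tissue column separately
    instead.  Membership uses strict inequality.
    """
    if E.scores.size == 0:
        raise ValueError("empty enrichment matrix")
    arr = E.scores.to_numpy(dtype=float)
    sets, desc = {}, {}
    if per_tissue:
        thresholds = {t: np.percentile(E.scores[t], percentile) for t in E.tissues}
    else:
        t_global = float(np.percentile(arr, percentile))
        thresholds = {t: t_global for t in E.tissues}
    for t in E.tissues:
        members = E.feature_ids[E.scores[t].to_numpy() > thresholds[t]]
        sets[t] = list(members)
        desc[t] = f"features with enrichment > {thresholds[t]:.6g} in {t}"
    return GeneSetCollection(sets=sets, descriptions=desc)


def hypergeometric_overlap(candidate, geneset, universe) -> float:
    """Upper-tail p of the candidate/gene-set overlap in a finite universe.

    ``P[Overlap >= observed]`` for a hypergeometric draw of
    ``|candidate|`` features from a universe of size ``N`` containing
    ``|geneset|`` successes.  Ids outside the universe are dropped with
    a warning.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    cand = set(candidate)
    gs = set(geneset)
    out_c, out_g = cand - uni, gs - uni
    if out_c or out_g:
        warnings.warn(
            f"dropping ids outside the universe: {len(out_c)} candidate, {len(out_g)} set"
        )
        cand &= uni
        gs &= uni
    N, m, n_draw = len(uni), len(gs), len(cand)
    k = len(cand & gs)
    return float(stats.hypergeom.sf(k - 1, N, m, n_draw))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def median_enrichment_profile(candidate, E: EnrichmentMatrix) -> pd.Series:
    """Per-tissue median enrichment score over a candidate gene list."""
    present = [g for g in candidate if g in set(E.feature_ids)]
    if not present:
        raise ValueError("candidate list has no features in the enrichment matrix")
    return E.scores.loc[present].median(axis=0)


def enrichment_table(
    candidates: dict[str, set],
    collection: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each candidate list against each set.

    BH adjustment is applied across sets within each candidate list.
    Returns columns: list, set, overlap, set_size, candidate_size,
    universe_size, p, p_adj.
    """
    uni = set(universe)
    rows = []
    for lname, cand in candidates.items():
        cand_u = set(cand) & uni
        ps = []
        for sname in collection.names():
            gs = set(collection[sname]) & uni
            p = hypergeometric_overlap(cand_u, gs, uni)
            ps.append(p)
            rows.append(
                {
                    "list": lname,
                    "set": sname,
                    "overlap": len(cand_u & gs),
                    "set_size": len(gs),
                    "candidate_size": len(cand_u),
                    "universe_size": len(uni),
                    "p": p,
                }
            )
        adj = bh_adjust(ps)
        for i in range(len(ps)):
            rows[len(rows) - len(ps) + i]["p_adj"] = float(adj[i])
    return pd.DataFrame(rows)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member ids...)."""
    sets: dict[str, list] = {}
    desc: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed GMT line {lineno}: needs name and description")
            name, description, *members = parts
            if name in sets:
                raise ValueError(f"{path}: duplicate gene set name {name!r} at line {lineno}")
            sets[name] = [m for m in members if m]
            desc[name] = description
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = "\t".join(str(m) for m in collection[name])
            fh.write(f"{name}\t{desc}" + (f"\t{members}" if members else "") + "\n")
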