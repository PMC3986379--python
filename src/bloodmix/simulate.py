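"""Synthetic whole-blood data generator with known ground truth.

Emulates the three data layers the deconvolution pipeline consumes:
isolated cell-type reference panels with planted marker genes,
whole-blood-like mixtures with Dirichlet-distributed composition
(optionally shifted between two clinical groups), multiplicative
lognormal measurement noise and cell-type-specific fold-change spikes,
and noisy aggregate leukocyte differentials.  Every draw is
reproducible from its seed and the generating truth is returned
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CELL_TYPES,
    COMPARTMENT_MAP,
    COMPARTMENTS,
    CompositionMatrix,
    Differential,
    ExpressionMatrix,
    GroupDesign,
)

__all__ = [
    "SimulationTruth",
    "BLOOD_MEAN_PROPORTIONS",
    "blood_dirichlet_alpha",
    "simulate_panel",
    "simulate_mixtures",
    "simulate_differentials",
]

#: Typical leukocyte mean proportions in adult whole blood, in the
#: canonical seven-type order of :data:`bloodmix.datatypes.CELL_TYPES`.
BLOOD_MEAN_PROPORTIONS: dict[str, float] = {
    "neutrophils": 0.55,
    "eosinophils": 0.04,
    "monocytes": 0.12,
    "CD4 T cells": 0.12,
    "CD8 T cells": 0.07,
    "NK cells": 0.05,
    "B cells": 0.05,
}

#: Default Dirichlet concentration; 30 gives a between-subject spread of
#: roughly +/-8 percentage points for a 30% compartment.  Clinically
#: extreme cohorts (e.g. acute rejection) show wider spread — pass a
#: smaller concentration to emulate them.
DEFAULT_CONCENTRATION = 30.0


def blood_dirichlet_alpha(
    cell_types=CELL_TYPES, concentration: float = DEFAULT_CONCENTRATION
) -> np.ndarray:
    """Dirichlet parameters matching typical whole-blood composition."""
    props = np.array([BLOOD_MEAN_PROPORTIONS[ct] for ct in cell_types])
    return concentration * props / props.sum()


@dataclass
class SimulationTruth:
    """Everything needed to reconstruct a simulated dataset exactly."""

    profiles: pd.DataFrame | None = None  # cell types x genes, linear scale
    true_W: CompositionMatrix | None = None
    spiked: list = field(default_factory=list)  # (gene, cell type, direction, fold)
    group_alphas: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    marker_genes: dict = field(default_factory=dict)  # cell type -> gene ids
    seed: int | None = None


def simulate_panel(
    K: int = 7,
    p: int = 2000,
    markers_per_type: int = 20,
    replicates: int = 5,
    marker_log2fc: float = 4.0,
    baseline_mean: float = 6.0,
    baseline_sd: float = 1.5,
    replicate_sd: float = 0.25,
    seed: int | None = None,
):
    """Reference panel of isolated profiles with planted marker genes.

    Baseline log2 expression per gene is Gaussian(6, 1.5) shared across
    cell types; each cell type's markers sit ``marker_log2fc`` log2
    units above that baseline in their own type only, and each replicate
    array adds Gaussian log2 noise (sd 0.25).  Returns
    ``(ReferencePanel, SimulationTruth)``; the truth carries the
    linear-scale type profiles and the marker map.
    """
    from .basis import ReferencePanel  # local import avoids a cycle at import time

    if K * markers_per_type > p:
        raise ValueError("marker allocation exceeds the number of genes")
    if marker_log2fc < 0:
        raise ValueError("marker_log2fc must be >= 0")
    rng = np.random.default_rng(seed)
    cell_types = list(CELL_TYPES) if K == 7 else [f"cell_{k+1}" for k in range(K)]
    genes = [f"g{j+1:05d}" for j in range(p)]
    baseline = rng.normal(baseline_mean, baseline_sd, size=p)
    log2_profiles = np.tile(baseline, (K, 1))
    marker_genes: dict[str, list] = {}
    for k, ct in enumerate(cell_types):
        idx = slice(k * markers_per_type, (k + 1) * markers_per_type)
        log2_profiles[k, idx] += marker_log2fc
        marker_genes[ct] = genes[idx]
    cols, labels = {}, []
    for k, ct in enumerate(cell_types):
        for r in range(replicates):
            noise = (
                rng.normal(0.0, replicate_sd, size=p) if replicate_sd > 0 else np.zeros(p)
            )
            cols[f"{ct}|rep{r+1}"] = log2_profiles[k] + noise
            labels.append(ct)
    panel = ReferencePanel(pd.DataFrame(cols, index=genes), labels=labels, scale="log2")
    truth = SimulationTruth(
        profiles=pd.DataFrame(np.exp2(log2_profiles), index=cell_types, columns=genes),
        marker_genes=marker_genes,
        noise={"replicate_sd": replicate_sd},
        seed=seed,
    )
    return panel, truth


def simulate_mixtures(
    profiles: pd.DataFrame,
    n_per_group: int = 24,
    dirichlet_alpha: dict | None = None,
    de_spec: list | None = None,
    noise_cv: float = 0.2,
    noise_model: str = "lognormal",
    labels: tuple[str, str] = ("NR", "AR"),
    seed: int | None = None,
):
    """Two-group whole-blood-like mixtures with known composition.

    Per sample, composition is drawn from the group's Dirichlet;
    ``de_spec`` entries ``(cell_type, n_genes, fold, direction)`` modify
    the case group's cell-type profiles multiplicatively (on the linear
    scale) before mixing, so compositional and expression signal vary
    independently.  Measurement noise is multiplicative lognormal with
    coefficient of variation ``noise_cv`` (heteroscedastic, like raw
    intensity data); ``noise_model="additive"`` instead adds Gaussian
    noise with standard deviation ``noise_cv`` times the grand mean
    expression, truncated at zero (homoscedastic, like
    variance-stabilized data).  The second label is the case group (the
    one carrying the spikes) and becomes the design's case.

    Returns ``(ExpressionMatrix, GroupDesign, SimulationTruth)``.
    """
    if noise_model not in ("lognormal", "additive"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    cell_types = list(profiles.index)
    genes = list(profiles.columns)
    K = len(cell_types)
    rng = np.random.default_rng(seed)
    if dirichlet_alpha is None:
        if set(cell_types) == set(CELL_TYPES):
            alpha = blood_dirichlet_alpha(cell_types)
        else:
            alpha = np.full(K, DEFAULT_CONCENTRATION / K)
        dirichlet_alpha = {g: alpha for g in labels}
    control, case = labels
    S = {g: profiles.to_numpy(dtype=float).copy() for g in labels}
    spiked = []
    for spec in de_spec or []:
        ct, n_genes, fold, direction = spec
        if fold <= 0:
            raise ValueError("spike fold change must be > 0")
        if ct not in cell_types:
            raise KeyError(f"unknown cell type in DE spec: {ct!r}")
        k = cell_types.index(ct)
        pick = rng.choice(len(genes), size=n_genes, replace=False)
        mult = fold if direction == "up" else 1.0 / fold
        S[case][k, pick] *= mult
        spiked.extend((genes[j], ct, direction, fold) for j in pick)
    sample_ids, rows_W, cols_X, design_labels = [], [], {}, []
    for g in labels:
        a = np.asarray(dirichlet_alpha[g], dtype=float)
        if a.size != K:
            raise ValueError("dirichlet_alpha length must equal the number of cell types")
        for i in range(n_per_group):
            sid = f"{g}{i+1:03d}"
            w = rng.dirichlet(a)
            x = S[g].T @ w  # genes
            if noise_cv > 0:
                if noise_model == "lognormal":
                    sigma = np.sqrt(np.log1p(noise_cv**2))
                    x = x * rng.lognormal(-0.5 * sigma**2, sigma, size=x.size)
                else:
                    sd = noise_cv * float(x.mean())
                    x = np.clip(x + rng.normal(0.0, sd, size=x.size), 0.0, None)
            sample_ids.append(sid)
            rows_W.append(w)
            cols_X[sid] = x
            design_labels.append(g)
    X = ExpressionMatrix(
        pd.DataFrame(cols_X, index=genes), scale="linear", normalized=False
    )
    W = CompositionMatrix(
        pd.DataFrame(np.array(rows_W), index=sample_ids, columns=cell_types)
    )
    design = GroupDesign(pd.Series(design_labels, index=sample_ids), case=case)
    truth = SimulationTruth(
        profiles=profiles,
        true_W=W,
        spiked=spiked,
        group_alphas={g: np.asarray(dirichlet_alpha[g]).tolist() for g in labels},
        noise={"noise_cv": noise_cv},
        seed=seed,
    )
    return X, design, truth


def simulate_differentials(
    true_W: CompositionMatrix,
    error_cv: float = 0.08,
    seed: int | None = None,
) -> Differential:
    """Noisy clinical leukocyte differential from true composition.

    The seven granular cell types are aggregated into the four
    compartments of a total leukocyte differential, then perturbed by
    multiplicative lognormal error (default CV 8%, within the reported
    measurement error of clinical differentials for lymphocytes); rows
    that would exceed 1 are renormalized back onto the simplex.
    """
    missing = [ct for ct in true_W.cell_types if ct not in COMPARTMENT_MAP]
    if missing:
        raise KeyError(f"cell types without a differential compartment: {missing}")
    rng = np.random.default_rng(seed)
    agg = pd.DataFrame(0.0, index=true_W.sample_ids, columns=list(COMPARTMENTS))
    for ct in true_W.cell_types:
        agg[COMPARTMENT_MAP[ct]] += true_W.weights[ct]
    vals = agg.to_numpy()
    if error_cv > 0:
        sigma = np.sqrt(np.log1p(error_cv**2))
        vals = vals * rng.lognormal(-0.5 * sigma**2, sigma, size=vals.shape)
    sums = vals.sum(axis=1, keepdims=True)
    over = sums[:, 0] > 1.0
    vals[over] = vals[over] / sums[over]
    vals = np.clip(vals, 0.0, 1.0)
    return Differential(pd.DataFrame(vals, index=agg.index, columns=agg.columns))
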