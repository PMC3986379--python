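"""Basis (signature) matrix construction from isolated cell-type profiles.

A reference panel of isolated leukocyte profiles is reduced to a small
set of cell-type-discriminating marker features in two steps: a
fold-change prefilter keeps features in the top fraction of at least one
pairwise cell-type contrast, then a multinomial elastic-net fit over a
lambda path (lambda set by cross-validation with the 1-SE rule) selects
the final features at each value of the mixing parameter alpha.  Each
candidate basis is the per-cell-type mean of the selected features'
profiles; the winning candidate minimizes the lymphocyte RMSE of reverse
deconvolution on training mixtures, ties broken toward the largest
alpha (the smallest basis).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .datatypes import (
    BasisMatrix,
    COMPARTMENT_MAP,
    Differential,
    ExpressionMatrix,
    LYMPHOCYTE_SUBTYPES,
)
from .model import adjusted_r2, rmse

__all__ = [
    "ReferencePanel",
    "BasisBuildConfig",
    "BasisCandidate",
    "contrast_prefilter",
    "fit_selection_path",
    "build_basis",
    "build_candidates",
    "evaluate_candidate",
    "select_basis",
    "condition_number",
]


@dataclass
class ReferencePanel:
    """Isolated replicate profiles (features x arrays) with cell-type labels."""

    data: pd.DataFrame
    labels: list[str]
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature ids in reference panel")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("one cell-type label per array column is required")
        counts = pd.Series(self.labels).value_counts()
        if len(counts) < 2:
            raise ValueError("a reference panel needs at least two cell types")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def cell_types(self) -> list[str]:
        return list(dict.fromkeys(self.labels))

    def type_means(self) -> pd.DataFrame:
        """Features x cell types mean profile over replicates."""
        lab = np.asarray(self.labels)
        cols = {ct: self.data.loc[:, lab == ct].mean(axis=1) for ct in self.cell_types}
        return pd.DataFrame(cols)


@dataclass
class BasisBuildConfig:
    """Tuning knobs for candidate basis construction."""

    alpha_grid: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    cv_folds: int = 10
    top_fraction: float = 0.05
    exclude: frozenset = frozenset()
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alpha_grid:
            raise ValueError("alpha_grid must be non-empty")
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must lie in (0, 1]")


@dataclass
class BasisCandidate:
    """One point on the alpha path with its basis and evaluation metrics."""

    alpha: float
    selected_features: tuple
    basis: BasisMatrix
    cv_deviance: float
    lambda_: float = math.nan
    lymphocyte_rmse: float = math.nan
    metrics: dict = field(default_factory=dict)
    condition_number: float = math.nan


def contrast_prefilter(
    panel: ReferencePanel,
    top_fraction: float = 0.05,
    already_excluded: frozenset = frozenset(),
) -> list:
    """Features in the top fraction of at least one pairwise contrast.

    Per unordered pair of cell types, features are ranked by the
    absolute difference of cell-type mean log2 expression; the top
    ``ceil(top_fraction * p)`` of any contrast are eligible, minus the
    exclusion list.  Rank ties are broken by feature id so the result is
    deterministic.  The eligible features are returned in panel order.
    """
    if panel.scale != "log2":
        raise ValueError("contrast_prefilter expects a log2-scale panel")
    means = panel.type_means()
    types = panel.cell_types
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    p = panel.data.shape[0]
    m = math.ceil(top_fraction * p)
    ids = panel.feature_ids
    eligible: set = set()
    for a in range(len(types)):
        for b in range(a + 1, len(types)):
            contrast = (means[types[a]] - means[types[b]]).abs()
            order = sorted(range(p), key=lambda i: (-contrast.iloc[i], str(ids[i])))
            eligible.update(ids[i] for i in order[:m])
    eligible -= set(already_excluded)
    return [f for f in ids if f in eligible]


def _lambda_path(Xs, Y_onehot, alpha, n_lambda, min_ratio):
    """glmnet-style geometric lambda grid from the null-model gradient."""
    n = Xs.shape[0]
    resid = Y_onehot - Y_onehot.mean(axis=0)
    lmax = np.abs(Xs.T @ resid).max() / (n * max(alpha, 1e-2))
    lmax = max(lmax, 1e-6)
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def _fit_path(X, y, alpha, lambdas, max_iter=2000):
    """Fit the penalized multinomial model along a descending lambda path.

    Returns the list of coefficient matrices (classes x features).
    """
    n = X.shape[0]
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        C=1.0,
        max_iter=max_iter,
        tol=1e-4,
        warm_start=True,
    )
    coefs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for lam in lambdas:
            clf.C = 1.0 / (n * lam)
            clf.fit(X, y)
            coefs.append(clf.coef_.copy())
    return coefs


def _cv_deviance(X, y, alpha, lambdas, folds, seed):
    """Mean and SE of multinomial deviance across CV folds, per lambda."""
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, lambdas.size))
    for f, (tr, va) in enumerate(skf.split(X, y)):
        scaler = StandardScaler().fit(X[tr])
        Xtr, Xva = scaler.transform(X[tr]), scaler.transform(X[va])
        n_tr = tr.size
        clf = LogisticRegression(
            solver="saga",
            l1_ratio=alpha,
            C=1.0,
            max_iter=2000,
            tol=1e-4,
            warm_start=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for j, lam in enumerate(lambdas):
                clf.C = 1.0 / (n_tr * lam)
                clf.fit(Xtr, y[tr])
                proba = clf.predict_proba(Xva)
                col = {c: i for i, c in enumerate(clf.classes_)}
                ll = np.log(
                    np.clip(proba[np.arange(va.size), [col[c] for c in y[va]]], 1e-12, None)
                )
                dev[f, j] = -2.0 * ll.mean()
    return dev.mean(axis=0), dev.std(axis=0, ddof=1) / math.sqrt(folds)


def fit_selection_path(
    panel: ReferencePanel,
    config: BasisBuildConfig,
    eligible: list | None = None,
) -> list[tuple[float, list, float, float]]:
    """Elastic-net feature selection at every alpha in the grid.

    For each alpha, lambda is chosen by stratified cross-validated
    multinomial deviance with the 1-SE rule (largest lambda within one
    standard error of the minimum); the selected features are those with
    a nonzero coefficient for any class at that lambda in a full-data
    refit.  Returns ``(alpha, selected ids, cv_deviance, lambda)``
    tuples.  CV folds shrink to the smallest per-class replicate count
    when necessary.
    """
    if eligible is None:
        eligible = contrast_prefilter(panel, config.top_fraction, config.exclude)
    eligible = [f for f in eligible if f not in config.exclude]
    y = np.asarray(panel.labels)
    K = len(panel.cell_types)
    if len(eligible) < K:
        raise ValueError(f"only {len(eligible)} eligible features for {K} cell types")
    X = panel.data.loc[eligible].to_numpy(dtype=float).T  # arrays x features
    min_class = int(pd.Series(y).value_counts().min())
    folds = max(2, min(config.cv_folds, min_class))
    out = []
    for alpha in config.alpha_grid:
        scaler_full = StandardScaler().fit(X)
        Xs_full = scaler_full.transform(X)
        onehot = (y[:, None] == np.unique(y)[None, :]).astype(float)
        lambdas = _lambda_path(Xs_full, onehot, alpha, config.n_lambda, config.lambda_min_ratio)
        mean_dev, se_dev = _cv_deviance(X, y, alpha, lambdas, folds, config.seed)
        j_min = int(np.argmin(mean_dev))
        threshold = mean_dev[j_min] + se_dev[j_min]
        j_1se = int(np.flatnonzero(mean_dev <= threshold)[0])  # lambdas descend
        coefs = _fit_path(Xs_full, y, alpha, lambdas)
        selected: list = []
        j = j_1se
        while j < lambdas.size:
            nonzero = np.abs(coefs[j]).max(axis=0) > 1e-8
            selected = [eligible[i] for i in np.flatnonzero(nonzero)]
            if selected:
                break
            j += 1  # walk down the path until the model is non-empty
        out.append((float(alpha), selected, float(mean_dev[j]), float(lambdas[j])))
    return out


def build_basis(panel: ReferencePanel, features) -> BasisMatrix:
    """Basis matrix: per-cell-type replicate mean of the given features."""
    features = list(features)
    if not features:
        raise ValueError("empty feature set")
    missing = [f for f in features if f not in panel.feature_ids]
    if missing:
        raise KeyError(f"features not in panel: {missing[:10]}")
    means = panel.type_means().loc[features]
    means = means.sort_index()
    return BasisMatrix(means, scale=panel.scale)


def build_candidates(panel: ReferencePanel, config: BasisBuildConfig) -> list[BasisCandidate]:
    """Run the selection path and materialize a basis per alpha."""
    path = fit_selection_path(panel, config)
    candidates = []
    for alpha, selected, dev, lam in path:
        basis = build_basis(panel, selected)
        candidates.append(
            BasisCandidate(
                alpha=alpha,
                selected_features=tuple(selected),
                basis=basis,
                cv_deviance=dev,
                lambda_=lam,
                condition_number=condition_number(basis),
            )
        )
    return candidates


def evaluate_candidate(
    candidate: BasisCandidate,
    train_X: ExpressionMatrix,
    train_diff: Differential,
) -> BasisCandidate:
    """Score a candidate by reverse-deconvolution accuracy on training data.

    The training mixtures are deconvolved with the candidate basis, the
    lymphoid sub-populations are summed into a predicted lymphocyte
    fraction, and RMSE (plus adjusted R^2 where defined) against the
    measured leukocyte differential is recorded per compartment.  The
    returned candidate carries ``lymphocyte_rmse``, a ``metrics`` dict
    and the basis condition number.
    """
    from .compose import deconvolve  # local import to keep modules acyclic

    missing = [s for s in train_diff.sample_ids if s not in train_X.sample_ids]
    if missing:
        raise KeyError(f"differential samples missing from expression: {missing}")
    result = deconvolve(train_X, candidate.basis)
    W = result.composition.weights.loc[train_diff.sample_ids]
    pred = {}
    lymph_cols = [c for c in LYMPHOCYTE_SUBTYPES if c in W.columns]
    pred["lymphocyte"] = W[lymph_cols].sum(axis=1)
    for ct, comp in COMPARTMENT_MAP.items():
        if comp != "lymphocyte" and ct in W.columns:
            pred[comp] = W[ct]
    metrics = {}
    for comp, series in pred.items():
        measured = train_diff.fractions[comp]
        metrics[f"{comp}_rmse"] = rmse(series.to_numpy(), measured.to_numpy())
        try:
            metrics[f"{comp}_adj_r2"] = adjusted_r2(series.to_numpy(), measured.to_numpy())
        except ValueError:
            metrics[f"{comp}_adj_r2"] = math.nan
    return replace(
        candidate,
        lymphocyte_rmse=metrics["lymphocyte_rmse"],
        metrics=metrics,
        condition_number=condition_number(candidate.basis),
    )


def select_basis(candidates: list[BasisCandidate], tie_tol: float = 1e-9) -> BasisCandidate:
    """Minimal-lymphocyte-RMSE candidate; ties go to the largest alpha."""
    if not candidates:
        raise ValueError("no candidates to select from")
    if any(math.isnan(c.lymphocyte_rmse) for c in candidates):
        raise ValueError("all candidates must be evaluated before selection")
    best = min(c.lymphocyte_rmse for c in candidates)
    tied = [c for c in candidates if c.lymphocyte_rmse <= best + tie_tol]
    return max(tied, key=lambda c: c.alpha)


def condition_number(H: BasisMatrix) -> float:
    """Ratio of the largest to smallest singular value of the basis."""
    s = np.linalg.svd(H.values.to_numpy(dtype=float), compute_uv=False)
    smax, smin = float(s.max()), float(s.min())
    if smin <= smax * np.finfo(float).eps * max(H.values.shape):
        return math.inf
    return smax / smin
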