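"""Marker prefiltering, elastic-net selection path and basis selection."""

import math

import numpy as np
import pandas as pd
import pytest

import bloodmix as bm
from bloodmix.basis import BasisBuildConfig, BasisCandidate, ReferencePanel


def _panel_from_means(means: pd.DataFrame, replicates=1):
    """Panel whose replicate profiles equal the given per-type means."""
    cols, labels = {}, []
    for ct in means.columns:
        for r in range(replicates):
            cols[f"{ct}|r{r}"] = means[ct]
            labels.append(ct)
    return ReferencePanel(pd.DataFrame(cols, index=means.index), labels=labels)


class TestContrastPrefilter:
    def test_single_strong_feature_eligible(self):
        means = pd.DataFrame(
            {"a": np.zeros(40), "b": np.zeros(40)},
            index=[f"g{j:02d}" for j in range(40)],
        )
        means.loc["g07", "a"] = 10.0
        panel = _panel_from_means(means)
        assert "g07" in bm.contrast_prefilter(panel, top_fraction=0.05)

    def test_constructed_ranking_slice(self):
        # contrasts 1..100 between two types: top 5% = ranks 96..100
        ids = [f"g{j:03d}" for j in range(1, 101)]
        means = pd.DataFrame(
            {"a": np.arange(1, 101, dtype=float), "b": np.zeros(100)}, index=ids
        )
        panel = _panel_from_means(means)
        out = bm.contrast_prefilter(panel, top_fraction=0.05)
        assert sorted(out) == ["g096", "g097", "g098", "g099", "g100"]

    def test_degenerate_ties_resolved_by_id(self):
        means = pd.DataFrame(
            {"a": np.ones(10), "b": np.zeros(10)},
            index=[f"g{j}" for j in range(10)],
        )
        panel = _panel_from_means(means)
        out = bm.contrast_prefilter(panel, top_fraction=0.3)
        assert out == sorted(out) and len(out) == 3

    def test_monotone_in_top_fraction(self, blood_panel):
        panel, _ = blood_panel
        small = set(bm.contrast_prefilter(panel, top_fraction=0.02))
        large = set(bm.contrast_prefilter(panel, top_fraction=0.10))
        assert small <= large

    def test_exclusion_respected(self, blood_panel):
        panel, truth = blood_panel
        victim = truth.marker_genes[panel.cell_types[0]][0]
        out = bm.contrast_prefilter(panel, 0.1, already_excluded=frozenset({victim}))
        assert victim not in out


class TestSelectionPath:
    def test_lasso_recovers_planted_markers(self, small_panel):
        panel, truth = small_panel
        config = BasisBuildConfig(alpha_grid=(1.0,), cv_folds=4, top_fraction=0.25, seed=0)
        (alpha, selected, dev, lam), = bm.fit_selection_path(panel, config)
        markers = {g for gs in truth.marker_genes.values() for g in gs}
        assert alpha == 1.0 and selected
        recovered = len(markers & set(selected)) / len(markers)
        assert recovered >= 0.9
        # not too many noise features ride along
        assert len(set(selected) - markers) <= len(markers)

    def test_excluded_features_never_selected(self, small_panel):
        panel, truth = small_panel
        banned = frozenset(truth.marker_genes[panel.cell_types[0]][:2])
        config = BasisBuildConfig(
            alpha_grid=(0.5, 1.0), cv_folds=3, top_fraction=0.25, exclude=banned, seed=0
        )
        eligible = set(bm.contrast_prefilter(panel, 0.25, banned))
        for alpha, selected, dev, lam in bm.fit_selection_path(panel, config):
            assert selected, "selection must be non-empty"
            assert set(selected) <= eligible
            assert not (set(selected) & banned)


class TestBuildBasis:
    def test_replicate_mean_oracle(self, small_panel):
        panel, truth = small_panel
        feats = list(panel.feature_ids[:10])
        H = bm.build_basis(panel, feats)
        lab = np.asarray(panel.labels)
        for ct in panel.cell_types:
            expected = panel.data.loc[sorted(feats), lab == ct].mean(axis=1)
            np.testing.assert_allclose(H.values[ct], expected)

    def test_single_replicate_equals_profile(self):
        means = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [3.0, 4.0]}, index=["g1", "g2"]
        )
        panel = _panel_from_means(means)
        H = bm.build_basis(panel, ["g1", "g2"])
        pd.testing.assert_frame_equal(H.values, means)

    def test_empty_feature_set_errors(self, small_panel):
        with pytest.raises(ValueError):
            bm.build_basis(small_panel[0], [])


def _dummy_candidate(alpha, rmse_value):
    H = bm.BasisMatrix(
        pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]}, index=["g1", "g2"])
    )
    return BasisCandidate(
        alpha=alpha, selected_features=("g1", "g2"), basis=H,
        cv_deviance=0.1, lymphocyte_rmse=rmse_value,
    )


class TestSelectBasis:
    def test_ties_go_to_largest_alpha(self):
        cands = [
            _dummy_candidate(1.0, 0.10),
            _dummy_candidate(0.6, 0.05),
            _dummy_candidate(0.3, 0.05),
        ]
        assert bm.select_basis(cands).alpha == 0.6

    def test_single_candidate_returned(self):
        c = _dummy_candidate(0.5, 0.2)
        assert bm.select_basis([c]) is c

    def test_order_invariance(self):
        cands = [_dummy_candidate(a, r) for a, r in [(0.2, 0.08), (1.0, 0.03), (0.5, 0.03)]]
        assert bm.select_basis(cands).alpha == bm.select_basis(cands[::-1]).alpha == 1.0

    def test_empty_and_unevaluated_rejected(self):
        with pytest.raises(ValueError):
            bm.select_basis([])
        with pytest.raises(ValueError):
            bm.select_basis([_dummy_candidate(1.0, math.nan)])


class TestConditionNumber:
    def test_orthonormal_columns_give_one(self):
        H = bm.BasisMatrix(
            pd.DataFrame(np.eye(3), index=["g1", "g2", "g3"], columns=["a", "b", "c"]),
        )
        assert bm.condition_number(H) == pytest.approx(1.0)

    def test_identical_columns_infinite(self):
        H = bm.BasisMatrix(
            pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]}, index=["g1", "g2"])
        )
        assert bm.condition_number(H) == math.inf

    def test_2x2_closed_form(self):
        M = np.array([[3.0, 0.0], [4.0, 5.0]])
        H = bm.BasisMatrix(pd.DataFrame(M, index=["g1", "g2"], columns=["a", "b"]))
        # singular values of M from eigenvalues of M^T M
        eig = np.linalg.eigvalsh(M.T @ M)
        expected = math.sqrt(eig[-1] / eig[0])
        assert bm.condition_number(H) == pytest.approx(expected)


class TestEvaluateCandidate:
    def test_perfect_predictions_give_zero_rmse(self, blood_panel):
        panel, truth = blood_panel
        markers = [g for gs in truth.marker_genes.values() for g in gs]
        H = bm.build_basis(panel, markers)
        # noiseless mixtures on the log2 scale of the basis itself
        W = bm.CompositionMatrix(
            pd.DataFrame(
                np.random.default_rng(0).dirichlet(np.ones(7), size=12),
                index=[f"s{i}" for i in range(12)],
                columns=H.cell_types,
            )
        )
        X = bm.ExpressionMatrix(
            pd.DataFrame(
                H.values.to_numpy() @ W.weights.to_numpy().T,
                index=H.feature_ids, columns=W.sample_ids,
            ),
            scale="log2",
        )
        diff = bm.simulate_differentials(W, error_cv=0.0)
        cand = BasisCandidate(
            alpha=1.0, selected_features=tuple(markers), basis=H, cv_deviance=0.0
        )
        out = bm.evaluate_candidate(cand, X, diff)
        assert out.lymphocyte_rmse == pytest.approx(0.0, abs=1e-6)
        assert np.isfinite(out.condition_number)
        assert "neutrophil_rmse" in out.metrics

    def test_marker_basis_beats_random_features(self, blood_panel):
        """Planted markers out-predict an equal number of random features."""
        panel, truth = blood_panel
        rng = np.random.default_rng(9)
        markers = [g for gs in truth.marker_genes.values() for g in gs]
        nonmarkers = [g for g in panel.feature_ids if g not in set(markers)]
        random_feats = list(rng.choice(nonmarkers, size=len(markers), replace=False))
        X, design, truth_mix = bm.simulate_mixtures(
            truth.profiles, n_per_group=15, noise_cv=0.1, seed=10
        )
        X_log = bm.to_log2(X, pseudocount=0.0)
        diff = bm.simulate_differentials(truth_mix.true_W, error_cv=0.0)
        rmses = []
        for feats in (markers, random_feats):
            H = bm.build_basis(panel, feats)
            cand = BasisCandidate(
                alpha=1.0, selected_features=tuple(feats), basis=H, cv_deviance=0.0
            )
            rmses.append(bm.evaluate_candidate(cand, X_log, diff).lymphocyte_rmse)
        assert rmses[0] < rmses[1]
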