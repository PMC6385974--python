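"""PCA, parallel analysis, covariate screening, stepdown and pruning."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from confoundr import (
    CountMatrix,
    SampleTable,
    greedy_stepdown,
    pca_normalized,
    prune_correlated,
    screen_covariates,
    select_num_pcs,
)
from confoundr.covsel import PCResult
from confoundr.normalize import size_factors

from conftest import make_sample_table


def _cm(counts):
    g = [f"g{i}" for i in range(counts.shape[0])]
    s = [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(g, s, np.asarray(counts))


class TestPCA:
    def test_identical_samples_have_zero_eigenvalues(self):
        counts = np.tile(np.array([[10], [40], [5]]), (1, 6))
        cm = _cm(counts)
        res = pca_normalized(cm, size_factors(cm))
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_rank_one_structure_dominates(self):
        rng = np.random.default_rng(1)
        factor = rng.normal(size=30)
        load = rng.normal(size=100)
        mu = np.exp(np.log(200) + 0.5 * np.outer(load, factor))
        counts = rng.poisson(mu)
        cm = _cm(counts)
        res = pca_normalized(cm, size_factors(cm))
        assert res.eigenvalues[0] / res.eigenvalues.sum() > 0.5

    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(2)
        counts = rng.negative_binomial(5, 0.05, size=(80, 12)) + 1
        cm = _cm(counts)
        nf = size_factors(cm)
        res = pca_normalized(cm, nf)
        from confoundr.covsel import normalized_log_matrix

        Y = normalized_log_matrix(cm, nf)
        total_var = Y.var(axis=0, ddof=1).sum()
        assert res.eigenvalues.sum() == pytest.approx(total_var, rel=1e-10)

    def test_single_sample_rejected(self):
        cm = _cm(np.array([[3], [5]]))
        with pytest.raises(ValueError):
            pca_normalized(cm, size_factors(cm))


class TestParallelAnalysis:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        counts = rng.negative_binomial(5, 0.05, size=(100, 20)) + 1
        cm = _cm(counts)
        nf = size_factors(cm)
        a = select_num_pcs(cm, nf, seed=9)
        b = select_num_pcs(cm, nf, seed=9)
        assert a.k_selected == b.k_selected
        np.testing.assert_array_equal(a.perm_eigenvalues, b.perm_eigenvalues)

    def test_k_capped_at_max_pcs(self):
        rng = np.random.default_rng(3)
        # very strong sample structure on many axes
        latent = rng.normal(size=(15, 40))
        loads = rng.normal(size=(300, 15))
        counts = rng.poisson(np.exp(np.log(100) + 0.3 * loads @ latent))
        cm = _cm(counts)
        res = select_num_pcs(cm, size_factors(cm), seed=1, max_pcs=4)
        assert res.k_selected <= 4


def _pc_result(scores):
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    return PCResult(scores=scores, eigenvalues=np.var(scores, axis=0, ddof=1),
                    k_selected=scores.shape[1])


class TestScreen:
    def test_perfect_monotone_continuous_association(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)
        st = make_sample_table(
            np.linspace(20, 80, 40),
            covariates={"x": scores.copy()},
            types={"x": "continuous"},
        )
        tab = screen_covariates(_pc_result(scores), st)
        row = tab[(tab.covariate == "x")].iloc[0]
        assert row.test == "Spearman"
        assert row.p < 1e-10 and row.candidate

    def test_fully_separated_binary_matches_exact_enumeration(self):
        # 10 vs 10 with complete separation: the two-sided exact MWW p-value
        # equals 2 / C(20,10) (only the two extreme rank assignments)
        scores = np.concatenate([np.arange(10), 100 + np.arange(10)]).astype(float)
        st = make_sample_table(
            [20.0] * 20,
            covariates={"grp": ["a"] * 10 + ["b"] * 10},
            types={"grp": "binary"},
        )
        tab = screen_covariates(_pc_result(scores), st)
        row = tab[tab.covariate == "grp"].iloc[0]
        assert row.test == "MWW"
        assert row.p == pytest.approx(2 / comb(20, 10), rel=1e-12)

    def test_independent_covariate_flagged_at_nominal_rate(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=60)
        pcs = _pc_result(scores)
        hits = 0
        n_sim = 800
        for _ in range(n_sim):
            st = make_sample_table(
                [20.0] * 60,
                covariates={"x": rng.normal(size=60)},
                types={"x": "continuous"},
            )
            tab = screen_covariates(pcs, st, include_trait=False)
            hits += int(tab.iloc[0].candidate)
        assert 0.07 < hits / n_sim < 0.13  # nominal 10% by construction

    def test_single_level_covariate_skipped_with_warning(self, caplog):
        st = make_sample_table(
            [20.0] * 10,
            covariates={"c": ["x"] * 10},
            types={"c": "categorical"},
        )
        with caplog.at_level("WARNING"):
            tab = screen_covariates(_pc_result(np.arange(10.0)), st)
        assert "c" not in set(tab.covariate[tab.covariate != "pcl_m"])

    def test_trait_is_screened_but_ineligible(self):
        rng = np.random.default_rng(7)
        st = make_sample_table(rng.uniform(18, 80, size=30))
        tab = screen_covariates(_pc_result(rng.normal(size=30)), st)
        trait_rows = tab[tab.covariate == "pcl_m"]
        assert len(trait_rows) == 1 and not trait_rows.iloc[0].eligible


class TestGreedyStepdown:
    def _setup(self, rng, n=120, n_decoys=10):
        true = rng.normal(size=n)
        scores = true + rng.normal(scale=1.0, size=n)  # R^2 about 0.5
        covs = {"true_pred": true}
        types = {"true_pred": "continuous"}
        for i in range(n_decoys):
            covs[f"decoy{i}"] = rng.normal(size=n)
            types[f"decoy{i}"] = "continuous"
        st = make_sample_table([20.0] * n, covariates=covs, types=types)
        pcs = _pc_result(scores)
        screen = screen_covariates(pcs, st, include_trait=False)
        return pcs, st, screen

    def test_true_predictor_recovered_few_decoys(self):
        rng = np.random.default_rng(11)
        recovered, decoys = 0, []
        for _ in range(50):
            pcs, st, screen = self._setup(rng)
            sel = greedy_stepdown(pcs, st, screen)[1]
            recovered += int("true_pred" in sel)
            decoys.append(len([c for c in sel if c != "true_pred"]))
        assert recovered >= 48  # >= 95% of runs
        assert np.mean(decoys) <= 1.0

    def test_duplicate_of_kept_covariate_rejected(self):
        rng = np.random.default_rng(12)
        n = 100
        true = rng.normal(size=n)
        scores = true + rng.normal(scale=0.5, size=n)
        st = make_sample_table(
            [20.0] * n,
            covariates={"a": true, "b": true.copy()},
            types={"a": "continuous", "b": "continuous"},
        )
        pcs = _pc_result(scores)
        screen = screen_covariates(pcs, st, include_trait=False)
        sel = greedy_stepdown(pcs, st, screen)[1]
        assert len(sel) == 1

    def test_empty_candidate_list_gives_empty_selection(self):
        rng = np.random.default_rng(13)
        st = make_sample_table(
            [20.0] * 30,
            covariates={"x": rng.normal(size=30)},
            types={"x": "continuous"},
        )
        pcs = _pc_result(rng.normal(size=30))
        screen = screen_covariates(pcs, st, include_trait=False)
        screen["candidate"] = False
        assert greedy_stepdown(pcs, st, screen) == {1: []}

    def test_selection_invariant_to_decoy_relabeling(self):
        rng1 = np.random.default_rng(14)
        pcs, st, screen = self._setup(rng1)
        sel1 = greedy_stepdown(pcs, st, screen)[1]
        # rename decoys (reverse order) without changing their values
        ren = {f"decoy{i}": f"decoy{9 - i}" for i in range(10)}
        st2 = SampleTable(st.data.rename(columns=ren),
                         {ren.get(k, k): v for k, v in st.covariate_types.items()})
        screen2 = screen_covariates(pcs, st2, include_trait=False)
        sel2 = greedy_stepdown(pcs, st2, screen2)[1]
        assert ("true_pred" in sel1) == ("true_pred" in sel2)
        assert len(sel1) == len(sel2)


class TestPrune:
    def test_perfectly_correlated_pair_keeps_one(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=50)
        st = make_sample_table(
            [20.0] * 50,
            covariates={"a": x, "b": 2 * x + 1},
            types={"a": "continuous", "b": "continuous"},
        )
        screen = pd.DataFrame(
            {"covariate": ["a", "b"], "pc": [1, 2], "test": ["Spearman"] * 2,
             "stat": [0, 0], "p": [1e-5, 1e-4], "candidate": [True, True],
             "eligible": [True, True]}
        )
        final = prune_correlated({1: ["a"], 2: ["b"]}, st, screen)
        assert final == ["a"]

    def test_independent_covariates_all_retained(self):
        rng = np.random.default_rng(16)
        st = make_sample_table(
            [20.0] * 50,
            covariates={"a": rng.normal(size=50), "b": rng.normal(size=50),
                        "c": rng.choice(list("xy"), size=50)},
            types={"a": "continuous", "b": "continuous", "c": "binary"},
        )
        screen = pd.DataFrame(
            {"covariate": ["a", "b", "c"], "pc": [1, 1, 2], "test": ["Spearman"] * 3,
             "stat": [0] * 3, "p": [1e-5, 1e-4, 1e-3], "candidate": [True] * 3,
             "eligible": [True] * 3}
        )
        final = prune_correlated({1: ["a", "b"], 2: ["c"]}, st, screen)
        assert sorted(final) == ["a", "b", "c"]

    def test_redundant_categorical_pair_pruned_via_cramers_v(self):
        levels = np.repeat(list("pqrs"), 12)
        st = make_sample_table(
            [20.0] * 48,
            covariates={"batch1": levels, "batch2": levels.copy()},
            types={"batch1": "categorical", "batch2": "categorical"},
        )
        screen = pd.DataFrame(
            {"covariate": ["batch1", "batch2"], "pc": [1, 2], "test": ["ANOVA"] * 2,
             "stat": [0, 0], "p": [1e-6, 1e-5], "candidate": [True, True],
             "eligible": [True, True]}
        )
        final = prune_correlated({1: ["batch1"], 2: ["batch2"]}, st, screen)
        assert final == ["batch1"]
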