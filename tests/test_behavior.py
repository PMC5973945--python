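import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fcident import (
    BehaviorSpec,
    CohortStack,
    CPMRegressor,
    SyntheticSpec,
    association_matrix,
    cpm_loocv,
    generate_behavior,
    generate_cohort,
    permutation_null,
    robust_intersection,
    significant_giant_component,
)
from fcident.behavior import AssociationGraph


def make_stack(matrix, subjects=None):
    n_cols = matrix.shape[1]
    subjects = subjects or [f"s{k + 1}" for k in range(n_cols)]
    n_regions = int((1 + np.sqrt(1 + 8 * matrix.shape[0])) / 2)
    return CohortStack(
        edge_matrix=matrix,
        sessions=pd.DataFrame({"subject": subjects, "visit": "test", "condition": "rest"}),
        n_regions=n_regions,
    )


def make_graph(n_regions, sig_edges, r=0.8):
    e = n_regions * (n_regions - 1) // 2
    p = np.ones(e)
    rv = np.zeros(e)
    from fcident import edge_index_pairs

    idx = {tuple(pair): k for k, pair in enumerate(edge_index_pairs(n_regions))}
    for pair in sig_edges:
        k = idx[tuple(sorted(pair))]
        p[k] = 1e-6
        rv[k] = r
    return AssociationGraph(r=rv, p=p, n_regions=n_regions, kept=np.ones(e, dtype=bool))


class TestAssociationMatrix:
    def test_matches_pearsonr_oracle(self, rng):
        x = rng.standard_normal((10, 6))  # 10 edges (5 regions), 6 subjects
        y = rng.standard_normal(6)
        g = association_matrix(make_stack(x), y)
        for e in range(10):
            r, p = stats.pearsonr(x[e], y)
            assert g.r[e] == pytest.approx(r, abs=1e-10)
            assert g.p[e] == pytest.approx(p, abs=1e-10)

    def test_noiseless_coupling_gives_unit_correlation(self, rng):
        x = rng.standard_normal((10, 8))
        g = association_matrix(make_stack(x), x[4])
        assert g.r[4] == pytest.approx(1.0, abs=1e-12)
        assert g.p[4] < 1e-10

    def test_constant_score_raises(self, rng):
        with pytest.raises(ValueError, match="constant"):
            association_matrix(make_stack(rng.standard_normal((10, 6))), np.ones(6))

    def test_series_alignment_by_subject(self, rng):
        x = rng.standard_normal((10, 6))
        y = rng.standard_normal(6)
        stack = make_stack(x)
        scrambled = pd.Series(y, index=stack.sessions["subject"]).sample(frac=1, random_state=0)
        g1 = association_matrix(stack, y)
        g2 = association_matrix(stack, scrambled)
        np.testing.assert_allclose(g1.r, g2.r, atol=1e-12)

    def test_shuffled_scores_break_association(self, rng):
        stack, truth = generate_cohort(SyntheticSpec(n_subjects=20, n_regions=15, seed=5))
        scores, bt = generate_behavior(stack, BehaviorSpec(n_coupled_edges=3, seed=5), truth)
        one = stack.select(visit="test")
        g = association_matrix(one, scores)
        gp = association_matrix(one, pd.Series(
            rng.permutation(scores.to_numpy()), index=scores.index))
        assert np.abs(g.r[bt.coupled_edges]).max() > np.abs(gp.r[bt.coupled_edges]).max()


class TestGiantComponent:
    def test_keeps_largest_component(self):
        g = make_graph(6, [(0, 1), (1, 2), (3, 4)])
        out = significant_giant_component(g, alpha=0.01)
        assert out.n_edges_kept == 2
        assert set(out.nodes_kept) == {0, 1, 2}

    def test_no_significant_edges_gives_empty_graph(self):
        g = make_graph(5, [])
        out = significant_giant_component(g)
        assert out.n_edges_kept == 0 and out.nodes_kept.size == 0

    def test_tied_components_keep_union(self):
        g = make_graph(6, [(0, 1), (2, 3)])
        out = significant_giant_component(g)
        assert out.n_edges_kept == 2
        assert set(out.nodes_kept) == {0, 1, 2, 3}

    def test_output_subset_of_input_and_monotone_in_alpha(self, rng):
        e = 45
        g = AssociationGraph(
            r=rng.uniform(-1, 1, e), p=rng.uniform(0, 1, e), n_regions=10,
            kept=np.ones(e, dtype=bool),
        )
        loose = significant_giant_component(g, alpha=0.5)
        tight = significant_giant_component(g, alpha=0.05)
        assert np.all(loose.kept <= g.kept)
        assert tight.n_edges_kept <= loose.n_edges_kept

    def test_networkx_export(self):
        g = significant_giant_component(make_graph(5, [(0, 1), (1, 2)]))
        nxg = g.to_networkx()
        assert nxg.number_of_edges() == 2


class TestRobustIntersection:
    def test_identical_graphs_keep_own_counts(self):
        g = significant_giant_component(make_graph(6, [(0, 1), (1, 2)]))
        assert robust_intersection(g, g) == (2, 3)

    def test_disjoint_graphs_give_zero(self):
        a = significant_giant_component(make_graph(6, [(0, 1)]))
        b = significant_giant_component(make_graph(6, [(3, 4)]))
        assert robust_intersection(a, b) == (0, 0)

    def test_single_shared_edge(self):
        a = significant_giant_component(make_graph(6, [(0, 1), (1, 2)]))
        b = significant_giant_component(make_graph(6, [(0, 1), (4, 5)]))
        assert robust_intersection(a, b) == (1, 2)

    def test_symmetric(self):
        a = significant_giant_component(make_graph(6, [(0, 1), (1, 2)]))
        b = significant_giant_component(make_graph(6, [(1, 2), (2, 3)]))
        assert robust_intersection(a, b) == robust_intersection(b, a)


class TestPermutationNull:
    def test_single_permutation_percentile_degenerate(self):
        stack, truth = generate_cohort(SyntheticSpec(n_subjects=10, n_regions=10, seed=2))
        scores, _ = generate_behavior(stack, BehaviorSpec(seed=2), truth)
        res = permutation_null(
            stack.select(visit="test"), stack.select(visit="retest"), scores,
            alpha=0.05, n_perm=1, seed=0,
        )
        assert res.percentile_edges in (0.0, 100.0)

    def test_deterministic_under_seed(self):
        stack, truth = generate_cohort(SyntheticSpec(n_subjects=10, n_regions=10, seed=2))
        scores, _ = generate_behavior(stack, BehaviorSpec(seed=2), truth)
        args = (stack.select(visit="test"), stack.select(visit="retest"), scores)
        a = permutation_null(*args, alpha=0.05, n_perm=20, seed=11)
        b = permutation_null(*args, alpha=0.05, n_perm=20, seed=11)
        np.testing.assert_array_equal(a.null_edges, b.null_edges)
        assert a.percentile_edges == b.percentile_edges

    def test_strong_coupling_scores_high_percentile(self):
        hits = 0
        for seed in range(5):
            spec = SyntheticSpec(n_subjects=40, n_regions=20, sd_noise=0.05, seed=seed)
            stack, truth = generate_cohort(spec)
            scores, _ = generate_behavior(
                stack, BehaviorSpec(n_coupled_edges=5, noise_sd=0.01, seed=seed), truth
            )
            res = permutation_null(
                stack.select(visit="test"), stack.select(visit="retest"), scores,
                alpha=0.05, n_perm=50, seed=seed,
            )
            hits += res.percentile_edges >= 90.0
        assert hits >= 3

    def test_observed_counts_match_direct_pipeline(self):
        stack, truth = generate_cohort(SyntheticSpec(n_subjects=12, n_regions=12, seed=7))
        scores, _ = generate_behavior(stack, BehaviorSpec(seed=7), truth)
        test, retest = stack.select(visit="test"), stack.select(visit="retest")
        res = permutation_null(test, retest, scores, alpha=0.1, n_perm=1, seed=0)
        ga = significant_giant_component(association_matrix(test, scores), alpha=0.1)
        gb = significant_giant_component(association_matrix(retest, scores), alpha=0.1)
        assert (res.n_edges_intersect, res.n_nodes_intersect) == robust_intersection(ga, gb)


class TestCPM:
    def test_noiseless_single_edge_coupling_predicts_well(self):
        spec = SyntheticSpec(n_subjects=30, n_regions=15, sd_noise=0.0, seed=9)
        stack, truth = generate_cohort(spec)
        scores, bt = generate_behavior(
            stack, BehaviorSpec(n_coupled_edges=1, noise_sd=0.0, seed=9), truth
        )
        # couple positively: flip the score sign if the planted beta is negative
        if bt.betas[0] < 0:
            scores = -scores
        res = cpm_loocv(stack.select(visit="test"), scores, k_grid=[1])
        assert res.r_pred[0] > 0.95

    def test_matches_bruteforce_loocv_oracle(self, rng):
        x = rng.standard_normal((15, 6))  # 6 regions... 15 edges, 6 subjects
        y = rng.standard_normal(6)
        stack = make_stack(x)
        k = 3
        res = cpm_loocv(stack, y, k_grid=[k], alpha=1.0)
        preds = np.empty(6)
        for i in range(6):
            train = [j for j in range(6) if j != i]
            xt, yt = x[:, train], y[train]
            rs = np.array([stats.pearsonr(xt[e], yt).statistic for e in range(15)])
            pool = np.flatnonzero(rs > 0)
            order = pool[np.argsort(-rs[pool], kind="stable")][:k]
            s_train = xt[order].sum(axis=0)
            slope, intercept = np.polyfit(s_train, yt, 1)
            preds[i] = intercept + slope * x[order, i].sum()
        expected = np.corrcoef(preds, y)[0, 1]
        assert res.r_pred[0] == pytest.approx(expected, abs=1e-10)

    def test_null_behavior_prediction_near_zero(self):
        rs = []
        for seed in range(6):
            stack, truth = generate_cohort(SyntheticSpec(n_subjects=25, n_regions=15, seed=seed))
            scores, _ = generate_behavior(
                stack, BehaviorSpec(n_coupled_edges=0, effect_sd=0.0, noise_sd=1.0, seed=seed),
                truth,
            )
            res = cpm_loocv(stack.select(visit="test"), scores, k_grid=[5, 10], alpha=0.05)
            rs.extend(res.r_pred[np.isfinite(res.r_pred)])
        assert abs(np.mean(rs)) < 0.35

    def test_empty_pool_reported_as_nan(self, rng):
        x = rng.standard_normal((15, 8))
        res = cpm_loocv(make_stack(x), rng.standard_normal(8), k_grid=[5], alpha=1e-12)
        assert np.isnan(res.r_pred[0])

    def test_icc_weighting_changes_ranking(self, rng):
        x = rng.standard_normal((15, 10))
        y = x[2] + 0.5 * x[7] + 0.1 * rng.standard_normal(10)
        icc = np.zeros(15)
        icc[7] = 1.0  # only edge 7 is reliable
        m_plain = CPMRegressor(k=1, alpha=1.0).fit(x.T, y)
        m_icc = CPMRegressor(k=1, alpha=1.0, icc=icc).fit(x.T, y)
        assert m_icc.edges_[0] == 7
        assert m_plain.edges_[0] == 2

    def test_rank_on_full_reproduces_leaky_variant(self, rng):
        x = rng.standard_normal((15, 8))
        y = x[3] + 0.3 * rng.standard_normal(8)
        full = cpm_loocv(make_stack(x), y, k_grid=[2], alpha=1.0, rank_on_full=True)
        fold = cpm_loocv(make_stack(x), y, k_grid=[2], alpha=1.0)
        assert np.isfinite(full.r_pred[0]) and np.isfinite(fold.r_pred[0])

    def test_sklearn_estimator_protocol(self, rng):
        from sklearn.model_selection import cross_val_predict, LeaveOneOut

        x = rng.standard_normal((12, 15))
        y = x[:, 4] + 0.1 * rng.standard_normal(12)
        est = CPMRegressor(k=2, alpha=1.0)
        preds = cross_val_predict(est, x, y, cv=LeaveOneOut())
        assert np.corrcoef(preds, y)[0, 1] > 0.5
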