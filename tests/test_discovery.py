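"""Statistics of episignature discovery, each checked against an
independent oracle (closed forms, brute-force enumerations, limma)."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from episig import discovery, io
from episig.io import SampleRecord, SampleSheet


def _beta(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"s{i:02d}" for i in range(values.shape[1])]
    return io.BetaMatrix(
        pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=samples)
    )


def _record(sid, group="case", sex="F", age=10.0, batch="b1"):
    return SampleRecord(sid, group, sex, age, batch, "EPIC", "discovery")


class TestMatchControls:
    def test_nearest_age_exact_categoricals(self):
        cases = SampleSheet([_record("case1", sex="F", age=10, batch="A")])
        pool = SampleSheet([
            _record("c1", "control", "F", 9, "A"),
            _record("c2", "control", "F", 30, "A"),
            _record("c3", "control", "M", 10, "A"),
        ])
        res = discovery.match_controls(cases, pool, ratio=1, exact_on=("sex", "batch"))
        assert res.matches == {"case1": ["c1"]}

    def test_ratio_two_takes_both_eligible(self):
        cases = SampleSheet([_record("case1", sex="F", age=10, batch="A")])
        pool = SampleSheet([
            _record("c1", "control", "F", 9, "A"),
            _record("c2", "control", "F", 30, "A"),
            _record("c3", "control", "M", 10, "A"),
        ])
        res = discovery.match_controls(cases, pool, ratio=2, exact_on=("sex", "batch"))
        assert res.matches["case1"] == ["c1", "c2"]

    def test_no_same_sex_control_errors(self):
        cases = SampleSheet([_record("case1", sex="F")])
        pool = SampleSheet([_record("c1", "control", "M")])
        with pytest.raises(io.ValidationError, match="case1"):
            discovery.match_controls(cases, pool, ratio=1)

    def test_without_replacement(self):
        cases = SampleSheet([_record("case1", age=10), _record("case2", age=10)])
        pool = SampleSheet([
            _record(f"c{i}", "control", age=10 + i) for i in range(8)
        ])
        res = discovery.match_controls(cases, pool, ratio=4)
        picked = res.control_ids
        assert len(picked) == len(set(picked)) == 8

    def test_age_tie_broken_by_control_id(self):
        cases = SampleSheet([_record("case1", age=10)])
        pool = SampleSheet([_record("c2", "control", age=11), _record("c1", "control", age=9)])
        res = discovery.match_controls(cases, pool, ratio=1)
        assert res.matches["case1"] == ["c1"]


class TestFitProbeModels:
    def test_no_covariates_equals_group_mean_difference(self):
        rng = np.random.default_rng(0)
        vals = rng.random((20, 8))
        sheet = SampleSheet(
            [_record(f"s{i:02d}", "case" if i < 4 else "control") for i in range(8)]
        )
        fit = discovery.fit_probe_models(_beta(vals), sheet)
        expected = vals[:, :4].mean(axis=1) - vals[:, 4:].mean(axis=1)
        assert np.allclose(fit.delta_beta, expected, atol=1e-12)

    def test_orthogonal_covariate_leaves_effect_unchanged(self):
        rng = np.random.default_rng(1)
        vals = rng.random((10, 8))
        sheet = SampleSheet(
            [_record(f"s{i:02d}", "case" if i < 4 else "control") for i in range(8)]
        )
        beta = _beta(vals)
        fit0 = discovery.fit_probe_models(beta, sheet)
        # covariate orthogonal to both intercept and case indicator
        cov = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        frac = np.column_stack([0.5 + 0.1 * cov, 0.5 - 0.1 * cov])
        cp = type("CP", (), {})()
        from episig.preprocess import CellProportions
        cp = CellProportions(pd.DataFrame(
            frac, index=pd.Index(beta.sample_ids, name="sample_id"), columns=["a", "b"]
        ))
        fit1 = discovery.fit_probe_models(beta, sheet, cp)
        assert np.allclose(fit0.delta_beta, fit1.delta_beta, atol=1e-10)

    def test_residual_df_two_groups_of_two(self):
        vals = np.random.default_rng(2).random((5, 4))
        sheet = SampleSheet(
            [_record(f"s{i:02d}", "case" if i < 2 else "control") for i in range(4)]
        )
        fit = discovery.fit_probe_models(_beta(vals), sheet)
        assert fit.df_residual == 2  # n - 2

    def test_rank_deficient_design_named(self):
        vals = np.random.default_rng(3).random((5, 6))
        sheet = SampleSheet(
            [_record(f"s{i:02d}", "case" if i < 3 else "control") for i in range(6)]
        )
        from episig.preprocess import CellProportions
        labels = np.array([1.0, 1, 1, 0, 0, 0])
        cp = CellProportions(pd.DataFrame(
            np.column_stack([0.3 + 0.2 * labels, 0.7 - 0.2 * labels]),
            index=pd.Index([f"s{i:02d}" for i in range(6)], name="sample_id"),
            columns=["a", "b"],
        ))
        with pytest.raises(io.ValidationError, match="collinear"):
            discovery.fit_probe_models(_beta(vals), sheet, cp)


class TestSqueezeVariances:
    def test_identical_variances_give_infinite_prior(self):
        s2 = np.full(100, 0.02)
        prior, post = discovery.squeeze_variances(s2, 8.0)
        assert np.isinf(prior.d0)
        assert np.allclose(post, prior.s0_2)

    def test_infinite_prior_df_gives_pooled_z_test(self):
        prior = discovery.VariancePrior(d0=np.inf, s0_2=0.05)
        rng = np.random.default_rng(0)
        s2 = rng.uniform(0.01, 0.1, 50)
        delta = rng.normal(0, 0.05, 50)
        fit = discovery.ProbeModelFit(
            probe_ids=[f"cg{i}" for i in range(50)], delta_beta=delta,
            s2=s2, df_residual=8.0, v=0.1, n_samples=10,
        )
        table = discovery.moderated_t_test(fit, prior)
        assert np.isinf(table["df_total"]).all()
        # per-probe variances are ignored entirely; normal reference
        t_ref = delta / np.sqrt(prior.s0_2 * fit.v)
        p_ref = 2 * stats.norm.sf(np.abs(t_ref))
        assert np.allclose(table["t"], t_ref) and np.allclose(table["p"], p_ref)

    def test_prior_recovery_from_simulated_variances(self):
        rng = np.random.default_rng(10)
        d0, s0_2, dg = 4.0, 0.02, 10.0
        true_var = s0_2 * d0 / rng.chisquare(d0, size=50_000)
        s2 = true_var * rng.chisquare(dg, size=50_000) / dg
        prior, _ = discovery.squeeze_variances(s2, dg)
        assert abs(prior.d0 - d0) / d0 <= 0.20
        assert abs(prior.s0_2 - s0_2) / s0_2 <= 0.10

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(io.ValidationError):
            discovery.squeeze_variances(np.array([0.01] * 20 + [0.0]), 8.0)

    def test_agrees_with_limma_squeezevar(self, tmp_path):
        rng = np.random.default_rng(3)
        dg = 8.0
        true_var = 0.03 * 5 / rng.chisquare(5, size=2_000)
        s2 = true_var * rng.chisquare(dg, size=2_000) / dg
        path = tmp_path / "s2.txt"
        np.savetxt(path, s2)
        prior, post = discovery.squeeze_variances(s2, dg)
        script = (
            'suppressMessages(library(limma));'
            f's2 <- scan("{path}", quiet=TRUE);'
            'fit <- squeezeVar(s2, df=8);'
            'cat(fit$df.prior, fit$var.prior, fit$var.post[1], fit$var.post[2000])'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                             check=True).stdout.split()
        r_d0, r_s0, r_p1, r_pn = map(float, out)
        assert prior.d0 == pytest.approx(r_d0, rel=1e-4)
        assert prior.s0_2 == pytest.approx(r_s0, rel=1e-4)
        assert post[0] == pytest.approx(r_p1, rel=1e-4)
        assert post[-1] == pytest.approx(r_pn, rel=1e-4)


class TestModeratedT:
    def _fit(self, delta, s2, dg=8.0, v=0.25):
        n = len(delta)
        return discovery.ProbeModelFit(
            probe_ids=[f"cg{i}" for i in range(n)], delta_beta=np.asarray(delta, float),
            s2=np.asarray(s2, float), df_residual=dg, v=v, n_samples=int(dg) + 2,
        )

    def test_zero_effect_gives_t_zero_p_one(self):
        table = discovery.moderated_t_test(
            self._fit([0.0, 0.1], [0.01, 0.01]), discovery.VariancePrior(4.0, 0.01)
        )
        assert table["t"].iloc[0] == 0.0
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_quadrupling_prior_variance_halves_t_at_infinite_d0(self):
        fit = self._fit([0.1] * 5, [0.02] * 5)
        t1 = discovery.moderated_t_test(fit, discovery.VariancePrior(np.inf, 0.02))["t"]
        t2 = discovery.moderated_t_test(fit, discovery.VariancePrior(np.inf, 0.08))["t"]
        assert np.allclose(t1, 2 * t2)

    def test_zero_prior_df_matches_textbook_t_test(self):
        # with d0 = 0 the moderated statistic is the ordinary two-sample t
        rng = np.random.default_rng(4)
        n1 = n2 = 6
        vals = rng.random((40, n1 + n2))
        sheet = SampleSheet(
            [_record(f"s{i:02d}", "case" if i < n1 else "control") for i in range(n1 + n2)]
        )
        fit = discovery.fit_probe_models(_beta(vals), sheet)
        table = discovery.moderated_t_test(fit, discovery.VariancePrior(0.0, 1.0))
        t_ref, p_ref = stats.ttest_ind(vals[:, :n1], vals[:, n1:], axis=1, equal_var=True)
        assert np.allclose(table["t"].to_numpy(), t_ref, atol=1e-10)
        assert np.allclose(table["p"].to_numpy(), p_ref, atol=1e-10)


def _bh_brute_force(p):
    """Literal step-up: adj_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        best = 1.0
        for rank_j in range(rank_i, m + 1):
            cand = min(1.0, m * p[order[rank_j - 1]] / rank_j)
            best = min(best, cand)
        adj[idx] = best
    return adj


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert discovery.benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_hand_enumerated_examples(self):
        assert np.allclose(
            discovery.benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )
        assert np.allclose(discovery.benjamini_hochberg([0.04, 0.01]), [0.04, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(io.ValidationError):
            discovery.benjamini_hochberg([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, p):
        assert np.allclose(discovery.benjamini_hochberg(p), _bh_brute_force(p), atol=1e-12)


class TestProbeAUC:
    def test_complete_separation(self):
        labels = [True, True, False, False]
        assert discovery.probe_auc([0.1, 0.2, 0.8, 0.9], labels) == 1.0

    def test_constant_probe_is_uninformative(self):
        assert discovery.probe_auc([0.5] * 6, [True] * 3 + [False] * 3) == 0.5

    def test_enumerated_pairs(self):
        # cases {0.2, 0.3}, controls {0.25, 0.4}: 3 of 4 pairs concordant
        labels = [True, True, False, False]
        assert discovery.probe_auc([0.2, 0.3, 0.25, 0.4], labels) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(io.ValidationError):
            discovery.probe_auc([0.1, 0.2], [True, True])


class TestPruneCorrelated:
    def test_duplicate_probe_dropped(self):
        rng = np.random.default_rng(0)
        row = rng.random(20)
        beta = _beta(np.vstack([row, row, rng.random(20)]), ["a", "b", "c"])
        assert discovery.prune_correlated(["a", "b", "c"], beta) == ["a", "c"]

    def test_independent_noise_all_retained(self):
        rng = np.random.default_rng(1)
        beta = _beta(rng.random((10, 50)))
        probes = beta.probe_ids
        assert discovery.prune_correlated(probes, beta) == probes

    def test_constructed_high_correlation_dropped(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.2, 0.7, 200)
        y = x + 0.082 * rng.uniform(0, 1, 200)  # engineered r close to 0.95
        r = np.corrcoef(x, y)[0, 1]
        assert 0.9 < r < 0.99
        beta = _beta(np.vstack([x, y]), ["top", "shadow"])
        assert discovery.prune_correlated(["top", "shadow"], beta, r_max=0.9) == ["top"]


class TestEvaluateSeparation:
    def test_tight_separated_clusters_score_high(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.01, size=(10, 5))
        b = rng.normal(1.0, 0.01, size=(10, 5))
        score = discovery.evaluate_separation(np.vstack([a, b]), ["x"] * 10 + ["y"] * 10)
        assert score > 0.9

    def test_permuted_labels_score_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0.5, 0.1, size=(40, 20))
        labels = rng.permutation(["x"] * 20 + ["y"] * 20)
        assert abs(discovery.evaluate_separation(X, labels)) < 0.1

    def test_duplicating_samples_leaves_score_nearly_unchanged(self):
        # mean silhouette is invariant to sample multiplicity up to the
        # zero self-copy distances, an O(1/n) effect
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.2, (8, 6)), rng.normal(1, 0.2, (8, 6))])
        labels = ["x"] * 8 + ["y"] * 8
        s1 = discovery.evaluate_separation(X, labels)
        s2 = discovery.evaluate_separation(np.vstack([X, X]), labels + labels)
        assert s1 == pytest.approx(s2, abs=0.05)

    def test_empty_probe_set_rejected(self):
        with pytest.raises(io.ValidationError):
            discovery.evaluate_separation(np.empty((10, 0)), ["x"] * 5 + ["y"] * 5)


class TestSelectEpisignature:
    def test_single_cutoff_returns_that_pruned_set(self, small_study):
        st_ = small_study
        full = discovery.select_episignature(st_.dmp, st_.model_beta, st_.labels,
                                             cutoff_grid=(0.05,))
        ranked = st_.dmp[st_.dmp["adj_p"] < 0.05]
        expected = discovery.prune_correlated(
            list(discovery._ranked_probes(st_.dmp)[lambda d: d["adj_p"] < 0.05].index),
            st_.model_beta,
        )
        assert full.probes == expected
        assert full.cutoff == 0.05
        assert len(ranked) >= len(full.probes)

    def test_empty_grid_rejected(self, small_study):
        with pytest.raises(io.ValidationError):
            discovery.select_episignature(
                small_study.dmp, small_study.model_beta, small_study.labels, cutoff_grid=()
            )

    def test_discovery_cases_pure_at_two_cut(self, default_study):
        st_ = default_study
        X = st_.model_beta.select_probes(st_.probe_set.probes).values.to_numpy().T
        dend = discovery.hierarchical_clustering(X, labels=st_.model_beta.sample_ids)
        clusters = dend.cut(2)
        case_clusters = {clusters[s] for s in st_.match.case_ids}
        ctrl_clusters = {clusters[s] for s in st_.match.control_ids}
        assert len(case_clusters) == 1
        assert case_clusters.isdisjoint(ctrl_clusters)


class TestClassicalMDS:
    def test_equilateral_triangle_recovered(self):
        D = np.ones((3, 3)) - np.eye(3)
        mds = discovery.classical_mds(D, k=2)
        coords = mds.coords.to_numpy()
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(coords), 1.0, atol=1e-8)

    def test_planar_configuration_reproduced(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(pts))
        mds = discovery.classical_mds(D, k=2)
        assert np.allclose(pdist(mds.coords.to_numpy()), pdist(pts), atol=1e-8)

    def test_identical_points_give_zero_coordinates(self):
        D = np.zeros((4, 4))
        mds = discovery.classical_mds(D, k=2)
        assert np.allclose(mds.coords.to_numpy(), 0.0)

    def test_asymmetric_input_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(io.ValidationError):
            discovery.classical_mds(D)


def _complete_linkage_brute_force(points):
    """Exhaustive agglomeration: merge the closest pair under max-distance."""
    from scipy.spatial.distance import cdist
    clusters = {i: [i] for i in range(len(points))}
    heights = []
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = cdist(points[clusters[a]], points[clusters[b]]).max()
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merges.append((frozenset(clusters[a]), frozenset(clusters[b])))
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return heights, merges


class TestHierarchicalClustering:
    def test_duplicate_pairs_merge_first_at_zero_height(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        dend = discovery.hierarchical_clustering(pts)
        assert np.allclose(dend.heights[:2], 0.0)
        assert dend.heights[-1] > 0

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(0)
        dend = discovery.hierarchical_clustering(rng.random((15, 4)))
        assert (np.diff(dend.heights) >= -1e-12).all()

    def test_matches_brute_force_on_five_points(self):
        rng = np.random.default_rng(5)
        pts = rng.random((5, 3))
        dend = discovery.hierarchical_clustering(pts)
        heights, _ = _complete_linkage_brute_force(pts)
        assert np.allclose(np.sort(dend.heights), np.sort(heights), atol=1e-10)

    def test_newick_reparses_with_same_leaves(self):
        rng = np.random.default_rng(1)
        labels = [f"s{i}" for i in range(8)]
        dend = discovery.hierarchical_clustering(rng.random((8, 5)), labels=labels)
        import skbio
        tree = skbio.TreeNode.read([dend.to_newick()])
        assert sorted(t.name for t in tree.tips()) == sorted(labels)

    def test_nan_rejected(self):
        pts = np.array([[0.0, np.nan], [1.0, 1.0]])
        with pytest.raises(io.ValidationError):
            discovery.hierarchical_clustering(pts)
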