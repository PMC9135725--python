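"""Bray-Curtis/nMDS/ANOSIM, PCA, mixed models and site clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from sigwhistle import stats, synth
from sigwhistle.features import PARAM_COLUMNS
from sigwhistle.stats import DistanceMatrix


def table_from(rows, labels=None):
    labels = labels or [f"s{i}" for i in range(len(rows))]
    return pd.DataFrame(np.asarray(rows, dtype=float), index=labels)


class TestBrayCurtis:
    def test_identical_vectors_have_zero_distance(self):
        dm = stats.bray_curtis(table_from([[1, 2, 3], [1, 2, 3]]), fourth_root=False)
        assert dm.matrix[0, 1] == 0.0

    def test_disjoint_support_after_fourth_root(self):
        dm = stats.bray_curtis(table_from([[16, 0], [0, 16]]), fourth_root=True)
        assert dm.matrix[0, 1] == pytest.approx(1.0)

    def test_symmetry_on_random_vectors(self):
        rng = np.random.default_rng(0)
        dm = stats.bray_curtis(table_from(rng.uniform(0, 5, (6, 4))))
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)
        assert dm.matrix.max() <= 1.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            stats.bray_curtis(table_from([[1, -1], [2, 3]]))


class TestNmds:
    def planar_dm(self, n=10, seed=1):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1, (n, 2))
        return DistanceMatrix([f"s{i}" for i in range(n)],
                              squareform(pdist(pts)), metric="euclidean")

    def test_planar_configuration_has_near_zero_stress(self):
        res = stats.nmds(self.planar_dm(), k=2, n_restarts=8, seed=0)
        assert res.stress < 0.01

    def test_seeded_runs_are_identical(self):
        dm = self.planar_dm(8, seed=2)
        a = stats.nmds(dm, n_restarts=4, seed=3)
        b = stats.nmds(dm, n_restarts=4, seed=3)
        assert np.allclose(a.coords.to_numpy(), b.coords.to_numpy())
        assert a.stress == b.stress

    def test_simplex_requires_positive_stress(self):
        # four mutually equidistant points need three dimensions
        m = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("abcd"), m, metric="euclidean")
        res = stats.nmds(dm, k=2, n_restarts=8, seed=0)
        assert res.stress > 0.0

    def test_too_few_samples_raises(self):
        m = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            stats.nmds(DistanceMatrix(list("abc"), m), k=2)


def brute_force_anosim(matrix, labels):
    """Independent ANOSIM: naive midranks and explicit enumeration."""
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    d = [matrix[i, j] for i, j in pairs]
    order = sorted(range(len(d)), key=lambda k: d[k])
    ranks = [0.0] * len(d)
    k = 0
    while k < len(order):
        j = k
        while j + 1 < len(order) and d[order[j + 1]] == d[order[k]]:
            j += 1
        avg = (k + j) / 2.0 + 1.0
        for idx in order[k:j + 1]:
            ranks[idx] = avg
        k = j + 1

    def r_of(lab):
        rw = [ranks[k] for k, (i, j) in enumerate(pairs) if lab[i] == lab[j]]
        rb = [ranks[k] for k, (i, j) in enumerate(pairs) if lab[i] != lab[j]]
        return (np.mean(rb) - np.mean(rw)) / (len(pairs) / 2.0)

    observed = r_of(labels)
    perms = sorted(set(itertools.permutations(labels)))
    r_all = [r_of(p) for p in perms]
    p = np.mean([r >= observed - 1e-12 for r in r_all])
    return observed, p, len(perms)


class TestAnosim:
    def test_perfectly_separated_groups_give_r_one(self):
        rows = [[1, 1], [1.1, 1], [1, 1.1], [5, 5], [5.1, 5], [5, 5.1]]
        dm = stats.bray_curtis(table_from(rows), fourth_root=False)
        res = stats.anosim(dm, ["a"] * 3 + ["b"] * 3, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        for sizes in [(3, 3), (2, 4), (2, 2, 2), (4, 4), (2, 3, 3)]:
            labels = [f"g{i}" for i, s in enumerate(sizes) for _ in range(s)]
            x = rng.uniform(0.1, 5, (len(labels), 3))
            dm = stats.bray_curtis(table_from(x), fourth_root=True)
            mine = stats.anosim(dm, labels, method="exhaustive")
            r_bf, p_bf, n_bf = brute_force_anosim(dm.matrix, labels)
            assert mine.r == pytest.approx(r_bf, abs=1e-12), sizes
            assert mine.p_value == pytest.approx(p_bf, abs=1e-12), sizes
            assert mine.n_permutations == n_bf

    def test_matches_scikit_bio(self):
        import skbio

        rng = np.random.default_rng(7)
        x = rng.uniform(0, 3, (12, 4))
        dm = stats.bray_curtis(table_from(x))
        g = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        mine = stats.anosim(dm, g, n_perm=499, seed=1)
        ref = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(dm.matrix, dm.labels), grouping=g,
            permutations=499)
        assert mine.r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_singleton_group_raises_with_name(self):
        dm = stats.bray_curtis(table_from(np.ones((5, 2)) + np.eye(5, 2)))
        with pytest.raises(ValueError, match="lonely"):
            stats.anosim(dm, ["a", "a", "b", "b", "lonely"])


class TestPca:
    def test_rank_one_data_loads_on_first_component(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=300)
        cols = {p: (i + 1) * base + rng.normal(scale=1e-6, size=300)
                for i, p in enumerate(PARAM_COLUMNS)}
        res = stats.pca_reduce(pd.DataFrame(cols))
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-6)

    def test_variance_fractions_sum_to_one(self):
        t = synth.make_blocked_feature_table(200, seed=1)
        res = stats.pca_reduce(t)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_scores_reconstruct_standardised_data(self):
        t = synth.make_blocked_feature_table(150, seed=2)
        res = stats.pca_reduce(t, kaiser=False)
        z = (t - t.mean()) / t.std(ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, z.to_numpy(), atol=1e-8)

    def test_blocked_table_retains_three_components(self):
        t = synth.make_blocked_feature_table(500, seed=4)
        res = stats.pca_reduce(t)
        assert res.n_retained == 3
        top = {pc: set(res.loadings[pc].abs().nlargest(2).index)
               for pc in ("PC1", "PC2", "PC3")}
        assert top["PC1"] == {"max_freq", "end_freq"}
        assert top["PC2"] == {"min_freq", "start_freq"}
        assert top["PC3"] <= {"duration", "n_inflections", "freq_range"}

    def test_reporting_orientation(self):
        t = synth.make_blocked_feature_table(500, seed=4)
        res = stats.orient_components(
            stats.pca_reduce(t),
            {"PC1": ("max_freq", -1), "PC2": ("min_freq", 1),
             "PC3": ("duration", 1)})
        assert res.loadings.loc["max_freq", "PC1"] < 0
        assert res.loadings.loc["end_freq", "PC1"] < 0
        assert res.loadings.loc["min_freq", "PC2"] > 0
        assert res.loadings.loc["start_freq", "PC2"] > 0
        assert res.loadings.loc["duration", "PC3"] > 0
        assert res.loadings.loc["freq_range", "PC3"] < 0

    def test_constant_column_raises_with_name(self):
        t = synth.make_blocked_feature_table(50, seed=0)
        t["duration"] = 1.0
        with pytest.raises(ValueError, match="duration"):
            stats.pca_reduce(t)

    def test_outlier_removal_drops_extreme_rows(self):
        t = synth.make_blocked_feature_table(100, seed=3)
        t.loc[0, "min_freq"] = 1e6
        kept = stats.remove_outliers(t)
        assert 0 not in kept.index and len(kept) >= 90


def simulate_mixed(seed, n_groups=40, obs=8, effect=0.0, re_sd=1.0, resid=0.5):
    rng = np.random.default_rng(seed)
    ids = np.repeat(np.arange(n_groups), obs)
    fac = np.where(ids % 2 == 0, "A", "B")
    y = effect * (fac == "B") + rng.normal(0, re_sd, n_groups)[ids] \
        + rng.normal(0, resid, ids.size)
    return pd.DataFrame({"y": y, "fac": fac, "sw_id": ids})


class TestMixedModels:
    def test_recovers_effect_and_variances(self):
        ests, re_sds, resid_sds = [], [], []
        for seed in range(5):
            df = simulate_mixed(seed, n_groups=100, obs=10, effect=0.5)
            res = stats.fit_glmm(df, "y", "fac")
            ests.append(res.fixed_effects.loc["B", "Value"])
            re_sds.append(res.random_intercept_sd)
            resid_sds.append(res.residual_sd)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.15)
        assert np.mean(re_sds) == pytest.approx(1.0, rel=0.12)
        assert np.mean(resid_sds) == pytest.approx(0.5, rel=0.1)

    def test_containment_degrees_of_freedom(self):
        df = simulate_mixed(1, n_groups=40, obs=8)
        res = stats.fit_glmm(df, "y", "fac")
        assert res.fixed_effects.loc["B", "DF"] == 40 - 1 - 1
        assert res.fixed_effects.loc["Intercept", "DF"] == 320 - 40 - 1

    def test_t_equals_value_over_se(self):
        df = simulate_mixed(2)
        res = stats.fit_glmm(df, "y", "fac")
        fe = res.fixed_effects
        assert np.allclose(fe["t-value"], fe["Value"] / fe["SE"])

    def test_invariant_to_row_order_and_relabelling(self):
        df = simulate_mixed(3)
        res1 = stats.fit_glmm(df, "y", "fac")
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        shuffled["sw_id"] = shuffled["sw_id"].map(lambda g: f"id-{g + 1000}")
        res2 = stats.fit_glmm(shuffled, "y", "fac")
        assert np.allclose(res1.fixed_effects["Value"],
                           res2.fixed_effects["Value"], atol=1e-6)
        assert res1.random_intercept_sd == pytest.approx(
            res2.random_intercept_sd, abs=1e-6)

    def test_equal_group_means_flag_boundary_variance(self):
        ids = np.repeat(np.arange(30), 4)
        y = np.tile([-1.0, 1.0, -0.5, 0.5], 30)  # every group mean exactly 0
        fac = np.where(ids % 2 == 0, "A", "B")
        df = pd.DataFrame({"y": y, "fac": fac, "sw_id": ids})
        res = stats.fit_glmm(df, "y", "fac")
        assert res.boundary
        assert res.random_intercept_sd == pytest.approx(0.0, abs=1e-3)

    def test_single_level_factor_raises(self):
        df = simulate_mixed(4)
        df["fac"] = "A"
        with pytest.raises(ValueError):
            stats.fit_glmm(df, "y", "fac")

    def test_diagnostics_present(self):
        res = stats.fit_glmm(simulate_mixed(5), "y", "fac")
        assert set(res.diagnostics) >= {"resid_mean", "shapiro_p",
                                        "abs_resid_vs_fitted_rho"}


class TestSiteClustering:
    def test_identical_rows_share_a_cluster(self):
        t = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 2.0, 9.0]},
                         index=["x", "y", "z"])
        for method in ("ward", "complete"):
            sc = stats.cluster_sites(t, method, 2)
            d = sc.as_dict()
            assert d["x"] == d["y"] != d["z"]

    def test_three_separated_triplets_recovered_by_both_linkages(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        rows, truth = [], []
        for c in range(3):
            for k in range(3):
                rows.append(centers[c] + rng.normal(0, 0.1, 2))
                truth.append(c)
        t = pd.DataFrame(rows, index=[f"s{i}" for i in range(9)])
        for method in ("ward", "complete"):
            sc = stats.cluster_sites(t, method, 3)
            got = sc.clusters
            mapping = {}
            for g, tr in zip(got, truth):
                mapping.setdefault(tr, g)
                assert mapping[tr] == g

    def test_seabottom_clustering_reproduces_reported_grouping(self, site_profiles):
        sc = stats.seabottom_clustering(site_profiles)
        assert sc.as_dict() == dict(site_profiles["seabottom"])

    def test_demography_clustering_reproduces_reported_partition(self, site_profiles):
        sc = stats.demography_clustering(site_profiles)
        got = sc.as_dict()
        partition = {}
        for site, lab in got.items():
            partition.setdefault(lab, set()).add(site)
        expected = {}
        for site, lab in site_profiles["demography"].items():
            expected.setdefault(lab, set()).add(site)
        assert set(map(frozenset, partition.values())) == \
               set(map(frozenset, expected.values()))

    def test_too_many_clusters_raises(self, site_profiles):
        with pytest.raises(ValueError):
            stats.cluster_sites(site_profiles[["depth_max_m"]], "ward", 10)


def test_mean_feature_table_averages_per_sw(small_study):
    df = pd.DataFrame({
        "sw_id": ["A", "A", "B"],
        "site": ["AL", "AL", "GC"],
        **{p: [1.0, 2.0, 3.0] for p in PARAM_COLUMNS},
    })
    means = stats.mean_feature_table(df)
    assert means.loc["A", "duration"] == 1.5
    assert means.loc["B", "duration"] == 3.0
    assert list(means["site"]) == ["AL", "GC"]
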