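"""Community statistics: distances, matrix tests, ordination, core, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import bioenv as skbio_bioenv

from oracles import (
    anosim_r_naive,
    mantel_exhaustive_p,
    weighted_unifrac_naive,
)
from riversed._utils import DegenerateInputError, RiversedError
from riversed.community import (
    anosim,
    best_env,
    core_features,
    hellinger_distance,
    mantel,
    partial_mantel,
    pcoa,
    per_feature_anova,
    procrustes,
    rarefy,
    weighted_unifrac,
    zscore_profiles,
)
from riversed.simulate import _random_tree_newick


def _euclid_dm(points, ids=None):
    points = np.asarray(points, float)
    ids = ids or [f"S{i}" for i in range(points.shape[0])]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestRarefy:
    def test_forced_outcome(self):
        t = pd.DataFrame([[10, 0]], index=["a"], columns=["x", "y"])
        out = rarefy(t, 5, seed=0)
        assert out.loc["a"].tolist() == [5, 0]

    def test_row_sums_equal_depth(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.integers(0, 60, size=(6, 10)))
        t.iloc[:, 0] += 100
        out = rarefy(t, 80, seed=1)
        assert (out.sum(axis=1) == 80).all()

    def test_shallow_samples_dropped_with_warning(self, caplog):
        t = pd.DataFrame([[50, 50], [2, 1]], index=["deep", "shallow"])
        with caplog.at_level("WARNING", logger="riversed"):
            out = rarefy(t, 10, seed=0)
        assert list(out.index) == ["deep"]
        assert any("shallow" in r.message for r in caplog.records)

    def test_invalid_depth_rejected(self):
        with pytest.raises(RiversedError):
            rarefy(pd.DataFrame([[5]]), 0, seed=0)

    def test_hypergeometric_mean(self):
        """[30, 30] rarefied to 30: mean first count ~ 15 (300 seeds)."""
        t = pd.DataFrame([[30, 30]], index=["a"])
        draws = [rarefy(t, 30, seed=s).iloc[0, 0] for s in range(300)]
        assert abs(np.mean(draws) - 15.0) < 1.0


class TestHellinger:
    def test_disjoint_supports_reach_sqrt2(self):
        t = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"])
        assert hellinger_distance(t)["a", "b"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_distance_zero(self):
        t = pd.DataFrame([[3, 5, 2], [3, 5, 2]], index=["a", "b"])
        assert hellinger_distance(t)["a", "b"] == pytest.approx(0.0)

    def test_compositional_invariance(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.integers(1, 40, size=(4, 6)))
        scaled = t.copy()
        scaled.iloc[2] *= 10
        np.testing.assert_allclose(hellinger_distance(t).data,
                                   hellinger_distance(scaled).data, atol=1e-12)

    def test_zero_sum_sample_rejected(self):
        with pytest.raises(RiversedError, match="zero-sum"):
            hellinger_distance(pd.DataFrame([[0, 0], [1, 2]], index=["a", "b"]))


class TestWeightedUnifrac:
    def test_two_leaf_closed_form(self):
        newick = "(a:1,b:1);"
        t = pd.DataFrame([[10, 0], [0, 10]], index=["A", "B"], columns=["a", "b"])
        assert weighted_unifrac(t, newick)["A", "B"] == pytest.approx(2.0)
        assert weighted_unifrac(t, newick, normalized=True)["A", "B"] == pytest.approx(1.0)

    def test_identical_abundances_distance_zero(self):
        newick = "((a:1,b:2):1,c:3);"
        t = pd.DataFrame([[4, 5, 6], [4, 5, 6]], index=["A", "B"],
                         columns=["a", "b", "c"])
        assert weighted_unifrac(t, newick)["A", "B"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_per_branch_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(8)]
        newick = _random_tree_newick(taxa, rng)
        counts = rng.integers(1, 30, size=(2, 8))
        t = pd.DataFrame(counts, index=["A", "B"], columns=taxa)
        for normalized in (False, True):
            expected = weighted_unifrac_naive(counts[0], counts[1], taxa, newick,
                                              normalized=normalized)
            got = weighted_unifrac(t, newick, normalized=normalized)["A", "B"]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_feature_missing_from_tree_rejected(self):
        t = pd.DataFrame([[1, 2], [3, 4]], index=["A", "B"], columns=["a", "zz"])
        with pytest.raises(RiversedError, match="zz"):
            weighted_unifrac(t, "(a:1,b:1);")


class TestMantel:
    def test_self_correlation_is_one(self):
        d = _euclid_dm(np.random.default_rng(0).normal(size=(6, 2)))
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        d = _euclid_dm(np.random.default_rng(0).normal(size=(5, 2)))
        const = DistanceMatrix(1 - np.eye(5), ids=list(d.ids))
        with pytest.raises(DegenerateInputError):
            mantel(d, const, n_perm=99)

    def test_mismatched_ids_rejected(self):
        a = _euclid_dm(np.random.default_rng(0).normal(size=(4, 2)), ids=list("abcd"))
        b = _euclid_dm(np.random.default_rng(1).normal(size=(4, 2)), ids=list("abcx"))
        with pytest.raises(RiversedError):
            mantel(a, b, n_perm=99)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        d1 = _euclid_dm(rng.normal(size=(5, 2)))
        d2 = _euclid_dm(rng.normal(size=(5, 2)), ids=list(d1.ids))
        exact = mantel_exhaustive_p(d1.data, d2.data)
        res = mantel(d1, d2, n_perm=9999, seed=0)
        assert res.p == pytest.approx(exact, abs=0.02)


class TestPartialMantel:
    def test_controlling_for_the_second_matrix_gives_zero(self):
        rng = np.random.default_rng(0)
        d1 = _euclid_dm(rng.normal(size=(8, 2)))
        d2 = _euclid_dm(rng.normal(size=(8, 2)), ids=list(d1.ids))
        res = partial_mantel(d1, d2, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_three_identical_matrices_degenerate(self):
        d = _euclid_dm(np.random.default_rng(0).normal(size=(6, 2)))
        with pytest.raises(DegenerateInputError):
            partial_mantel(d, d, d, n_perm=99)

    def test_independent_control_preserves_simple_r(self):
        """With an unrelated control, partial r ~ simple r (n=20)."""
        rng = np.random.default_rng(1)
        base = rng.normal(size=(20, 2))
        d1 = _euclid_dm(base)
        d2 = _euclid_dm(base + rng.normal(scale=0.3, size=base.shape),
                        ids=list(d1.ids))
        dc = _euclid_dm(rng.normal(size=(20, 2)), ids=list(d1.ids))
        simple = mantel(d1, d2, n_perm=99, seed=0).r
        partial = partial_mantel(d1, d2, dc, n_perm=99, seed=0).r
        assert partial == pytest.approx(simple, abs=0.05)


class TestBestEnv:
    def _driven_instance(self, seed=0, extra_noise_vars=3):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=12)
        dm = DistanceMatrix(np.abs(v[:, None] - v[None, :]),
                            ids=[f"S{i}" for i in range(12)])
        env = pd.DataFrame({"driver": v}, index=list(dm.ids))
        for j in range(extra_noise_vars):
            env[f"noise{j}"] = rng.normal(size=12)
        return dm, env

    def test_perfect_driver_recovered_with_rho_one(self):
        dm, env = self._driven_instance()
        res = best_env(dm, env)
        assert res.variables == ("driver",)
        assert res.rho == pytest.approx(1.0)

    def test_all_nonempty_subsets_evaluated(self):
        dm, env = self._driven_instance(extra_noise_vars=5)
        res = best_env(dm, env)
        assert len(res.table) == 2**6 - 1

    def test_pure_noise_variable_does_not_help(self):
        """Adding a noise variable leaves the best rho essentially unchanged."""
        diffs = []
        for seed in range(20):
            dm, env = self._driven_instance(seed=seed, extra_noise_vars=2)
            rho_without = best_env(dm, env.drop(columns="noise1")).rho
            rho_with = best_env(dm, env).rho
            assert rho_with >= rho_without - 1e-12  # supersets can only help
            diffs.append(rho_with - rho_without)
        assert np.mean(diffs) < 0.02

    def test_matches_skbio_bioenv_best_correlation(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 2))
        dm = _euclid_dm(pts)
        env = pd.DataFrame(rng.normal(size=(10, 3)), index=list(dm.ids),
                           columns=["a", "b", "c"])
        env["a"] += pts[:, 0]
        mine = best_env(dm, env)
        ref = skbio_bioenv(dm, env)
        assert mine.rho == pytest.approx(ref["correlation"].max(), abs=1e-9)

    def test_guards(self):
        dm, env = self._driven_instance()
        with pytest.raises(RiversedError):
            best_env(dm, env.iloc[:, :0])
        wide = pd.DataFrame(np.random.default_rng(0).normal(size=(12, 21)),
                            index=list(dm.ids))
        wide.columns = [f"v{i}" for i in range(21)]
        with pytest.raises(RiversedError):
            best_env(dm, wide)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        block = np.array([
            [0.0, 1.0, 5.0, 6.0],
            [1.0, 0.0, 6.0, 5.0],
            [5.0, 6.0, 0.0, 1.0],
            [6.0, 5.0, 1.0, 0.0],
        ])
        res = anosim(DistanceMatrix(block), ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_null_r_centred_on_zero(self):
        rs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d = _euclid_dm(rng.normal(size=(8, 2)))
            labels = rng.permutation(["a"] * 4 + ["b"] * 4)
            rs.append(anosim(d, list(labels), n_perm=99, seed=seed).R)
        assert abs(np.mean(rs)) < 0.05

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_rank_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 9))
        d = _euclid_dm(rng.normal(size=(n, 2)))
        labels = ["a"] * (n // 2) + ["b"] * (n - n // 2)
        res = anosim(d, labels, n_perm=99, seed=seed)
        assert res.R == pytest.approx(anosim_r_naive(d.data, labels), abs=1e-9)

    def test_singleton_group_rejected(self):
        d = _euclid_dm(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(DegenerateInputError):
            anosim(d, ["a", "a", "a", "a", "b"], n_perm=99)


class TestPcoa:
    def test_equilateral_triangle_has_two_equal_eigenvalues(self):
        d = DistanceMatrix(np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]]))
        res = pcoa(d)
        eig = np.sort(res.eigenvalues.to_numpy())[::-1]
        assert len(eig) == 2
        assert eig[0] == pytest.approx(eig[1], rel=1e-9)
        assert (eig > 0).all()

    def test_euclidean_distances_roundtrip(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(7, 3))
        res = pcoa(_euclid_dm(pts))
        rec = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(rec, squareform(pdist(pts)), atol=1e-9)

    def test_duplicated_sample_coincides(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        res = pcoa(_euclid_dm(pts))
        c = res.coordinates.to_numpy()
        np.testing.assert_allclose(c[1], c[2], atol=1e-9)

    def test_non_euclidean_input_drops_negative_axes_with_warning(self, caplog):
        d = DistanceMatrix(np.array([
            [0.0, 1.0, 1.0, 1.9],
            [1.0, 0.0, 1.9, 1.0],
            [1.0, 1.9, 0.0, 1.0],
            [1.9, 1.0, 1.0, 0.0],
        ]))
        with caplog.at_level("WARNING", logger="riversed"):
            res = pcoa(d)
        assert res.negative_fraction > 0
        assert any("negative-eigenvalue" in r.message for r in caplog.records)


class TestProcrustes:
    def _config(self, seed=0, n=8, k=2):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, k)),
                            index=[f"S{i}" for i in range(n)])

    def test_rotated_scaled_copy_superimposes_exactly(self):
        x = self._config()
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        y = pd.DataFrame(3.0 * x.to_numpy() @ rot + 5.0, index=x.index)
        res = procrustes(x, y, n_perm=99, seed=0)
        assert res.m2 == pytest.approx(0.0, abs=1e-12)

    def test_axis_relabeling_invariance(self):
        x = self._config(1)
        y = self._config(2)
        swapped = y.iloc[:, [1, 0]]
        a = procrustes(x, y, n_perm=99, seed=0)
        b = procrustes(x, swapped, n_perm=99, seed=0)
        assert a.m2 == pytest.approx(b.m2, abs=1e-12)

    def test_dimension_padding(self):
        x = self._config(3, k=3)
        y = self._config(3, k=2)
        res = procrustes(x, y, n_perm=99, seed=0)
        assert 0 <= res.m2 <= 1

    def test_small_noise_gives_small_m2_and_significant_p(self):
        x = self._config(4)
        spread = x.to_numpy().std()
        y = x + np.random.default_rng(5).normal(scale=0.01 * spread, size=x.shape)
        res = procrustes(x, y, n_perm=999, seed=0)
        assert res.m2 < 0.05 and res.p <= 0.05

    def test_too_few_samples_rejected(self):
        x = self._config().iloc[:2]
        with pytest.raises(RiversedError):
            procrustes(x, x, n_perm=99)


class TestCoreFeatures:
    def _table(self):
        return pd.DataFrame(
            {
                "everywhere_abundant": [100, 100, 60],   # total 260 > 200, all > 0
                "patchy_abundant": [0, 10**6, 10**6],    # absent once
                "everywhere_rare": [50, 50, 50],         # total 150 <= 200
            },
            index=["s1", "s2", "s3"],
        )

    def test_default_rule(self):
        res = core_features(self._table())
        assert res.features == ("everywhere_abundant",)
        total = self._table().to_numpy().sum()
        assert res.read_fraction == pytest.approx(260 / total)

    def test_per_sample_threshold_flag(self):
        res = core_features(self._table(), min_total_reads=55, per_sample=True)
        assert res.features == ("everywhere_abundant",)
        res2 = core_features(self._table(), min_total_reads=40, per_sample=True)
        assert set(res2.features) == {"everywhere_abundant", "everywhere_rare"}

    def test_core_and_noncore_partition_features(self):
        t = self._table()
        res = core_features(t)
        assert set(res.features) | (set(t.columns) - set(res.features)) == set(t.columns)


class TestPerFeatureAnova:
    def test_hand_computed_f(self):
        t = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]})
        res = per_feature_anova(t, ["a", "a", "b", "b"])
        assert res.loc[0, "F"] == pytest.approx(8.0)

    def test_bonferroni_definition(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(size=(6, 10)))
        res = per_feature_anova(t, ["a", "a", "a", "b", "b", "b"])
        np.testing.assert_allclose(
            res["p_bonferroni"], np.minimum(res["p"] * 10, 1.0), atol=1e-12
        )

    def test_degenerate_feature_flagged_na(self):
        t = pd.DataFrame({"flat": [1.0, 1.0, 2.0, 2.0], "ok": [1.0, 2.0, 3.0, 5.0]})
        res = per_feature_anova(t, ["a", "a", "b", "b"]).set_index("feature")
        assert res.loc["flat", "degenerate"]
        assert np.isnan(res.loc["flat", "p"])
        assert not res.loc["ok", "degenerate"]

    def test_group_requirements(self):
        t = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(DegenerateInputError):
            per_feature_anova(t, ["a", "a", "b"])


class TestZscoreProfiles:
    def test_linear_profile(self):
        sm = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f1"], columns=["s1", "s2", "s3"])
        res = zscore_profiles(sm)
        np.testing.assert_allclose(res.z.loc["f1"], [-1.0, 0.0, 1.0])

    def test_constant_profile_flagged_zeros(self, caplog):
        sm = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]],
                          index=["flat", "rise"], columns=["s1", "s2", "s3"])
        with caplog.at_level("WARNING", logger="riversed"):
            res = zscore_profiles(sm)
        assert res.constant_features == ("flat",)
        np.testing.assert_allclose(res.z.loc["flat"], 0.0)

    def test_identical_profiles_merge_first_at_height_zero(self):
        sm = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 1.0, 2.0]],
                          index=["a", "b", "c"], columns=["s1", "s2", "s3"])
        res = zscore_profiles(sm)  # a and b share a z-profile
        first = res.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_single_site_rejected(self):
        with pytest.raises(RiversedError):
            zscore_profiles(pd.DataFrame([[1.0]], index=["f"], columns=["s"]))
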