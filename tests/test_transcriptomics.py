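"""Normalization, EC binning, exact tests, kinetics, masking, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from defcom import synthetic as syn
from defcom import transcriptomics as tx


def _cm(counts: pd.DataFrame, species=None, ec=None) -> tx.CountMatrix:
    annot = pd.DataFrame(index=counts.index)
    annot["species"] = species if species is not None else "sp01"
    annot["ec"] = ec if ec is not None else None
    return tx.CountMatrix(counts=counts, annotation=annot)


class TestSizeFactors:
    def test_doubled_sample_gets_double_factor(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [20, 40, 10]})
        sf = tx.size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_identical_samples_all_one(self):
        counts = pd.DataFrame({"s1": [3, 9, 1], "s2": [3, 9, 1], "s3": [3, 9, 1]})
        assert np.allclose(tx.size_factors(counts), 1.0)

    def test_median_of_ratios_hand_computation(self):
        counts = pd.DataFrame({"s1": [2, 4], "s2": [4, 8]})
        sf = tx.size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert sf["s2"] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_fallback_to_library_size_with_warning(self):
        counts = pd.DataFrame({"s1": [5, 0], "s2": [0, 15]})
        with pytest.warns(RuntimeWarning, match="library-size"):
            sf = tx.size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(3.0)


class TestNormalize:
    def test_single_species_levels_agree(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [20, 40, 10]},
                              index=["g1", "g2", "g3"])
        cm = _cm(counts)
        a = tx.normalize(cm, "community").counts
        b = tx.normalize(cm, "species").counts
        pd.testing.assert_frame_equal(a, b, check_like=True)

    def test_species_level_restores_stable_species(self):
        # species A doubles in s2; species B constant
        counts = pd.DataFrame(
            {"s1": [10, 30, 8, 24], "s2": [20, 60, 8, 24]},
            index=["a1", "a2", "b1", "b2"],
        )
        cm = _cm(counts, species=["A", "A", "B", "B"])
        sp = tx.normalize(cm, "species").counts
        assert np.allclose(sp.loc[["b1", "b2"], "s1"], sp.loc[["b1", "b2"], "s2"])
        assert np.allclose(sp.loc[["a1", "a2"], "s1"], sp.loc[["a1", "a2"], "s2"])

    def test_normalizing_normalized_matrix_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [2, 4]})
        cm = tx.normalize(_cm(counts), "community")
        with pytest.raises(ValueError, match="raw"):
            tx.normalize(cm, "community")


class TestBinByEc:
    def test_same_ec_summed(self):
        counts = pd.DataFrame({"s1": [5, 7, 3]}, index=["g1", "g2", "g3"])
        cm = _cm(counts, ec=["1.1.1.1", "1.1.1.1", None])
        out = tx.bin_by_ec(cm)
        assert out.at["1.1.1.1", "s1"] == 12
        assert len(out) == 1  # no-EC gene contributes nowhere

    def test_multi_ec_gene_counts_fully_in_each(self):
        counts = pd.DataFrame({"s1": [5]}, index=["g1"])
        cm = _cm(counts, ec=["1.1.1.1;2.2.2.2"])
        out = tx.bin_by_ec(cm)
        assert out.at["1.1.1.1", "s1"] == 5
        assert out.at["2.2.2.2", "s1"] == 5

    def test_matches_groupby_oracle_and_sum_identity(self, rng):
        genes = [f"g{i}" for i in range(40)]
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(40, 3)), index=genes, columns=["s1", "s2", "s3"]
        )
        ecs = rng.choice(["1.1.1.1", "2.2.2.2", "3.3.3.3", None], size=40).tolist()
        cm = _cm(counts, ec=ecs)
        out = tx.bin_by_ec(cm)
        # independent aggregation oracle
        oracle = counts.assign(ec=ecs).dropna(subset=["ec"]).groupby("ec").sum()
        pd.testing.assert_frame_equal(out, oracle.astype(float), check_names=False)
        # collapsing-then-summing equals summing annotated genes
        annotated = counts.loc[[g for g, e in zip(genes, ecs) if e is not None]]
        assert np.allclose(out.sum(axis=0), annotated.sum(axis=0))


class TestNbExactTest:
    def test_binomial_oracle_at_zero_dispersion(self):
        ec = pd.DataFrame(
            {"a1": [0], "a2": [0], "b1": [10], "b2": [10]}, index=["e"]
        )
        sf = pd.Series(1.0, index=["a1", "a2", "b1", "b2"])
        res = tx.nb_exact_test(ec, sf, ["a1", "a2"], ["b1", "b2"], dispersion=0.0)
        expected = sps.binomtest(0, 20, 0.5).pvalue  # 0/20 split at p=1/2
        assert res.table.at["e", "p"] == pytest.approx(expected, rel=1e-9)

    def test_identical_groups_p_one(self):
        ec = pd.DataFrame({"a1": [7], "a2": [7], "b1": [7], "b2": [7]}, index=["e"])
        sf = pd.Series(1.0, index=ec.columns)
        res = tx.nb_exact_test(ec, sf, ["a1", "a2"], ["b1", "b2"])
        assert res.table.at["e", "p"] == pytest.approx(1.0)

    def test_all_zero_feature_p_one(self):
        ec = pd.DataFrame({"a1": [0], "a2": [0], "b1": [0], "b2": [0]}, index=["e"])
        sf = pd.Series(1.0, index=ec.columns)
        res = tx.nb_exact_test(ec, sf, ["a1", "a2"], ["b1", "b2"])
        assert res.table.at["e", "p"] == 1.0

    def test_null_type_one_error_within_band(self):
        rng = np.random.default_rng(42)
        n_feat = 1000
        counts = pd.DataFrame(
            rng.poisson(40.0, size=(n_feat, 6)),
            index=[f"e{i}" for i in range(n_feat)],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        sf = pd.Series(1.0, index=counts.columns)
        res = tx.nb_exact_test(counts, sf, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        rate = (res.table["p"] < 0.05).mean()
        assert 0.03 < rate < 0.07

    def test_unequal_size_factors_shift_expectation(self):
        # group B sequenced twice as deep: equal normalized means -> null
        ec = pd.DataFrame({"a1": [10], "a2": [10], "b1": [20], "b2": [20]}, index=["e"])
        sf = pd.Series({"a1": 1.0, "a2": 1.0, "b1": 2.0, "b2": 2.0})
        res = tx.nb_exact_test(ec, sf, ["a1", "a2"], ["b1", "b2"], dispersion=0.0)
        assert res.table.at["e", "p"] > 0.5


class TestMannWhitneyExact:
    def test_complete_separation_four_vs_four(self):
        p = tx.mann_whitney_exact([1, 2, 3, 4], [5, 6, 7, 8])
        assert p == pytest.approx(2 / 70)
        assert round(p, 2) == 0.03

    def test_identical_multisets_p_one(self):
        assert tx.mann_whitney_exact([1, 2, 2], [1, 2, 2]) == pytest.approx(1.0)

    @pytest.mark.parametrize("na,nb", [(2, 3), (3, 3), (4, 4), (4, 5), (5, 5)])
    def test_matches_scipy_exact_without_ties(self, na, nb, rng):
        for _ in range(20):
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            ours = tx.mann_whitney_exact(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ties_match_exact_permutation_oracle(self, rng):
        for _ in range(10):
            a = rng.integers(0, 4, size=4).astype(float)
            b = rng.integers(0, 4, size=4).astype(float)
            ours = tx.mann_whitney_exact(a, b)
            # independent oracle: enumerate labelings, U from scratch
            pooled = np.concatenate([a, b])
            na = len(a)
            mid = na * len(b) / 2

            def u_stat(idx):
                grp = pooled[list(idx)]
                rest = np.delete(pooled, list(idx))
                return sum((g > r) + 0.5 * (g == r) for g in grp for r in rest)

            obs = u_stat(range(na))
            devs = [
                abs(u_stat(c) - mid) >= abs(obs - mid) - 1e-9
                for c in itertools.combinations(range(len(pooled)), na)
            ]
            assert ours == pytest.approx(np.mean(devs), rel=1e-9)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            tx.mann_whitney_exact([1.0, np.nan], [2.0, 3.0])


class TestKinetics:
    def _traj(self, pairs):
        return pd.Series(dict(pairs))

    def test_step_change_is_rapid(self):
        t = self._traj({13: 0.0, 14: 10.0, 20: 10.0, 27: 10.0})
        assert tx.classify_kinetics(t, 13, 27).label == "rapid"

    def test_linear_ramp_is_gradual(self):
        t = self._traj({13: 0.0, 15: 1.5, 20: 5.0, 24: 7.8, 27: 10.0})
        assert tx.classify_kinetics(t, 13, 27).label == "gradual"

    def test_flat_then_jump_is_delayed(self):
        t = self._traj({13: 0.0, 15: 0.2, 20: 0.5, 24: 0.8, 27: 10.0})
        assert tx.classify_kinetics(t, 13, 27).label == "delayed"

    def test_subfloor_change_is_none(self):
        t = self._traj({13: 5.0, 15: 5.1, 20: 5.0, 24: 5.2, 27: 5.1})
        assert tx.classify_kinetics(t, 13, 27, response_floor=2.0).label == "none"

    def test_missing_required_day_rejected(self):
        t = self._traj({13: 0.0, 20: 5.0, 27: 10.0})
        with pytest.raises(ValueError, match="within 2 d"):
            tx.classify_kinetics(t, 13, 27)


class TestMasking:
    def _result(self, p, direction):
        return tx.DiffResult(
            pd.DataFrame(
                {"statistic": [0.0], "p": [p], "q": [p], "fold_change": [1.0],
                 "direction": [direction]},
                index=["ec1"],
            )
        )

    def test_opposite_significant_directions_flagged(self):
        flagged = tx.detect_masking(
            self._result(0.03, "down"), self._result(0.03, "up"), alpha=0.05
        )
        assert flagged == ["ec1"]

    def test_same_direction_not_flagged(self):
        assert (
            tx.detect_masking(
                self._result(0.01, "up"), self._result(0.01, "up"), alpha=0.05
            )
            == []
        )

    def test_nonsignificant_not_flagged(self):
        assert (
            tx.detect_masking(
                self._result(0.2, "down"), self._result(0.01, "up"), alpha=0.05
            )
            == []
        )

    def test_synthetic_scenario_end_to_end(self):
        _, _, cm, sp, ec = syn.masking_scenario(seed=77)
        diets = cm.sample_meta["diet"]
        ga = list(diets.index[diets == "LF/HPP"])
        gb = list(diets.index[diets == "HF/HS"])
        comm, spres, flagged = tx.masking_pipeline(cm, ga, gb)
        assert ec in flagged
        assert comm.table.at[ec, "direction"] == "down"
        assert spres.table.at[ec, "direction"] == "up"
        assert comm.table.at[ec, "p"] == pytest.approx(2 / 70)
        assert spres.table.at[ec, "p"] == pytest.approx(2 / 70)


class TestClusterWithBootstrap:
    def test_duplicated_column_groups_fully_supported(self):
        rng = np.random.default_rng(8)
        sig1 = rng.normal(0, 1, 50)
        sig2 = rng.normal(0, 1, 50)
        cols = {
            "a1": sig1 + rng.normal(0, 0.01, 50),
            "a2": sig1 + rng.normal(0, 0.01, 50),
            "b1": sig2 + rng.normal(0, 0.01, 50),
            "b2": sig2 + rng.normal(0, 0.01, 50),
        }
        values = pd.DataFrame(cols)
        _, support = tx.cluster_with_bootstrap(values, n_boot=50, seed=1)
        by_members = support.set_index("members")["support"]
        assert by_members[("a1", "a2")] == 1.0
        assert by_members[("b1", "b2")] == 1.0

    def test_noise_columns_weak_support(self):
        rng = np.random.default_rng(9)
        values = pd.DataFrame(
            rng.normal(size=(60, 8)), columns=[f"c{i}" for i in range(8)]
        )
        _, support = tx.cluster_with_bootstrap(values, n_boot=60, seed=2)
        nontrivial = support[(support["size"] > 1) & (support["size"] < 8)]
        assert nontrivial["support"].median() < 0.95

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(10)
        values = pd.DataFrame(rng.normal(size=(30, 5)))
        values.columns = [f"c{i}" for i in range(5)]
        _, s1 = tx.cluster_with_bootstrap(values, n_boot=30, seed=3)
        _, s2 = tx.cluster_with_bootstrap(values, n_boot=30, seed=3)
        pd.testing.assert_frame_equal(s1, s2)

    def test_zero_bootstrap_rejected(self):
        values = pd.DataFrame(np.eye(4), columns=list("abcd"))
        with pytest.raises(ValueError, match="n_boot"):
            tx.cluster_with_bootstrap(values, n_boot=0)


class TestPresentAndDeCalls:
    def _setup(self, det_a, det_b, expr_b_scale=1.0, n=7):
        genes = ["g1"]
        ga = [f"a{i}" for i in range(n)]
        gb = [f"b{i}" for i in range(n)]
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            np.concatenate(
                [rng.normal(100, 5, n), rng.normal(100 * expr_b_scale, 5, n)]
            )[None, :],
            index=genes,
            columns=ga + gb,
        )
        flags = pd.DataFrame(
            [[i < det_a for i in range(n)] + [i < det_b for i in range(n)]],
            index=genes,
            columns=ga + gb,
        )
        return expr, flags, {"A": ga, "B": gb}

    def test_five_of_seven_on_one_diet_present(self):
        expr, flags, groups = self._setup(5, 0)
        present, _ = tx.present_and_de_calls(expr, flags, groups)
        assert present["g1"]

    def test_four_of_seven_on_both_diets_excluded(self):
        expr, flags, groups = self._setup(4, 4)
        present, _ = tx.present_and_de_calls(expr, flags, groups)
        assert not present["g1"]

    def test_fold_change_below_two_not_de(self):
        # strong signal but |FC| < 2 -> never DE regardless of p
        rng = np.random.default_rng(1)
        n = 7
        ga = [f"a{i}" for i in range(n)]
        gb = [f"b{i}" for i in range(n)]
        expr = pd.DataFrame(
            np.vstack(
                [
                    np.concatenate([rng.normal(100, 1, n), rng.normal(180, 1, n)]),
                    np.concatenate([rng.normal(100, 1, n), rng.normal(300, 1, n)]),
                ]
            ),
            index=["g_small_fc", "g_big_fc"],
            columns=ga + gb,
        )
        flags = pd.DataFrame(True, index=expr.index, columns=expr.columns)
        _, res = tx.present_and_de_calls(expr, flags, {"A": ga, "B": gb})
        assert res.table.at["g_small_fc", "direction"] == "none"
        assert res.table.at["g_big_fc", "direction"] == "up"
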