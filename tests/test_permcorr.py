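"""Group-mean collapse and permutation-test correlation significance."""

import math

import numpy as np
import pandas as pd
import pytest

import lnclink as L


class TestGroupMeans:
    def test_replicate_average(self, normalized_small, small_dataset):
        gm = L.group_means(normalized_small, small_dataset.samples)
        assert gm.group_labels == small_dataset.samples.group_order()
        ids = small_dataset.samples.groups["BALBc_2w_sham"]
        expected = normalized_small.data[ids].mean(axis=1)
        np.testing.assert_allclose(gm.data["BALBc_2w_sham"], expected)

    def test_sample_column_order_irrelevant(self, normalized_small, small_dataset):
        gm1 = L.group_means(normalized_small, small_dataset.samples)
        shuffled = L.ExpressionMatrix(
            normalized_small.data[normalized_small.sample_ids[::-1]], scale="log2"
        )
        gm2 = L.group_means(shuffled, small_dataset.samples)
        pd.testing.assert_frame_equal(gm1.data, gm2.data)

    def test_single_replicate_group_warns(self, caplog):
        data = pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["s1", "s2"])
        m = L.ExpressionMatrix(data, scale="log2")
        samples = L.SampleTable(pd.DataFrame({
            "sample_id": ["s1", "s2"], "strain": "BALBc", "timepoint_weeks": 4,
            "treatment": ["sham", "IR"], "replicate": [1, 1],
        }))
        with caplog.at_level("WARNING"):
            gm = L.group_means(m, samples)
        assert any("single replicate" in r.message for r in caplog.records)
        np.testing.assert_array_equal(gm.data.to_numpy(), 1.0)


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert L.pearson_r(x, x) == 1.0
        assert L.pearson_r(x, -x) == -1.0

    def test_textbook_sum_formula_oracle(self):
        # n*Sxy - Sx*Sy over sqrt((n*Sxx - Sx^2)(n*Syy - Sy^2)) = 19/21
        x = np.arange(1.0, 9.0)
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0])
        assert L.pearson_r(x, y) == pytest.approx(19 / 21, abs=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(L.DegeneratePairError):
            L.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(L.ValidationError):
            L.pearson_r([1.0, 2.0], [3.0, 4.0])


class TestMonteCarloPermutation:
    def test_self_correlation_greater_mode_gives_p_zero(self):
        x = np.arange(8.0)
        res = L.permutation_pvalue(x, x, comparison="greater", seed=0)
        assert res.r_observed == 1.0 and res.p_perm == 0.0

    def test_same_seed_reproduces_result_exactly(self):
        x, y = L.simulate_pair(8, target_r=0.5, seed=4)
        a = L.permutation_pvalue(x, y, seed=123)
        b = L.permutation_pvalue(x, y, seed=123)
        assert a == b
        c = L.permutation_pvalue(x, y, seed=124)
        band = 4 * math.sqrt(max(a.p_perm * (1 - a.p_perm), 1e-4) / a.n_perms)
        assert abs(c.p_perm - a.p_perm) <= band

    def test_monte_carlo_matches_exhaustive_on_fixture(self):
        x, y = L.simulate_pair(8, target_r=0.4, seed=9)
        exact = L.exhaustive_permutation_pvalue(x, y)
        mc = L.permutation_pvalue(x, y, n_perms=10_000, seed=2)
        band = 3 * math.sqrt(exact.p_perm * (1 - exact.p_perm) / 10_000)
        assert abs(mc.p_perm - exact.p_perm) <= band

    def test_p_consistency_invariant(self):
        x, y = L.simulate_pair(8, target_r=0.2, seed=1)
        res = L.permutation_pvalue(x, y, n_perms=500, seed=0)
        assert res.p_perm == res.n_exceeding / res.n_perms
        assert 0 <= res.p_perm <= 1
        assert res.p_corrected == (res.n_exceeding + 1) / (res.n_perms + 1)

    def test_invalid_inputs(self):
        x = np.arange(8.0)
        with pytest.raises(L.ValidationError):
            L.permutation_pvalue(x, x, n_perms=0)
        with pytest.raises(L.DegeneratePairError):
            L.permutation_pvalue(np.ones(8), x)
        with pytest.raises(L.ValidationError):
            L.permutation_pvalue(x, x, comparison="two_sided")


class TestExhaustivePermutation:
    def test_length_8_enumerates_40320(self):
        x, y = L.simulate_pair(8, target_r=0.3, seed=3)
        res = L.exhaustive_permutation_pvalue(x, y)
        assert res.n_perms == math.factorial(8) == 40_320
        assert res.mode == "exhaustive"

    def test_constant_vector_rejected(self):
        with pytest.raises(L.DegeneratePairError):
            L.exhaustive_permutation_pvalue(np.ones(8), np.arange(8.0))

    def test_too_long_directs_to_monte_carlo(self):
        with pytest.raises(L.ValidationError, match="Monte-Carlo"):
            L.exhaustive_permutation_pvalue(np.arange(11.0), np.arange(11.0))

    def test_anti_sorted_pair_one_sided_p_near_one(self):
        x = np.arange(8.0)
        res = L.exhaustive_permutation_pvalue(x, -x + 0.01 * x**2, comparison="greater")
        assert res.p_perm > 0.99

    def test_symmetry_permuting_x_or_y(self):
        x, y = L.simulate_pair(8, target_r=0.6, seed=5)
        assert (
            L.exhaustive_permutation_pvalue(x, y).p_perm
            == L.exhaustive_permutation_pvalue(y, x).p_perm
        )

    def test_monotone_in_observed_correlation(self):
        """Within one x-family of increasing |r|, exhaustive p never increases."""
        rng = np.random.default_rng(8)
        y = rng.normal(size=8)
        e = rng.normal(size=8)
        results = []
        for alpha in np.linspace(0.0, 1.0, 9):
            x = alpha * y + (1 - alpha) * e
            res = L.exhaustive_permutation_pvalue(x, y)
            results.append((abs(res.r_observed), res.p_perm))
        results.sort(key=lambda t: t[0])
        ps = [p for _, p in results]
        assert all(p2 <= p1 for p1, p2 in zip(ps, ps[1:]))


class TestCorrelateAllPairs:
    @pytest.fixture()
    def toy_means(self):
        rng = np.random.default_rng(14)
        groups = [f"g{i}" for i in range(8)]
        lnc = L.GroupMeanMatrix(pd.DataFrame(rng.normal(size=(2, 8)),
                                             index=["l1", "l2"], columns=groups))
        mrna = L.GroupMeanMatrix(pd.DataFrame(rng.normal(size=(3, 8)),
                                              index=["m1", "m2", "m3"], columns=groups))
        return lnc, mrna

    def test_cardinality(self, toy_means):
        edges = L.correlate_all_pairs(*toy_means, n_perms=200, seed=0)
        assert len(edges) == 6
        assert not edges.duplicated(["lnc_id", "mrna_id"]).any()

    def test_iteration_order_does_not_change_results(self, toy_means):
        lnc, mrna = toy_means
        fwd = L.correlate_all_pairs(lnc, mrna, n_perms=500, seed=7)
        rev = L.correlate_all_pairs(
            L.GroupMeanMatrix(lnc.data.iloc[::-1]),
            L.GroupMeanMatrix(mrna.data.iloc[::-1]),
            n_perms=500,
            seed=7,
        )
        key = ["lnc_id", "mrna_id"]
        pd.testing.assert_frame_equal(
            fwd.sort_values(key).reset_index(drop=True),
            rev.sort_values(key).reset_index(drop=True),
        )

    def test_constant_probe_recorded_as_skip(self, toy_means):
        lnc, mrna = toy_means
        lnc.data.loc["l1"] = 3.0
        edges = L.correlate_all_pairs(lnc, mrna, n_perms=100, seed=0)
        skipped = edges[edges["skip_reason"] != ""]
        assert set(skipped["lnc_id"]) == {"l1"}
        assert (skipped["skip_reason"] == "constant_lncRNA").all()
        assert skipped["r"].isna().all()

    def test_group_label_mismatch_rejected(self, toy_means):
        lnc, mrna = toy_means
        bad = L.GroupMeanMatrix(mrna.data.rename(columns={"g0": "h0"}))
        with pytest.raises(L.ValidationError, match="group columns"):
            L.correlate_all_pairs(lnc, bad)

    def test_exhaustive_mode_matches_single_pair_calls(self, toy_means):
        lnc, mrna = toy_means
        edges = L.correlate_all_pairs(lnc, mrna, mode="exhaustive")
        for row in edges.itertuples(index=False):
            ref = L.exhaustive_permutation_pvalue(
                lnc.data.loc[row.lnc_id], mrna.data.loc[row.mrna_id]
            )
            assert row.p_perm == ref.p_perm
            assert row.r == pytest.approx(ref.r_observed, abs=1e-12)

    def test_planted_coupled_pair_is_significant(self, normalized_small, small_dataset):
        gm = L.group_means(normalized_small, small_dataset.samples)
        pair = small_dataset.truth.coupled_pairs.iloc[0]
        res = L.permutation_pvalue(
            gm.data.loc[pair["lnc_id"]], gm.data.loc[pair["mrna_id"]],
            n_perms=10_000, seed=3,
        )
        assert res.p_perm < 5e-3
        assert abs(res.r_observed) > 0.8
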