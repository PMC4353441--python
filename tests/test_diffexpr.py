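"""Pooled-variance t-test, fold-change gating, and DE summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import lnclink as L
from conftest import ir_contrast

finite_floats = st.floats(min_value=-100, max_value=100, allow_nan=False, width=32)
group = st.lists(finite_floats, min_size=2, max_size=6)


class TestStudentTTest:
    def test_identical_groups_give_t0_p1(self):
        res = L.student_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0 and not res.degenerate

    def test_zero_variance_unequal_means_flagged_degenerate(self):
        res = L.student_t_test([1, 1, 1], [2, 2, 2])
        assert res.degenerate and res.p == 0.0

    def test_hand_computed_textbook_oracle(self):
        # pooled s^2 = 0.04, se = sqrt(0.04*2/3), t = 1/se = sqrt(37.5), df = 4
        res = L.student_t_test([1.0, 1.2, 0.8], [2.0, 2.2, 1.8])
        assert res.t == pytest.approx(6.123724356957946, abs=1e-12)
        assert res.p == pytest.approx(0.003602232609104, abs=1e-12)

    def test_matches_scipy_pooled_ttest(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = rng.normal(size=4), rng.normal(size=5)
            res = L.student_t_test(a, b)
            ref = stats.ttest_ind(b, a, equal_var=True)
            assert res.t == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    @given(group, group)
    @settings(max_examples=50, deadline=None)
    def test_swapping_groups_negates_t_and_preserves_p(self, a, b):
        fwd = L.student_t_test(a, b)
        rev = L.student_t_test(b, a)
        assert fwd.t == pytest.approx(-rev.t, abs=1e-9)
        assert fwd.p == pytest.approx(rev.p, abs=1e-12)

    def test_groups_smaller_than_two_rejected(self):
        with pytest.raises(L.ValidationError):
            L.student_t_test([1.0], [1.0, 2.0])

    def test_null_pvalues_are_uniform(self):
        """KS test on 10^4 null t-test p-values is not rejected at 1%."""
        rng = np.random.default_rng(12)
        data = pd.DataFrame(rng.normal(0, 1, (10_000, 6)),
                            index=[f"p{i}" for i in range(10_000)],
                            columns=[f"s{j}" for j in range(6)])
        m = L.ExpressionMatrix(data, scale="log2")
        samples = L.SampleTable(pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(6)],
            "strain": "BALBc", "timepoint_weeks": 4,
            "treatment": ["sham"] * 3 + ["IR"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        }))
        de = L.differential_expression(m, samples, ir_contrast("BALBc", 4))
        assert stats.kstest(de["p_value"], "uniform").pvalue > 0.01


class TestFoldChange:
    @pytest.mark.parametrize(
        "mean_a,mean_b,fc,direction",
        [
            (2.0, 2.0, 1.0, "up"),  # tie -> "up" by convention, FC 1
            (1.0, 2.0, 2.0, "up"),
            (0.0, -np.log2(1.5), 1.5, "down"),
        ],
    )
    def test_definition(self, mean_a, mean_b, fc, direction):
        got_fc, got_dir = L.fold_change(mean_a, mean_b)
        assert got_fc == pytest.approx(fc, rel=1e-12)
        assert got_dir == direction

    def test_fc_always_at_least_one(self):
        rng = np.random.default_rng(0)
        for a, b in rng.normal(size=(50, 2)):
            assert L.fold_change(a, b)[0] >= 1.0


class TestDifferentialExpression:
    def test_boundary_fold_change_fails_strict_gate(self):
        # probe with exactly FC 1.5 between group means, tiny noise-free shift
        delta = np.log2(1.5)
        data = pd.DataFrame(
            [[0.0, 0.1, -0.1, delta, delta + 0.1, delta - 0.1],
             [0.0, 0.1, -0.1, 1.0, 1.1, 0.9]],
            index=pd.Index(["boundary", "clear"], name="probe_id"),
            columns=[f"s{j}" for j in range(6)],
        )
        m = L.ExpressionMatrix(data, scale="log2")
        samples = L.SampleTable(pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(6)],
            "strain": "BALBc", "timepoint_weeks": 4,
            "treatment": ["sham"] * 3 + ["IR"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        }))
        de = L.differential_expression(m, samples, ir_contrast("BALBc", 4))
        assert de.loc["boundary", "fold_change"] == pytest.approx(1.5, abs=1e-12)
        assert not de.loc["boundary", "passes_fc"]
        assert de.loc["clear", "passes_fc"]

    def test_combined_filter_never_exceeds_p_filter(self, normalized_small, small_dataset):
        de = L.differential_expression(normalized_small, small_dataset.samples,
                                       ir_contrast("BALBc", 4))
        assert de["is_de"].sum() <= de["passes_p"].sum()
        assert (de["is_de"] <= (de["passes_p"] & de["passes_fc"])).all()

    def test_requires_log2_scale(self, small_dataset):
        with pytest.raises(L.ValidationError, match="log2"):
            L.differential_expression(small_dataset.expression, small_dataset.samples,
                                      ir_contrast("BALBc", 4))

    def test_planted_probes_recovered_in_their_contrast(self, normalized_small, small_dataset):
        truth = small_dataset.truth.de_probes
        planted = truth[truth["contrast"] == "BALBc_4w_IR_vs_sham"]
        de = L.differential_expression(normalized_small, small_dataset.samples,
                                       ir_contrast("BALBc", 4))
        recovered = de.loc[planted["probe_id"], "is_de"]
        assert recovered.mean() >= 0.9
        # directions agree with the planted signs
        dirs = de.loc[planted["probe_id"], "direction"].to_numpy()
        assert (dirs == planted["direction"].to_numpy()).all()


class TestCountByClass:
    def test_empty_table_gives_zeros(self, small_dataset):
        de = pd.DataFrame(
            {"direction": [], "is_de": []},
            index=pd.Index([], name="probe_id"),
        )
        counts = L.count_by_class(de, small_dataset.annotation)
        assert counts.to_numpy().sum() == 0

    def test_toy_counts_and_conservation(self, small_dataset):
        ann = small_dataset.annotation
        lnc = ann.probes_of_class("lncRNA")[:2]
        mrna = ann.probes_of_class("mRNA")[:1]
        de = pd.DataFrame(
            {"direction": ["up", "up", "down"], "is_de": [True, True, True]},
            index=pd.Index(lnc + mrna, name="probe_id"),
        )
        counts = L.count_by_class(de, ann)
        assert counts.loc["lncRNA", "up"] == 2
        assert counts.loc["mRNA", "down"] == 1
        assert counts.to_numpy().sum() == de["is_de"].sum()

    def test_unannotated_probe_rejected(self, small_dataset):
        de = pd.DataFrame({"direction": ["up"], "is_de": [True]},
                          index=pd.Index(["nope"], name="probe_id"))
        with pytest.raises(L.ValidationError, match="missing from annotation"):
            L.count_by_class(de, small_dataset.annotation)


def test_de_union_is_union_of_flagged_probes():
    t1 = pd.DataFrame({"is_de": [True, False]}, index=["a", "b"])
    t2 = pd.DataFrame({"is_de": [True, True]}, index=["b", "c"])
    assert L.de_union({"x": t1, "y": t2}) == {"a", "b", "c"}
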