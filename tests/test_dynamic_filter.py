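"""Descriptive statistics, one-way ANOVA, BH step-up, and the filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mirchron.core_model import FilterThresholds, MIRNA_THRESHOLDS, MRNA_THRESHOLDS
from mirchron.dynamic_filter import (
    anova_timecourse,
    apply_dynamic_filter,
    fdr_stepup,
    feature_descriptive_stats,
    overlap_report,
)
from .conftest import make_matrix


def bh_oracle(p):
    """Textbook step-up: q_(i) = min_{j>=i} p_(j) m / j, in input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestDescriptiveStats:
    def test_extrema_over_timepoint_means(self, design):
        # per-timepoint means (7,8,9,8,7,7,7) -> Max 9, Min 7, Range 2, FC 4
        profile = np.repeat([7.0, 8, 9, 8, 7, 7, 7], 2)
        em = make_matrix([profile], design)
        s = feature_descriptive_stats(em)
        assert s.loc["f0", "max"] == 9 and s.loc["f0", "min"] == 7
        assert s.loc["f0", "range"] == 2 and s.loc["f0", "fold_change"] == 4

    def test_constant_profile(self, design):
        em = make_matrix([np.full(14, 5.0)], design)
        s = feature_descriptive_stats(em)
        assert s.loc["f0", "range"] == 0 and s.loc["f0", "fold_change"] == 1

    def test_replicates_averaged_before_extrema(self, design):
        # replicate pairs (6,8),(9,9),(5,5),... -> means (7,9,5,...) feed extrema
        row = np.array([6.0, 8, 9, 9, 5, 5, 7, 7, 7, 7, 7, 7, 7, 7])
        s = feature_descriptive_stats(make_matrix([row], design))
        assert s.loc["f0", "max"] == 9 and s.loc["f0", "min"] == 5


class TestAnova:
    def test_matches_scipy_oracle_on_random_matrices(self, design):
        rng = np.random.default_rng(42)
        vals = rng.normal(size=(50, 14))
        em = make_matrix(vals, design)
        res = anova_timecourse(em)
        assert (res["df_between"] == 6).all() and (res["df_within"] == 7).all()
        for i in range(50):
            groups = [vals[i, 2 * j : 2 * j + 2] for j in range(7)]
            f, p = sps.f_oneway(*groups)
            assert res["f_stat"].iloc[i] == pytest.approx(f, rel=1e-10)
            assert res["p"].iloc[i] == pytest.approx(p, rel=1e-10)

    def test_hand_oracle_three_groups(self):
        # groups {1,2},{2,3},{3,4}: SSB=4 (df 2), SSW=1.5 (df 3) -> F=4
        from mirchron.core_model import ExpressionMatrix, TimeCourseDesign

        design = TimeCourseDesign(
            rna_timepoints=("E12", "E14", "E16"),
            replicate_map={"a1": "E12", "a2": "E12", "b1": "E14", "b2": "E14",
                           "c1": "E16", "c2": "E16"},
        )
        vals = pd.DataFrame(
            [[1.0, 2, 2, 3, 3, 4]], index=["f"],
            columns=["a1", "a2", "b1", "b2", "c1", "c2"],
        )
        res = anova_timecourse(ExpressionMatrix("mRNA", vals, design))
        assert res.loc["f", "f_stat"] == pytest.approx(4.0)
        assert res.loc["f", "p"] == pytest.approx(0.14242717305466185, rel=1e-10)

    def test_perfect_separation_flagged(self, design):
        profile = np.repeat([0.0, 5, 0, 0, 0, 0, 0], 2)
        res = anova_timecourse(make_matrix([profile], design))
        assert res["degenerate"].iloc[0]
        assert 0 < res["p"].iloc[0] < 1e-300

    def test_all_identical_is_degenerate_p1(self, design):
        res = anova_timecourse(make_matrix([np.full(14, 3.0)], design))
        assert res["degenerate"].iloc[0] and res["p"].iloc[0] == 1.0


class TestFdrStepup:
    def test_single_p_identity(self):
        assert fdr_stepup([0.03]) == pytest.approx([0.03])

    def test_hand_enumerated_example(self):
        np.testing.assert_allclose(
            fdr_stepup([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_stepup([0.5, 1.2])
        with pytest.raises(ValueError):
            fdr_stepup([-0.1])

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_textbook_oracle(self, p):
        np.testing.assert_allclose(fdr_stepup(p), bh_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10))
    def test_preserves_significance_order(self, p):
        q = fdr_stepup(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFilter:
    def make_stats(self, **kw):
        base = {"max": 7.5, "min": 5.0, "range": 1.3, "fold_change": 2.5, "fdr_q": 0.01}
        base.update(kw)
        return pd.DataFrame([base], index=["f"])

    def test_mrna_pass_at_published_thresholds(self):
        passing, audit = apply_dynamic_filter(self.make_stats(), MRNA_THRESHOLDS)
        assert passing == ["f"] and audit.loc["f", "failed"] == ""

    def test_range_failure_audited(self):
        passing, audit = apply_dynamic_filter(self.make_stats(range=1.0), MRNA_THRESHOLDS)
        assert passing == [] and audit.loc["f", "failed"] == "range"

    def test_mirna_min_gate(self):
        # Min ΔCT 12 fails no matter how good Range and q are
        stats = self.make_stats(min=12.0, range=5.0, fdr_q=1e-6)
        passing, audit = apply_dynamic_filter(stats, MIRNA_THRESHOLDS)
        assert passing == [] and "extremum" in audit.loc["f", "failed"]

    def test_layer_mismatch_rejected(self):
        with pytest.raises(ValueError, match="layer"):
            apply_dynamic_filter(self.make_stats(), MRNA_THRESHOLDS, layer="miRNA")

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        stats = pd.DataFrame(
            {
                "max": rng.uniform(5, 10, 50), "min": rng.uniform(3, 8, 50),
                "range": rng.uniform(0, 3, 50), "fdr_q": rng.uniform(0, 0.2, 50),
            },
            index=[f"f{i}" for i in range(50)],
        )
        tight, _ = apply_dynamic_filter(stats, MRNA_THRESHOLDS)
        loose, _ = apply_dynamic_filter(
            stats, FilterThresholds("mRNA", "max_above", 6.0, 1.0, 0.1)
        )
        assert set(tight) <= set(loose)

    def test_global_null_fdr_calibration(self, design):
        # i.i.d. noise, no time effect: BH discoveries stay near/below 5%
        rng = np.random.default_rng(2024)
        n_mat, n_feat, disc, total = 40, 100, 0, 0
        from mirchron.dynamic_filter import anova_timecourse, fdr_stepup

        for _ in range(n_mat):
            em = make_matrix(rng.normal(size=(n_feat, 14)), design)
            q = fdr_stepup(anova_timecourse(em)["p"].to_numpy())
            disc += int((q < 0.05).sum())
            total += n_feat
        frac = disc / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert frac <= 0.05 + 3 * se


class TestOverlapReport:
    def test_percentages(self):
        rep = overlap_report(["a", "b", "c", "d"], ["b", "c", "d", "e"])
        assert rep["n_overlap"] == 3
        assert rep["percent_of_a"] == pytest.approx(75.0)
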