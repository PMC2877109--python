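"""Fraction merging, time-axis alignment, protein-layer target calls."""

import numpy as np
import pandas as pd
import pytest

from mirchron.core_model import (
    ExpressionMatrix,
    IdMap,
    PROTEIN_TIMEPOINTS,
    TargetPredictionTable,
    TimeCourseDesign,
)
from mirchron.protein_integration import (
    align_time_axes,
    merge_fractions,
    protein_correlation_targets,
    read_protein_table,
)
from .conftest import make_matrix


def long_table(rows):
    return pd.DataFrame(rows, columns=["protein_id", "fraction", "timepoint", "count"])


class TestMergeFractions:
    def test_sum_and_log2(self):
        t = long_table([
            ("P1", "nuclear", "E13.5", 2),
            ("P1", "mitochondrion", "E13.5", 3),
            ("P1", "cytosol", "E13.5", 5),
        ])
        em = merge_fractions(t)
        assert em.layer == "protein"
        assert em.values.loc["P1", "E13.5"] == pytest.approx(np.log2(11))

    def test_absent_everywhere_is_zero(self):
        t = long_table([("P1", "nuclear", "E13.5", 4)])
        em = merge_fractions(t)
        assert em.values.loc["P1", "E16"] == 0.0  # log2(0 + 1)

    def test_single_fraction_power_of_two(self):
        em = merge_fractions(long_table([("P1", "cytosol", "P2", 7)]))
        assert em.values.loc["P1", "P2"] == pytest.approx(3.0)

    def test_unknown_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            merge_fractions(long_table([("P1", "membrane", "E16", 1)]))

    def test_permutation_invariant_and_additive(self):
        rows = [("P1", f, "E18", c) for f, c in
                [("cytosol", 5), ("nuclear", 2), ("mitochondrion", 3)]]
        a = merge_fractions(long_table(rows))
        b = merge_fractions(long_table(rows[::-1]))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_mean_and_max_aggregates(self):
        t = long_table([
            ("P1", "nuclear", "E16", 6),
            ("P1", "cytosol", "E16", 12),
        ])
        # absent mitochondrion counts as 0 for every aggregate
        assert merge_fractions(t, aggregate="mean").values.loc["P1", "E16"] == pytest.approx(
            np.log2(6 + 1)
        )
        assert merge_fractions(t, aggregate="max").values.loc["P1", "E16"] == pytest.approx(
            np.log2(12 + 1)
        )

    def test_duplicate_rows_rejected(self):
        t = long_table([("P1", "nuclear", "E16", 1), ("P1", "nuclear", "E16", 2)])
        with pytest.raises(ValueError, match="duplicate"):
            merge_fractions(t)

    def test_read_roundtrip(self, tmp_path):
        t = long_table([("P1", "nuclear", "E13.5", 2), ("P2", "cytosol", "Adult", 9)])
        path = tmp_path / "prot.tsv"
        t.to_csv(path, sep="\t", index=False)
        pd.testing.assert_frame_equal(read_protein_table(path), t)


class TestAlignTimeAxes:
    def test_default_mapping(self, design):
        rna = make_matrix([np.arange(14.0)], design)
        prot_vals = pd.DataFrame(
            [np.arange(6.0)], index=["P1"], columns=list(PROTEIN_TIMEPOINTS)
        )
        pdesign = design.with_samples(
            dict(design.replicate_map) | {tp: tp for tp in PROTEIN_TIMEPOINTS}
        )
        prot = ExpressionMatrix("protein", prot_vals, pdesign)
        rna_a, prot_a = align_time_axes(prot, rna)
        assert list(rna_a.columns) == list(PROTEIN_TIMEPOINTS)
        assert list(prot_a.columns) == list(PROTEIN_TIMEPOINTS)
        # E12 (RNA mean 0.5) never appears; E14 pairs with E13.5
        assert rna_a.loc["f0", "E13.5"] == 2.5
        assert 0.5 not in rna_a.loc["f0"].to_numpy()

    def test_missing_mapped_timepoint_rejected(self, design):
        sub = {s: tp for s, tp in design.replicate_map.items() if tp != "P10"}
        rna = make_matrix([np.arange(14.0)], design)
        rna_sub = ExpressionMatrix(
            "mRNA", rna.values[[s for s in rna.values.columns if s in sub]],
            design.with_samples(sub),
        )
        pdesign = design.with_samples({tp: tp for tp in PROTEIN_TIMEPOINTS})
        prot = ExpressionMatrix(
            "protein",
            pd.DataFrame([np.arange(6.0)], index=["P1"], columns=list(PROTEIN_TIMEPOINTS)),
            pdesign,
        )
        with pytest.raises(ValueError, match="P10"):
            align_time_axes(prot, rna_sub)


class TestProteinTargets:
    def build(self, design, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        mirna_profile = np.array([0.0, 1, 2, 3, 4, 5, 6])
        mirna = make_matrix([np.repeat(mirna_profile, 2)], design,
                            layer="miRNA", features=["miR-a"])
        # protein = negation of the miRNA profile on the mapped six points
        mapped = mirna_profile[[1, 2, 3, 4, 5, 6]]
        counts = 2.0 ** (10 - mapped)
        rows = []
        for tp, c in zip(PROTEIN_TIMEPOINTS, counts):
            noisy = max(0, c + rng.normal(0, noise * c))
            rows.append(("prot_P1", "cytosol", tp, int(round(noisy))))
        table = long_table(rows)
        pdesign = design.with_samples(
            dict(design.replicate_map) | {tp: tp for tp in PROTEIN_TIMEPOINTS}
        )
        prot = merge_fractions(table, design=pdesign, pseudocount=1.0)
        return mirna, prot

    def test_exact_negation_is_direct_if_predicted(self, design):
        mirna, prot = self.build(design)
        pairs = protein_correlation_targets(
            mirna, prot, cutoff=0.8,
            predictions=TargetPredictionTable({("miR-a", "tx_G1")}),
            prediction_idmap=IdMap([("tx_G1", "probe_G1")]),
            protein_idmap=IdMap([("prot_P1", "probe_G1")]),
        )
        assert (pairs["n"] == 6).all()
        row = pairs.iloc[0]
        assert row["direction"] == "negative" and row["direct"]
        assert row["r"] < -0.99

    def test_threshold_ordering(self, design):
        mirna, prot = self.build(design, noise=0.35, seed=5)
        loose = protein_correlation_targets(mirna, prot, cutoff=0.8)
        tight = protein_correlation_targets(mirna, prot, cutoff=0.9)
        r = None
        if len(loose):
            r = loose["r"].iloc[0]
        # any pair admitted at 0.9 must be admitted at 0.8
        assert len(tight) <= len(loose)
        if r is not None and -0.9 < r < -0.8:
            assert len(tight) == 0

    def test_translational_edges_recovered(self, design):
        # planted mode-B edges: flat mRNA, anti-correlated protein
        from mirchron.synthetic_data import SimParams, generate
        from mirchron import qpcr_preprocess as q

        bundle = generate(SimParams(noise_sd_rna=0.1, noise_sd_ct=0.1), seed=3)
        dct = q.delta_ct(q.censor_ct(bundle.ct), design=bundle.design)
        expr = q.dct_to_log2_expression(dct)
        pem = merge_fractions(bundle.protein_table, design=bundle.design)
        pairs = protein_correlation_targets(
            expr, pem, cutoff=0.8, predictions=bundle.predictions,
            prediction_idmap=bundle.tx_to_probe, protein_idmap=bundle.protein_to_probe,
        )
        direct = set(zip(pairs.loc[pairs.direct, "mirna"],
                         [t.replace("prot_", "") for t in pairs.loc[pairs.direct, "target"]]))
        planted_b = bundle.truth.edges_of_mode("B_translational")
        recovered = len(planted_b & direct) / len(planted_b)
        assert recovered >= 0.9
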