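"""Cold-induction calls, reduction arithmetic, regulon membership, binning."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cbfreg.classify import (
    COLD_EXPRESSION_RATIO,
    INDUCTION_RATIO,
    bin_reductions,
    call_cold_induced,
    call_regulon_membership,
    classify_table,
    reduction_percent,
    summarize_first_wave,
)
from cbfreg.simulate import SimulationConfig, generate_expression_tables


class TestColdInduced:
    @pytest.mark.parametrize("fc,q,expected", [
        (1.5, 0.001, True),
        (0.9, 1e-6, False),   # fold-change boundary
        (1.0, 0.01, True),    # thresholds inclusive
        (3.0, 0.02, False),   # FDR fails
    ])
    def test_threshold_logic(self, fc, q, expected):
        assert call_cold_induced(fc, q) is expected

    def test_missing_q_requires_override(self):
        with pytest.raises(ValueError, match="allow_missing_q"):
            call_cold_induced(2.0, float("nan"))
        assert call_cold_induced(2.0, float("nan"), allow_missing_q=True)

    @given(
        fc=st.floats(-3, 6), q=st.floats(0, 1),
        stricter_fc=st.floats(1, 3), looser_q=st.floats(0.01, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_threshold_monotonicity(self, fc, q, stricter_fc, looser_q):
        # raising the fold-change bar or lowering the FDR cutoff never adds genes
        strict = call_cold_induced(fc, q, stricter_fc, 0.01)
        loose = call_cold_induced(fc, q, 1.0, looser_q)
        if strict:
            assert call_cold_induced(fc, q, 1.0, 0.01)
        if call_cold_induced(fc, q, 1.0, 0.01):
            assert loose


class TestReductionPercent:
    def test_eightfold_vs_twofold(self):
        assert reduction_percent(8.0, 1.0, 2.0, 1.0) == pytest.approx(75.0)

    def test_mutant_identical_to_wt(self):
        assert reduction_percent(6.0, 2.0, 6.0, 2.0) == pytest.approx(0.0)

    def test_cold_expression_version(self):
        assert reduction_percent(10.0, 1.0, 4.0, 1.0,
                                 version=COLD_EXPRESSION_RATIO) == pytest.approx(60.0)

    def test_versions_agree_when_warm_baseline_shared(self):
        a = reduction_percent(8.0, 2.0, 2.0, 2.0, INDUCTION_RATIO)
        b = reduction_percent(8.0, 2.0, 2.0, 2.0, COLD_EXPRESSION_RATIO)
        assert a == pytest.approx(b)

    def test_zero_abundance_names_gene(self):
        with pytest.raises(ValueError, match="AT1G09350"):
            reduction_percent(8.0, 0.0, 2.0, 1.0, gene_id="AT1G09350")


class TestMembership:
    def test_both_criteria_met(self):
        call = call_regulon_membership("g", "SW", 2.0, 1e-4, 1.2, 1e-3)
        assert call.regulon_member and call.cold_induced

    def test_insufficient_downregulation(self):
        call = call_regulon_membership("g", "SW", 2.0, 1e-4, 0.5, 1e-3)
        assert call.cold_induced and not call.regulon_member

    def test_member_implies_induced_enforced(self):
        from cbfreg.classify import RegulonCall
        with pytest.raises(ValueError, match="member"):
            RegulonCall("g", "SW", cold_induced=False, reduction_pct=80.0,
                        regulon_member=True)

    def test_per_genotype_fdr(self):
        # Col-0-style definition relaxes the mutant-contrast FDR to 0.05
        strict = call_regulon_membership("g", "SW", 2.0, 1e-4, 1.5, 0.03)
        relaxed = call_regulon_membership("g", "Col-0", 2.0, 1e-4, 1.5, 0.03,
                                          mut_q_threshold=0.05)
        assert not strict.regulon_member
        assert relaxed.regulon_member


class TestPlantedRecovery:
    def test_planted_cbf_dependent_recovered_exactly(self):
        # 100 strongly reduced genes among 2000: membership recovers them all
        cfg = SimulationConfig(
            seed=123, n_genes=2000,
            class_fractions={"cbf_dependent": 0.05, "coregulated": 0.0,
                             "cbf_independent_cor": 0.0, "non_cor": 0.95},
            mutant_reduction_range={
                "cbf_dependent": (0.75, 0.95), "coregulated": (0.3, 0.45),
                "cbf_independent_cor": (-0.1, 0.1), "non_cor": (-0.1, 0.1)},
        )
        tabs = generate_expression_tables(cfg)
        calls = classify_table(tabs.de, "SW")
        truth = tabs.truth[tabs.truth.genotype == "SW"]
        planted = set(truth[truth.gene_class == "cbf_dependent"].gene_id)
        called = set(calls[calls.regulon_member].gene_id)
        assert len(planted) == 100
        assert called == planted

    def test_degenerate_all_non_cor(self):
        cfg = SimulationConfig(
            seed=5, n_genes=300,
            class_fractions={"cbf_dependent": 0.0, "coregulated": 0.0,
                             "cbf_independent_cor": 0.0, "non_cor": 1.0})
        tabs = generate_expression_tables(cfg)
        calls = classify_table(tabs.de, "SW")
        assert not calls.cold_induced.any()
        assert not calls.regulon_member.any()

    def test_membership_subset_of_induced(self, expression):
        calls = classify_table(expression.de, "IT")
        assert (calls.regulon_member <= calls.cold_induced).all()


class TestBinReductions:
    def test_hand_example(self):
        h = bin_reductions([75, 75, 25, -5])
        assert h.over50_count == 2
        assert h.over50_fraction == pytest.approx(0.5)
        assert h.counts[0] == 1  # (-inf, 0) bin
        assert sum(h.counts) == 4

    def test_empty_input(self):
        h = bin_reductions([])
        assert sum(h.counts) == 0
        assert h.over50_count == 0 and h.over50_fraction == 0.0

    def test_conservation(self, expression):
        calls = classify_table(expression.de, "SW")
        reds = calls.loc[calls.cold_induced, "reduction_pct"]
        h = bin_reductions(reds)
        assert sum(h.counts) == int(calls.cold_induced.sum())

    def test_boundary_membership(self):
        h = bin_reductions([0.0, 10.0, 50.0, 90.0, 100.0])
        labels = dict(zip(h.bin_labels, h.counts))
        assert labels["[0,10)"] == 1
        assert labels["[90,100]"] == 2  # 90 and 100 share the closed top bin
        assert h.over50_count == 2  # 50 itself is not "> 50%"

    def test_over_100_rejected(self):
        with pytest.raises(ValueError, match="100"):
            bin_reductions([101.0])


class TestFirstWave:
    def test_matrix_shape_and_missing_flag(self, expression):
        panel = ["G00000", "G00001", "NOT_A_GENE"]
        mat = summarize_first_wave(panel, expression.de)
        assert mat.shape == (3, 2)  # 3 panel genes x 2 genotypes
        assert mat.loc["NOT_A_GENE"].isna().all()
        assert ("NOT_A_GENE", "SW") in mat.attrs["missing"]

    def test_all_zero_table(self):
        de = pd.DataFrame(dict(
            genotype=["SW", "SW"], contrast=["warm_vs_cold24h"] * 2,
            gene_id=["a", "b"], log2fc=[0.0, 0.0], q_value=[1.0, 1.0],
            fpkm_ref=[1, 1], fpkm_alt=[1, 1]))
        mat = summarize_first_wave(["a", "b"], de)
        assert (mat.to_numpy() == 0).all()
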