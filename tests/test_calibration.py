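"""Overlap annotation, contingency scenarios, odds ratios, and the evidence scale."""

import math

import numpy as np
import pytest

from duality import (
    ClassLabel,
    ContingencyTable,
    EvidenceScale,
    Scenario,
    annotate_overlap,
    bin_insilico_scores,
    build_contingency,
    build_contingency_from_counts,
    evidence_strength,
    odds_ratio,
    positive_likelihood_ratio,
)
from duality.variants import GenomicVariant, GermlineRecord, HotspotMutation, ProteinChange

from conftest import make_germline, make_hotspot, records_from_counts

# class composition of the overlap analysis: overlapping variants per class
# and class totals of the full germline set
OVERLAP = {ClassLabel.LP_P: 426, ClassLabel.VUS: 261, ClassLabel.LB_B: 4}
TOTALS = {ClassLabel.LP_P: 3149, ClassLabel.VUS: 45442, ClassLabel.LB_B: 2755}


class TestAnnotateOverlap:
    def test_nucleotide_match_copies_counts(self):
        hs = make_hotspot(0)
        rec = make_germline(0, ClassLabel.LP_P)
        (out,) = annotate_overlap([rec], [hs], mode="nucleotide")
        assert out.overlaps_hotspot is True
        assert (out.tumor_count_change, out.tumor_count_residue) == (5, 9)

    def test_nucleotide_requires_exact_allele(self):
        hs = make_hotspot(0)
        other = GermlineRecord(
            variant=GenomicVariant(hs.variant.chrom, hs.variant.pos, "A", "T"),
            change=hs.change,
            label=ClassLabel.LP_P,
        )
        (out,) = annotate_overlap([other], [hs], mode="nucleotide")
        assert out.overlaps_hotspot is False and out.tumor_count_change == 0

    def test_residue_change_mode_groups_nucleotide_variants(self):
        hs = make_hotspot(0, gene="KRAS")
        # a different SNV encoding the same amino-acid change
        sibling = GermlineRecord(
            variant=GenomicVariant("5", 999, "C", "T"),
            change=hs.change,
            label=ClassLabel.VUS,
        )
        by_nt = annotate_overlap([sibling], [hs], mode="nucleotide")
        by_aa = annotate_overlap([sibling], [hs], mode="residue_change")
        assert by_nt[0].overlaps_hotspot is False
        assert by_aa[0].overlaps_hotspot is True

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            annotate_overlap([], [], mode="codon")


class TestBuildContingency:
    def test_classification_scenario_counts(self):
        t = build_contingency_from_counts(OVERLAP, TOTALS, Scenario.LPP_vs_LBB)
        assert t.cells == (426, 4, 2723, 2751)

    def test_vus_folded_scenario_counts(self):
        t = build_contingency_from_counts(OVERLAP, TOTALS, Scenario.VUS_as_benign)
        assert t.cells == (426, 265, 2723, 47932)
        assert t.cells[2] + t.cells[3] == 50655  # "all other" germline variants

    def test_record_and_count_paths_agree(self):
        overlap = {ClassLabel.LP_P: 12, ClassLabel.VUS: 7, ClassLabel.LB_B: 1}
        totals = {ClassLabel.LP_P: 60, ClassLabel.VUS: 200, ClassLabel.LB_B: 40,
                  ClassLabel.CIP: 25}
        records = records_from_counts(overlap, totals)
        for scenario in (
            Scenario.LPP_vs_LBB,
            Scenario.VUS_as_benign,
            Scenario.VUS_and_CIP_as_benign,
        ):
            assert (
                build_contingency(records, scenario).cells
                == build_contingency_from_counts(overlap, totals, scenario).cells
            )

    def test_scenarios_nested_comparator_never_shrinks(self):
        overlap = {ClassLabel.LP_P: 5, ClassLabel.VUS: 3, ClassLabel.LB_B: 2,
                   ClassLabel.CIP: 1}
        totals = {ClassLabel.LP_P: 30, ClassLabel.VUS: 100, ClassLabel.LB_B: 20,
                  ClassLabel.CIP: 10}
        records = records_from_counts(overlap, totals)
        sizes = [
            sum(build_contingency(records, s).cells[i] for i in (1, 3))
            for s in (Scenario.LPP_vs_LBB, Scenario.VUS_as_benign,
                      Scenario.VUS_and_CIP_as_benign)
        ]
        assert sizes == sorted(sizes)

    def test_cells_partition_eligible_records(self):
        overlap = {ClassLabel.LP_P: 4, ClassLabel.VUS: 2}
        totals = {ClassLabel.LP_P: 10, ClassLabel.VUS: 50, ClassLabel.LB_B: 5,
                  ClassLabel.OTHER: 7}
        records = records_from_counts(overlap, totals)
        t = build_contingency(records, Scenario.VUS_as_benign)
        assert t.n == 10 + 50 + 5  # OTHER records are ineligible

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            build_contingency([], Scenario.LPP_vs_LBB)

    def test_gene_subset_scenario(self):
        recs = [
            make_germline(0, ClassLabel.LP_P, overlap=True, gene="CONC"),
            make_germline(1, ClassLabel.LP_P, overlap=False, gene="CONC"),
            make_germline(2, ClassLabel.VUS, overlap=False, gene="CONC"),
            make_germline(3, ClassLabel.LP_P, overlap=True, gene="DISC"),
            make_germline(4, ClassLabel.VUS, overlap=False, gene="DISC"),
        ]
        t = build_contingency(recs, Scenario.gene_subset, genes=["CONC"])
        assert t.cells == (1, 0, 1, 1)
        with pytest.raises(ValueError):
            build_contingency(recs, Scenario.gene_subset)

    def test_unannotated_records_rejected(self):
        with pytest.raises(ValueError, match="annotated"):
            build_contingency([make_germline(0, ClassLabel.LP_P)], Scenario.LPP_vs_LBB)


class TestOddsRatio:
    def test_classification_scenario_estimate(self):
        est = odds_ratio(ContingencyTable(426, 4, 2723, 2751, Scenario.LPP_vs_LBB))
        assert est.odds_ratio == pytest.approx(107.6, abs=0.05)
        assert est.ci_low == pytest.approx(40.1, abs=0.05)
        assert est.ci_high == pytest.approx(288.4, abs=0.05)
        assert est.p_value < 1e-4 and not est.correction_applied

    def test_symmetric_table_is_null(self):
        est = odds_ratio(ContingencyTable(10, 10, 10, 10, Scenario.LPP_vs_LBB))
        assert est.odds_ratio == 1.0
        assert est.ci_low < 1.0 < est.ci_high

    def test_haldane_correction_on_zero_cell(self):
        est = odds_ratio(ContingencyTable(5, 0, 5, 5, Scenario.LPP_vs_LBB))
        # (5.5 * 5.5) / (0.5 * 5.5)
        assert est.odds_ratio == pytest.approx(11.0)
        assert est.correction_applied

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError):
            odds_ratio(ContingencyTable(0, 0, 5, 5, Scenario.LPP_vs_LBB))

    def test_ci_widens_with_confidence(self):
        t = ContingencyTable(20, 10, 15, 30, Scenario.LPP_vs_LBB)
        widths = [
            math.log(odds_ratio(t, alpha=a).ci_high / odds_ratio(t, alpha=a).ci_low)
            for a in (0.10, 0.05, 0.01)
        ]
        assert widths == sorted(widths)

    def test_fisher_and_chi2_agree_on_significance(self):
        t = ContingencyTable(426, 4, 2723, 2751, Scenario.LPP_vs_LBB)
        assert odds_ratio(t, method="fisher").p_value < 1e-4

    def test_brute_force_cross_product(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a, b, c, d = rng.integers(1, 200, size=4)
            est = odds_ratio(ContingencyTable(int(a), int(b), int(c), int(d),
                                              Scenario.LPP_vs_LBB))
            assert est.odds_ratio == pytest.approx((a * d) / (b * c))
            assert est.ci_low <= est.odds_ratio <= est.ci_high


class TestPositiveLikelihoodRatio:
    def test_vus_folded_scenario_value(self):
        t = ContingencyTable(426, 265, 2723, 47932, Scenario.VUS_as_benign)
        # (426/3149) / (265/48197)
        assert positive_likelihood_ratio(t) == pytest.approx(24.6, abs=0.05)

    def test_simple_ratio(self):
        assert positive_likelihood_ratio(
            ContingencyTable(1, 1, 1, 3, Scenario.LPP_vs_LBB)
        ) == pytest.approx(2.0)

    def test_zero_sensitivity(self):
        assert positive_likelihood_ratio(
            ContingencyTable(0, 5, 9, 5, Scenario.LPP_vs_LBB)
        ) == 0.0

    def test_no_comparator_overlap_is_infinite(self):
        assert math.isinf(
            positive_likelihood_ratio(ContingencyTable(3, 0, 7, 10, Scenario.LPP_vs_LBB))
        )


class TestEvidenceScale:
    def test_original_calibration_moderate_threshold(self):
        assert EvidenceScale(350).moderate == pytest.approx(4.33, abs=0.005)

    def test_computational_calibration_thresholds(self):
        scale = EvidenceScale(1124)
        assert scale.moderate == pytest.approx(5.79, abs=0.005)
        assert scale.supporting == pytest.approx(1124 ** 0.125)

    @pytest.mark.parametrize("odds", [2.0, 350.0, 1124.0, 10000.0])
    def test_band_thresholds_strictly_increase(self, odds):
        scale = EvidenceScale(odds)
        thresholds = [scale.supporting, scale.moderate, scale.strong, scale.very_strong]
        assert thresholds == sorted(thresholds) and len(set(thresholds)) == 4
        for points, value in zip((1, 2, 4, 8), thresholds):
            assert value == pytest.approx(odds ** (points / 8))

    @pytest.mark.parametrize(
        "lr,band",
        [
            (1.0, "none"),
            (2.0, "none"),  # below supporting = 350^(1/8) ~ 2.08
            (2.1, "supporting"),
            (4.4, "moderate"),
            (18.3, "moderate"),  # below strong = 350^0.5 ~ 18.71
            (18.8, "strong"),
            (351.0, "very_strong"),
        ],
    )
    def test_band_assignment_original_scale(self, lr, band):
        assert evidence_strength(lr, EvidenceScale(350)) == band

    def test_nonpositive_lr_rejected(self):
        with pytest.raises(ValueError):
            evidence_strength(0.0)


class TestScoreBinning:
    def test_boundary_scores(self):
        counts = bin_insilico_scores([0.29, 0.290001, 0.5, 0.644, 0.9, None])
        assert counts == {"pp3": 2, "indeterminate": 2, "bp4": 1, "missing": 1}

    def test_revel_at_cutoff_is_benign_supporting(self):
        assert bin_insilico_scores([0.29])["bp4"] == 1

    def test_mid_score_indeterminate(self):
        assert bin_insilico_scores([0.5])["indeterminate"] == 1

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            bin_insilico_scores([0.5], thresholds={"pp3": 0.2, "bp4": 0.4})

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(1)
        scores = rng.random(200).tolist() + [None] * 5
        counts = bin_insilico_scores(scores)
        brute = {
            "pp3": sum(1 for s in scores if s is not None and s >= 0.644),
            "bp4": sum(1 for s in scores if s is not None and s <= 0.290),
            "missing": 5,
        }
        brute["indeterminate"] = len(scores) - sum(brute.values())
        assert counts == brute
        assert sum(counts.values()) == len(scores)
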