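"""Feature extraction and the diagnostic rule engine."""

import pytest

from cnaprofiler.classifier import (
    ClassifierConfig,
    NO_SUPPORT_LABEL,
    UNCLASSIFIED_LABEL,
    ProfileFeatures,
    classify,
    classify_profile,
    extract_features,
)
from cnaprofiler.segio import AUTOSOMES, ConfigurationError, filter_segments
from conftest import make_profile


def features(**overrides) -> ProfileFeatures:
    """A quiet near-diploid feature set, overridable per test."""
    base = dict(
        sample_id="s",
        ploidy_baseline=2,
        n_structural=0,
        n_numerical=0,
        total_cna=0,
        n_chrom_structural=0,
        n_chrom_aberrant=0,
        genome_wide_changes=False,
        amplicons=(),
        genes_amplified=frozenset(),
        genes_deleted=frozenset(),
        genes_loh=frozenset(),
        loh_genome_fraction=0.0,
        retained_het_chroms=frozenset(AUTOSOMES),
        arms_lost=frozenset(),
    )
    base.update(overrides)
    if "total_cna" not in overrides:
        base["total_cna"] = base["n_structural"] + base["n_numerical"]
    return ProfileFeatures(**base)


class TestExtractFeatures:
    def test_high_level_amplicon_reports_spanned_genes(self, genome, loci):
        p = make_profile(genome, [("12", 57_000_000, 70_000_000, 8)])
        f = extract_features(p, loci=loci)
        assert {"MDM2", "CDK4"} <= set(f.genes_amplified)
        assert f.amplicons and f.amplicons[0][2] == 8

    def test_gain_below_amplification_threshold_is_not_amplicon(self, genome, loci):
        p = make_profile(genome, [("12", 57_000_000, 70_000_000, 4)])
        f = extract_features(p, loci=loci)
        assert f.amplicons == () and f.genes_amplified == frozenset()

    def test_near_whole_chromosome_gain_counts_numerical(self, genome, loci):
        length = genome["20"]
        p = make_profile(genome, [("20", 0, int(0.96 * length), 3)])
        f = extract_features(p, loci=loci)
        assert (f.n_numerical, f.n_structural) == (1, 0)
        p2 = make_profile(genome, [("20", 0, int(0.5 * length), 3)])
        f2 = extract_features(p2, loci=loci)
        assert (f2.n_numerical, f2.n_structural) == (0, 1)

    def test_genome_wide_loh_sparing_5_and_22(self, genome, loci):
        rows = [
            (c, 0, genome[c], 2, True) for c in AUTOSOMES if c not in ("5", "22")
        ]
        p = make_profile(genome, rows)
        f = extract_features(p, loci=loci)
        expected = 1 - (genome["5"] + genome["22"]) / genome.autosomal_length
        assert f.loh_genome_fraction == pytest.approx(expected, abs=1e-12)
        assert {"5", "22"} <= set(f.retained_het_chroms)
        assert "1" not in f.retained_het_chroms

    def test_gene_deletion_and_loh_flags(self, genome, loci):
        p = make_profile(genome, [
            ("17", 7_000_000, 8_000_000, 1),          # spans TP53
            ("9", 21_000_000, 22_500_000, 2, True),    # cnLOH over CDKN2A
        ])
        f = extract_features(p, loci=loci)
        assert "TP53" in f.genes_deleted
        assert "CDKN2A" in f.genes_loh and "CDKN2A" not in f.genes_deleted

    def test_arm_losses_assigned_by_centromere(self, genome, loci):
        p = make_profile(genome, [
            ("1", 3_000_000, 30_000_000, 1),            # 1p
            ("14", 20_000_000, 100_000_000, 1),         # 14q (acrocentric)
        ])
        f = extract_features(p, loci=loci)
        assert {"1p", "14q"} <= set(f.arms_lost)
        assert "1q" not in f.arms_lost

    def test_missing_locus_table_rejected(self, genome):
        p = make_profile(genome, [("1", 0, 1_000_000, 3)])
        with pytest.raises(ConfigurationError):
            extract_features(p, loci=None)


class TestRules:
    def test_complex_aneuploid_profile_indicates_mfs_ups(self):
        f = features(ploidy_baseline=3, n_structural=60, n_chrom_structural=15,
                     n_chrom_aberrant=15, genome_wide_changes=True)
        res = classify(f, context="soft_tissue")
        assert res.top.label == "MFS/UPS" and res.top.tier == "specific"

    def test_mdm2_cdk4_amplicon_without_jun_is_wdls_not_ddls(self):
        f = features(
            n_structural=3, n_chrom_structural=1, n_chrom_aberrant=1,
            amplicons=(("12", (69_000_000, 70_000_000), 12),),
            genes_amplified=frozenset({"MDM2", "CDK4"}),
        )
        res = classify(f, context="soft_tissue")
        assert res.top.label == "ALT/WDLS"
        assert all(i.label != "DDLS" for i in res.indications)

    def test_jun_amplification_upgrades_to_ddls(self):
        f = features(
            n_structural=3, n_chrom_structural=2, n_chrom_aberrant=2,
            amplicons=(("12", (69_000_000, 70_000_000), 12),),
            genes_amplified=frozenset({"MDM2", "CDK4", "JUN"}),
        )
        res = classify(f, context="soft_tissue")
        assert res.top.label == "DDLS"
        assert all(i.label != "ALT/WDLS" for i in res.indications)

    def test_genome_wide_changes_also_upgrade_to_ddls(self):
        f = features(
            n_structural=30, n_chrom_structural=10, n_chrom_aberrant=14,
            genome_wide_changes=True,
            amplicons=(("12", (69_000_000, 70_000_000), 12),),
            genes_amplified=frozenset({"MDM2", "CDK4"}),
        )
        assert classify(f, context="soft_tissue").top.label == "DDLS"

    def test_mdm2_amplicon_context_dependence(self):
        f = features(
            n_structural=2, n_chrom_structural=1, n_chrom_aberrant=1,
            amplicons=(("12", (69_000_000, 70_000_000), 12),),
            genes_amplified=frozenset({"MDM2"}),
        )
        assert classify(f, "soft_tissue").top.label == "ALT/WDLS"
        assert classify(f, "bone_surface").top.label == "parosteal osteosarcoma"
        assert classify(f, "bone").top.label == "ALT or parosteal osteosarcoma"

    def test_haploidization_with_retained_5_and_22_is_ilms(self):
        f = features(
            n_numerical=17, n_chrom_aberrant=17, genome_wide_changes=True,
            loh_genome_fraction=0.85,
            retained_het_chroms=frozenset({"5", "18", "20", "21", "22"}),
        )
        assert classify(f, "soft_tissue").top.label == "ILMS"

    def test_haploidization_without_retained_22_is_not_ilms(self):
        f = features(
            n_numerical=20, n_chrom_aberrant=20, genome_wide_changes=True,
            loh_genome_fraction=0.9,
            retained_het_chroms=frozenset({"5"}),
        )
        assert all(i.label != "ILMS" for i in classify(f, "soft_tissue").indications)

    def test_bone_lesion_thresholds_for_osteosarcoma(self):
        f = features(ploidy_baseline=3, n_structural=35, n_chrom_structural=8,
                     n_chrom_aberrant=8)
        assert classify(f, "bone").top.label == "high-grade osteosarcoma"
        # same profile in soft tissue matches no specific rule
        res = classify(f, "soft_tissue")
        assert all(i.tier != "specific" for i in res.indications)

    def test_lms_requires_gene_evidence(self):
        base = dict(ploidy_baseline=2, n_structural=40, n_chrom_structural=14,
                    n_chrom_aberrant=14, genome_wide_changes=True)
        without = classify(features(**base), "soft_tissue")
        assert all(i.label != "LMS" for i in without.indications)
        with_myocd = classify(
            features(**base, genes_amplified=frozenset({"MYOCD"}),
                     amplicons=(("17", (12_600_000, 12_700_000), 6),)),
            "soft_tissue",
        )
        assert any(i.label == "LMS" for i in with_myocd.indications)
        with_tp53 = classify(
            features(**base, genes_deleted=frozenset({"TP53"})), "soft_tissue"
        )
        assert any(i.label == "LMS" for i in with_tp53.indications)

    def test_gist_requires_intraabdominal_context(self):
        f = features(n_structural=3, n_chrom_structural=3, n_chrom_aberrant=3,
                     arms_lost=frozenset({"1p", "14q", "22q"}))
        assert classify(f, "intraabdominal").top.label == "GIST"
        assert all(
            i.label != "GIST" for i in classify(f, "soft_tissue").indications
        )

    def test_gist_needs_1p_plus_14q_or_22q(self):
        only_1p = features(n_structural=1, n_chrom_structural=1, n_chrom_aberrant=1,
                           arms_lost=frozenset({"1p"}))
        assert all(
            i.label != "GIST" for i in classify(only_1p, "intraabdominal").indications
        )

    def test_aneuploid_mostly_numerical_bone_lesion_is_chondrosarcoma(self):
        f = features(ploidy_baseline=3, n_numerical=8, n_structural=2,
                     n_chrom_structural=2, n_chrom_aberrant=9)
        assert classify(f, "bone").top.label == "chondrosarcoma"

    def test_broad_tiers_fire_only_without_specific_indication(self):
        hgs = features(n_structural=25, n_chrom_structural=8, n_chrom_aberrant=8)
        res = classify(hgs, "soft_tissue")
        assert res.top.label == "high-grade sarcoma NOS" and res.top.tier == "broad"
        sarcoma = features(n_structural=10, n_chrom_structural=5, n_chrom_aberrant=5)
        assert classify(sarcoma, "soft_tissue").top.label == "sarcoma NOS"
        neoplasia = features(n_structural=2, n_chrom_structural=2, n_chrom_aberrant=2)
        assert classify(neoplasia, "soft_tissue").top.label == "neoplasia NOS"

    def test_trisomy_plus_deletion_is_neoplasia_nos(self, genome, loci):
        # a whole-chromosome gain and one focal deletion as the sole changes
        p = make_profile(genome, [
            ("2", 0, genome["2"], 3),
            ("10", 88_000_000, 95_000_000, 1),
        ], context="soft_tissue")
        res = classify_profile(filter_segments(p), loci=loci)
        assert res.top.label == "neoplasia NOS"

    def test_empty_profile_reports_no_support_with_caveats(self):
        res = classify(features(), context="unknown", profile_empty=True)
        assert res.profile_normal
        assert [i.label for i in res.indications] == [NO_SUPPORT_LABEL]
        assert any("nonrepresentative" in e for e in res.top.evidence)

    def test_profile_matching_no_rule_is_unclassified(self):
        # aneuploid but quiet: no rule covers it
        f = features(ploidy_baseline=3, n_structural=2, n_chrom_structural=2,
                     n_chrom_aberrant=2)
        res = classify(f, "soft_tissue")
        assert res.top.label == UNCLASSIFIED_LABEL and res.top.tier == "none"

    def test_specific_indications_precede_broad_and_are_co_reported(self):
        # complex bone lesion: MFS/UPS and osteosarcoma rules both fire
        f = features(ploidy_baseline=3, n_structural=60, n_chrom_structural=15,
                     n_chrom_aberrant=15, genome_wide_changes=True)
        res = classify(f, "bone")
        labels = [i.label for i in res.indications]
        assert "MFS/UPS" in labels and "high-grade osteosarcoma" in labels
        assert all(i.tier == "specific" for i in res.indications)

    def test_determinism(self):
        f = features(ploidy_baseline=3, n_structural=60, n_chrom_structural=15,
                     n_chrom_aberrant=15)
        assert classify(f, "soft_tissue") == classify(f, "soft_tissue")

    def test_thresholds_configurable(self):
        f = features(ploidy_baseline=3, n_structural=45, n_chrom_structural=15,
                     n_chrom_aberrant=15)
        assert classify(f, "soft_tissue").top.label != "MFS/UPS"
        lax = ClassifierConfig(complex_structural_gt=40)
        assert classify(f, "soft_tissue", config=lax).top.label == "MFS/UPS"
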