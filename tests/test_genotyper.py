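"""Phasing, allele matching, SV integration, and diplotype rendering."""

import numpy as np
import pytest

from pgxstar import simdata, svcall
from pgxstar.covdepth import AlleleFractionProfile
from pgxstar.catalog import VariantKey
from pgxstar.errors import GenotypeError
from pgxstar.genotyper import (
    DiplotypeCall,
    Haplotype,
    assign_diplotype,
    match_alleles,
    order_alleles,
    phase_variants,
    render_diplotype,
)
from pgxstar.svcall import SVCall


V80 = "2-234667800-C-T"
V28 = "2-234668879-C-CAT"
V6 = "2-234669500-G-A"


def hap(variants, sample="S", copy=1):
    return Haplotype(sample=sample, copy_index=copy, variants=frozenset(VariantKey.parse(v) for v in variants))


def af_profile(gene, fractions):
    return AlleleFractionProfile(
        sample="S", gene=gene, fractions={VariantKey.parse(k): v for k, v in fractions.items()}
    )


class TestPhasing:
    def test_hom_alt_lands_on_both_haplotypes(self, toy_table_factory, gene_models, translation_tables):
        t = toy_table_factory(["S"], [(V80, {"S": ((1, 1),)})])
        h1, h2 = phase_variants(t, gene_models["UGT1A1"], translation_tables["UGT1A1"])["S"]
        assert VariantKey.parse(V80) in h1.variants
        assert VariantKey.parse(V80) in h2.variants

    def test_jointly_defining_het_pair_placed_cis(self, toy_table_factory, gene_models, translation_tables):
        """*80 + *28 variants together define the *80+*28 haplotype: cis wins
        because the brute-force phaser maximizes whole-allele explanations."""
        t = toy_table_factory(["S"], [(V80, {"S": ((0, 1),)}), (V28, {"S": ((0, 1),)})])
        h1, h2 = phase_variants(t, gene_models["UGT1A1"], translation_tables["UGT1A1"])["S"]
        sets = sorted([h1.variants, h2.variants], key=len)
        assert sets[0] == frozenset()
        assert sets[1] == {VariantKey.parse(V80), VariantKey.parse(V28)}

    def test_two_distinct_single_variant_alleles_placed_trans(self, toy_table_factory, gene_models, translation_tables):
        # *6 and *80 define separate alleles and no joint allele: trans wins
        t = toy_table_factory(["S"], [(V6, {"S": ((0, 1),)}), (V80, {"S": ((0, 1),)})])
        h1, h2 = phase_variants(t, gene_models["UGT1A1"], translation_tables["UGT1A1"])["S"]
        assert {len(h1.variants), len(h2.variants)} == {1}
        assert h1.variants != h2.variants

    def test_passthrough_honors_phase_and_rejects_unphased(self, toy_table_factory, gene_models, translation_tables):
        phased = toy_table_factory(["S"], [(V80, {"S": ((1, 0), None, True)})])
        h1, h2 = phase_variants(
            phased, gene_models["UGT1A1"], translation_tables["UGT1A1"], mode="passthrough"
        )["S"]
        assert VariantKey.parse(V80) in h1.variants and V80 not in {v.render() for v in h2.variants}

        unphased = toy_table_factory(["S"], [(V80, {"S": ((0, 1),)})])
        with pytest.raises(GenotypeError, match="match mode"):
            phase_variants(unphased, gene_models["UGT1A1"], translation_tables["UGT1A1"], mode="passthrough")


class TestMatchAlleles:
    def test_empty_haplotype_matches_reference(self, translation_tables):
        assert match_alleles(hap([]), translation_tables["CYP2D6"])[0].name == "*1"

    def test_tata_box_variant_matches_cyp2a6_9(self, translation_tables):
        ranked = match_alleles(hap(["19-41356379-A-C"]), translation_tables["CYP2A6"])
        assert ranked[0].name == "*9"

    def test_combination_allele_outranks_components(self, translation_tables):
        ranked = match_alleles(hap([V80, V28]), translation_tables["UGT1A1"])
        assert ranked[0].name == "*80+*28"
        names = [a.name for a in ranked]
        assert set(names) >= {"*80+*28", "*80", "*28"}

    def test_result_independent_of_variant_input_order(self, translation_tables):
        a = match_alleles(hap([V80, V28]), translation_tables["UGT1A1"])
        b = match_alleles(hap([V28, V80]), translation_tables["UGT1A1"])
        assert [x.name for x in a] == [x.name for x in b]


class TestAssignDiplotype:
    def test_no_variants_normal_sv_is_homozygous_reference(self, translation_tables):
        table = translation_tables["CYP2D6"]
        sv = SVCall(gene="CYP2D6", label="normal", scores={})
        call = assign_diplotype((hap([]), hap([], copy=2)), sv, None, table)
        assert call.diplotype == "*1/*1"

    def test_ugt2b17_homozygous_deletion(self, translation_tables):
        table = translation_tables["UGT2B17"]
        sv = SVCall(gene="UGT2B17", label="del_hom", scores={})
        call = assign_diplotype((hap([]), hap([], copy=2)), sv, None, table)
        assert call.diplotype == "*2/*2"

    def test_ugt2b17_heterozygous_deletion(self, translation_tables):
        table = translation_tables["UGT2B17"]
        sv = SVCall(gene="UGT2B17", label="del_het", scores={})
        call = assign_diplotype((hap([]), hap([], copy=2)), sv, None, table)
        assert call.diplotype == "*1/*2"

    def test_one_three_allele_fraction_resolves_7_7x3(self, translation_tables):
        """Total copy 4 with het fractions at 1/4 and 3/4 is *7/*7x3, not *7x2/*7x2."""
        table = translation_tables["CYP2E1"]
        v7 = "10-135341500-G-T"
        haps = (hap([v7]), hap([v7], copy=2))  # *7 variants homozygous
        sv = SVCall(gene="CYP2E1", label="mult", scores={})
        af = af_profile("CYP2E1", {"10-135340700-A-G": 0.26, "10-135342300-C-T": 0.74})
        call = assign_diplotype(haps, sv, af, table)
        assert call.diplotype == "*7/*7x3"

    def test_balanced_fractions_resolve_7x2_7x2(self, translation_tables):
        table = translation_tables["CYP2E1"]
        v7 = "10-135341500-G-T"
        haps = (hap([v7]), hap([v7], copy=2))
        sv = SVCall(gene="CYP2E1", label="mult", scores={})
        af = af_profile("CYP2E1", {"10-135340700-A-G": 0.52, "10-135342300-C-T": 0.49})
        call = assign_diplotype(haps, sv, af, table)
        assert call.diplotype == "*7x2/*7x2"

    def test_duplication_suffix_follows_elevated_fraction(self, translation_tables):
        table = translation_tables["CYP2D6"]
        v2 = "22-42523500-C-T"
        haps = (hap([]), hap([v2], copy=2))
        sv = SVCall(gene="CYP2D6", label="whole_dup", scores={})
        af = af_profile("CYP2D6", {v2: 0.68})  # 2 of 3 copies carry *2
        call = assign_diplotype(haps, sv, af, table)
        assert call.diplotype == "*1/*2x2"

    def test_contradictory_fraction_refuses_the_call(self, translation_tables):
        table = translation_tables["CYP2D6"]
        v2 = "22-42523500-C-T"
        haps = (hap([]), hap([v2], copy=2))
        sv = SVCall(gene="CYP2D6", label="whole_dup", scores={})
        af = af_profile("CYP2D6", {v2: 0.05})  # incompatible with any split of 3
        call = assign_diplotype(haps, sv, af, table)
        assert call.indeterminate
        assert "inconsistent" in call.reason

    def test_duplication_without_evidence_is_low_confidence(self, translation_tables):
        table = translation_tables["CYP2A6"]
        sv = SVCall(gene="CYP2A6", label="dup", scores={})
        call = assign_diplotype((hap([]), hap([], copy=2)), sv, None, table)
        assert call.diplotype == "*1/*1x2"
        assert call.confidence == "low"

    def test_hybrid_substituted_on_base_haplotype(self, translation_tables):
        table = translation_tables["CYP2D6"]
        v10, v41 = "22-42526500-C-T", "22-42523800-G-A"
        haps = (hap([v41]), hap([v10], copy=2))
        sv = SVCall(gene="CYP2D6", label="hyb_36x2_10", scores={})
        call = assign_diplotype(haps, sv, None, table)
        assert call.diplotype == "*36x2+*10/*41"

    def test_indeterminate_sv_propagates(self, translation_tables):
        table = translation_tables["CYP2D6"]
        sv = SVCall(gene="CYP2D6", label="indeterminate", scores={}, indeterminate=True, reason="novel")
        call = assign_diplotype((hap([]), hap([], copy=2)), sv, None, table)
        assert call.indeterminate
        assert call.diplotype == "Indeterminate"


class TestRendering:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            (("*4", "*1"), "*1/*4"),
            (("*41", "*36x2+*10"), "*36x2+*10/*41"),
            (("*7x3", "*7"), "*7/*7x3"),
            (("*1x2", "*1"), "*1/*1x2"),
            (("*B", "*A"), "*A/*B"),
        ],
    )
    def test_canonical_order(self, pair, expected):
        call = DiplotypeCall(gene="G", sample="S", allele1=pair[0], allele2=pair[1])
        assert render_diplotype(call) == expected

    def test_indeterminate_renders_as_indeterminate(self):
        call = DiplotypeCall(gene="G", sample="S", allele1=None, allele2=None, indeterminate=True)
        assert render_diplotype(call) == "Indeterminate"

    def test_order_alleles_idempotent(self):
        assert order_alleles("*1", "*4") == order_alleles("*4", "*1") == ("*1", "*4")


class TestEndToEndRecovery:
    def test_cyp2d6_cohort_recovered(self, cyp2d6_classifier, translation_tables):
        """Simulate a mixed CYP2D6 cohort (SNV alleles, deletion, duplication,
        hybrids) and recover every truth diplotype through the full path."""
        from pgxstar.pipeline import genotype_cohort

        clf, model = cyp2d6_classifier
        gene = "CYP2D6"
        table = translation_tables[gene]
        mix = [
            ("*1", "*1"), ("*1", "*4"), ("*2", "*41"), ("*1", "*5"), ("*4", "*5"),
            ("*1", "*2x2"), ("*1", "*36+*10"), ("*41", "*36x2+*10"), ("*2", "*68+*4"),
            ("*10", "*17"),
        ]
        diplos = [mix[i % len(mix)] for i in range(40)]
        cfg = simdata.SimConfig(mean_depth=250, seed=2024)
        truth, depth, variants = simdata.simulate_cohort(gene, diplos, cfg, table, model)
        normals = [s for s, d in truth.diplotypes.items() if svcall.expected_sv_class(gene, d) == "normal"]
        calls = genotype_cohort(
            model.gene, model.control, table, variants, depth, clf,
            cohort_mode="no_sv_samples", no_sv_ids=normals,
        )
        recovered = 0
        for s, d in truth.diplotypes.items():
            want = render_diplotype(DiplotypeCall(gene=gene, sample=s, allele1=d[0], allele2=d[1]))
            recovered += calls[s].diplotype == want
        assert recovered == len(diplos)

    def test_reference_only_cohort_is_homozygous_reference(self, gstt1_classifier, translation_tables):
        from pgxstar.pipeline import genotype_cohort

        clf, model = gstt1_classifier
        table = translation_tables["GSTT1"]
        cfg = simdata.SimConfig(mean_depth=250, seed=9)
        truth, depth, variants = simdata.simulate_cohort("GSTT1", [("*A", "*A")] * 10, cfg, table, model)
        calls = genotype_cohort(model.gene, model.control, table, variants, depth, clf)
        assert all(c.diplotype == "*A/*A" for c in calls.values())
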