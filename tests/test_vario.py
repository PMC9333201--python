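"""Variant-table I/O, merging, multiallelic filtering, and concordance."""

import itertools

import numpy as np
import pytest

from pgxstar.errors import VariantIOError
from pgxstar.vario import (
    GenotypeCall,
    drop_multiallelic,
    flag_discordant_samples,
    genotype_concordance,
    merge_variant_tables,
    read_variant_table,
    write_variant_table,
)


def brute_force_concordance(test, truth, sample):
    """Independent per-site enumeration oracle for one sample.

    Walks the explicit union of sites, treating absent/missing genotypes as
    homozygous reference and skipping half-missing ones, and counts matches,
    false positives, and false negatives directly.
    """
    keys = sorted(
        {s.key for s in test.sites} | {s.key for s in truth.sites},
        key=lambda k: (k.chrom, k.pos, k.ref, k.alt),
    )
    matches = compared = fp = fn = 0
    for key in keys:
        def geno(table):
            for site in table.sites:
                if site.key == key and sample in site.genotypes:
                    g = site.genotypes[sample]
                    return (0, 0) if g.is_missing else g.alleles
            return (0, 0)

        a, b = geno(test), geno(truth)
        if None in a or None in b:
            continue
        compared += 1
        if sorted(a) == sorted(b):
            matches += 1
        a_nonref, b_nonref = any(x for x in a), any(x for x in b)
        if a_nonref and not b_nonref:
            fp += 1
        if b_nonref and not a_nonref:
            fn += 1
    return matches / compared, fp, fn


class TestReadWrite:
    def test_vcf_round_trip_with_bed_filter(self, toy_table_factory, tmp_path):
        table = toy_table_factory(
            ["S1", "S2"],
            [
                ("1-50-A-C", {"S1": ((0, 1), (12, 10)), "S2": ((0, 0),)}),
                ("1-100-G-T", {"S1": ((1, 1),), "S2": ((0, 1),)}),
                ("1-200-T-TA", {"S1": ((0, 1),), "S2": None}),
            ],
        )
        path = tmp_path / "toy.vcf"
        write_variant_table(table, path)

        full = read_variant_table(path)
        assert len(full) == 3
        assert full.genotype(full.sites[0], "S1").ad == (12, 10)

        # BED is 0-based half-open: [99, 100) keeps only 1-based position 100
        kept = read_variant_table(path, regions=[("1", 99, 100)])
        assert [s.key.pos for s in kept.sites] == [100]

        two = read_variant_table(path, regions=[("1", 0, 150)])
        assert len(two) == 2

    def test_multiallelic_site_flagged_at_read_time(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\t.\tA\tC,G\t.\t.\t.\tGT\t1/2\n"
        )
        table = read_variant_table(vcf)
        assert len(table) == 1
        assert table.sites[0].multiallelic

    def test_sample_less_vcf_rejected(self, tmp_path):
        vcf = tmp_path / "nosamples.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t100\t.\tA\tC\t.\t.\t.\n"
        )
        with pytest.raises(VariantIOError, match="no samples"):
            read_variant_table(vcf)

    def test_unsorted_vcf_rejected(self, tmp_path):
        vcf = tmp_path / "unsorted.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t200\t.\tA\tC\t.\t.\t.\tGT\t0/1\n"
            "1\t100\t.\tG\tT\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(VariantIOError, match="sorted"):
            read_variant_table(vcf)


class TestMerge:
    def test_site_union_with_missing_for_private_sites(self, toy_table_factory):
        a = toy_table_factory(["A1"], [("1-100-G-T", {"A1": ((0, 1),)})])
        b = toy_table_factory(["B1"], [("1-200-C-A", {"B1": ((1, 1),)})])
        merged = merge_variant_tables(a, b)
        assert merged.samples == ["A1", "B1"]
        assert len(merged) == 2
        site100 = next(s for s in merged.sites if s.key.pos == 100)
        assert merged.genotype(site100, "B1").is_missing

    def test_identical_sites_stack_samples(self, toy_table_factory):
        a = toy_table_factory(["A1"], [("1-100-G-T", {"A1": ((0, 1),)})])
        b = toy_table_factory(["B1"], [("1-100-G-T", {"B1": ((1, 1),)})])
        merged = merge_variant_tables(a, b)
        assert len(merged) == 1 and len(merged.samples) == 2

    def test_merge_with_empty_is_identity(self, toy_table_factory):
        a = toy_table_factory(["A1"], [("1-100-G-T", {"A1": ((0, 1),)})])
        empty = toy_table_factory(["B1"], [])
        merged = merge_variant_tables(a, empty)
        assert [s.key for s in merged.sites] == [a.sites[0].key]

    def test_overlapping_samples_rejected(self, toy_table_factory):
        a = toy_table_factory(["S"], [])
        b = toy_table_factory(["S"], [])
        with pytest.raises(VariantIOError, match="overlapping"):
            merge_variant_tables(a, b)


class TestDropMultiallelic:
    def test_triallelic_record_removed(self, toy_table_factory):
        t = toy_table_factory(
            ["S"], [("1-100-A-C", {"S": ((0, 1),)}), ("1-200-G-T", {"S": ((0, 1),)})]
        )
        t.sites[0].alts = ("C", "G")
        assert [s.key.pos for s in drop_multiallelic(t).sites] == [200]

    def test_split_records_at_same_position_both_removed(self, toy_table_factory):
        t = toy_table_factory(
            ["S"],
            [
                ("1-100-A-C", {"S": ((0, 1),)}),
                ("1-100-A-G", {"S": ((0, 1),)}),
                ("1-200-G-T", {"S": ((0, 1),)}),
            ],
        )
        assert [s.key.pos for s in drop_multiallelic(t).sites] == [200]

    def test_all_biallelic_unchanged(self, toy_table_factory):
        t = toy_table_factory(
            ["S"], [("1-100-A-C", {"S": ((0, 1),)}), ("1-200-G-T", {"S": ((1, 1),)})]
        )
        assert len(drop_multiallelic(t)) == 2


class TestConcordance:
    def test_self_concordance_is_exactly_one(self, toy_table_factory):
        t = toy_table_factory(
            ["S1", "S2"],
            [
                ("1-100-A-C", {"S1": ((0, 1),), "S2": ((1, 1),)}),
                ("1-200-G-GT", {"S1": ((0, 0),), "S2": ((0, 1),)}),
            ],
        )
        report = genotype_concordance(t, t)
        assert (report.per_sample["overall_concordance"] == 1.0).all()
        assert (report.per_sample[["false_positive_count", "false_negative_count"]] == 0).all().all()

    def test_missed_het_counts_as_false_negative(self, toy_table_factory):
        records = [(f"1-{100 + i}-A-C", {"T": ((0, 0),), "R": ((0, 0),)}) for i in range(9)]
        records.append(("1-300-G-T", {"T": ((0, 0),), "R": ((0, 1),)}))
        test = toy_table_factory(["T"], [(k, {"T": v["T"]}) for k, v in records])
        truth_t = toy_table_factory(["T"], [(k, {"T": v["R"]}) for k, v in records])
        report = genotype_concordance(test, truth_t)
        row = report.per_sample.loc["T"]
        assert row["overall_concordance"] == pytest.approx(0.9)
        assert row["false_negative_count"] == 1
        assert row["false_positive_count"] == 0

    def test_matches_brute_force_oracle_on_random_tables(self, toy_table_factory, rng):
        """Equivalence with independent per-site enumeration, <=20 sites x 5 samples."""
        samples = [f"S{i}" for i in range(5)]
        gts = [(0, 0), (0, 1), (1, 1), (None, None), (0, None)]
        for trial in range(10):
            n_sites = int(rng.integers(1, 21))
            positions = sorted(rng.choice(np.arange(100, 5000), size=n_sites, replace=False))

            def random_records():
                return [
                    (
                        f"1-{p}-A-{'C' if p % 2 else 'CT'}",
                        {s: (gts[rng.integers(len(gts))],) for s in samples},
                    )
                    for p in positions
                ]

            test = toy_table_factory(samples, random_records())
            truth = toy_table_factory(samples, random_records())
            report = genotype_concordance(test, truth)
            for s in samples:
                conc, fp, fn = brute_force_concordance(test, truth, s)
                row = report.per_sample.loc[s]
                assert row["overall_concordance"] == pytest.approx(conc)
                assert row["false_positive_count"] == fp
                assert row["false_negative_count"] == fn

    def test_swapping_test_and_truth_swaps_fp_fn(self, toy_table_factory, rng):
        samples = ["S0", "S1"]
        gts = [(0, 0), (0, 1), (1, 1)]
        recs_a = [(f"1-{100 + i}-A-C", {s: (gts[rng.integers(3)],) for s in samples}) for i in range(15)]
        recs_b = [(f"1-{100 + i}-A-C", {s: (gts[rng.integers(3)],) for s in samples}) for i in range(15)]
        fwd = genotype_concordance(toy_table_factory(samples, recs_a), toy_table_factory(samples, recs_b))
        rev = genotype_concordance(toy_table_factory(samples, recs_b), toy_table_factory(samples, recs_a))
        for s in samples:
            f, r = fwd.per_sample.loc[s], rev.per_sample.loc[s]
            assert f["overall_concordance"] == pytest.approx(r["overall_concordance"])
            assert f["false_positive_count"] == r["false_negative_count"]
            assert f["false_negative_count"] == r["false_positive_count"]

    def test_random_perturbation_rate_recovered(self, toy_table_factory, rng):
        """5% of 1000 sites perturbed -> concordance near 0.95."""
        n = 1000
        flip = rng.random(n) < 0.05
        truth_recs, test_recs = [], []
        for i in range(n):
            key = f"1-{1000 + i}-A-C"
            truth_recs.append((key, {"S": ((0, 1),)}))
            test_recs.append((key, {"S": ((1, 1) if flip[i] else (0, 1),)}))
        report = genotype_concordance(
            toy_table_factory(["S"], test_recs), toy_table_factory(["S"], truth_recs)
        )
        observed = report.per_sample.loc["S", "overall_concordance"]
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(observed - 0.95) < 4 * se

    def test_no_shared_samples_rejected(self, toy_table_factory):
        with pytest.raises(VariantIOError, match="shared"):
            genotype_concordance(toy_table_factory(["A"], []), toy_table_factory(["B"], []))

    def test_snv_indel_split(self, toy_table_factory):
        t = toy_table_factory(
            ["S"], [("1-100-A-C", {"S": ((0, 1),)}), ("1-200-G-GT", {"S": ((0, 1),)})]
        )
        u = toy_table_factory(
            ["S"], [("1-100-A-C", {"S": ((0, 1),)}), ("1-200-G-GT", {"S": ((1, 1),)})]
        )
        row = genotype_concordance(t, u).per_sample.loc["S"]
        assert row["snv_concordance"] == 1.0
        assert row["indel_concordance"] == 0.0


class TestDiscordantSampleFlagging:
    def _report(self, toy_table_factory, values):
        import pandas as pd

        from pgxstar.vario import ConcordanceReport

        df = pd.DataFrame(
            {"overall_concordance": values}, index=[f"S{i}" for i in range(len(values))]
        )
        return ConcordanceReport(per_sample=df, site_union=100)

    def test_swap_grade_outlier_flagged(self, toy_table_factory):
        # a sample-swap presents as a far outlier against a concordant cohort
        report = self._report(toy_table_factory, [0.963, 0.767, 0.971])
        assert flag_discordant_samples(report, 0.90) == ["S1"]

    def test_no_outliers_empty(self, toy_table_factory):
        report = self._report(toy_table_factory, [0.95, 0.99])
        assert flag_discordant_samples(report, 0.90) == []

    def test_zero_threshold_vacuous(self, toy_table_factory):
        report = self._report(toy_table_factory, [0.1, 0.0001])
        assert flag_discordant_samples(report, 0.0) == []
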