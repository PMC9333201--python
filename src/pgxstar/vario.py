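"""Multi-sample variant tables and genotype concordance.

Implements the variant-comparison workflow used to validate a targeted
panel's calls against a reference call set: read VCFs restricted to the
targeted regions, merge the two call sets, drop multiallelic sites, and
compute per-sample genotype concordance with false-positive/false-negative
splits for SNVs and indels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .catalog import VariantKey
from .errors import VariantIOError

__all__ = [
    "GenotypeCall",
    "Site",
    "VariantTable",
    "ConcordanceReport",
    "read_bed",
    "read_variant_table",
    "write_variant_table",
    "merge_variant_tables",
    "drop_multiallelic",
    "genotype_concordance",
    "flag_discordant_samples",
]

MISSING = (None, None)


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid genotype: allele indices (0=ref, 1=alt, None=missing), phase, depths."""

    alleles: tuple = MISSING
    phased: bool = False
    ad: tuple | None = None  # (ref_count, alt_count)

    @property
    def is_missing(self) -> bool:
        return all(a is None for a in self.alleles)

    @property
    def is_half_missing(self) -> bool:
        return any(a is None for a in self.alleles) and not self.is_missing

    @property
    def is_nonref(self) -> bool:
        return any(a not in (0, None) for a in self.alleles)


@dataclass
class Site:
    """One variant record: key, full ALT list (for multiallelic flagging), genotypes."""

    key: VariantKey
    alts: tuple[str, ...]
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    @property
    def multiallelic(self) -> bool:
        return len(self.alts) > 1


@dataclass
class VariantTable:
    """Ordered variant sites x samples, sorted by (chrom, pos, ref, alt)."""

    samples: list[str]
    sites: list[Site] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise VariantIOError("duplicate sample ids")
        self.sort()

    def sort(self) -> None:
        self.sites.sort(key=lambda s: (s.key.chrom, s.key.pos, s.key.ref, s.key.alt))

    def genotype(self, site: Site, sample: str) -> GenotypeCall:
        return site.genotypes.get(sample, GenotypeCall())

    def __len__(self) -> int:
        return len(self.sites)


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED intervals (0-based, half-open)."""
    intervals = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        intervals.append((chrom, int(start), int(end)))
    return intervals


def _in_regions(chrom: str, pos: int, regions) -> bool:
    """1-based position against 0-based half-open intervals."""
    c = chrom.removeprefix("chr")
    for rchrom, start, end in regions:
        if rchrom.removeprefix("chr") == c and start < pos <= end:
            return True
    return False


def read_variant_table(path, regions=None) -> VariantTable:
    """Read a VCF into a :class:`VariantTable`.

    ``regions`` is an optional BED path or interval list; only sites whose
    1-based position falls inside a region are kept.  Multiallelic records
    are retained and flagged.  GT and AD fields are honored.
    """
    if regions is not None and not isinstance(regions, list):
        regions = read_bed(regions)
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if not samples:
        raise VariantIOError(f"{path}: VCF has no samples")
    sites = []
    last = None
    for rec in vcf:
        if last is not None and last[0] == rec.chrom and rec.pos < last[1]:
            raise VariantIOError(f"{path}: VCF not position-sorted at {rec.chrom}:{rec.pos}")
        last = (rec.chrom, rec.pos)
        if rec.alts is None:
            continue
        if regions is not None and not _in_regions(rec.chrom, rec.pos, regions):
            continue
        key = VariantKey(rec.chrom, rec.pos, rec.ref, rec.alts[0])
        genotypes = {}
        for s in samples:
            sgt = rec.samples[s]
            alleles = tuple(sgt.get("GT", MISSING))
            if len(alleles) == 1:  # haploid record; treat as half-missing
                alleles = (alleles[0], None)
            ad = sgt.get("AD")
            ad = tuple(int(x) for x in ad[:2]) if ad is not None and ad[0] is not None else None
            genotypes[s] = GenotypeCall(alleles=alleles, phased=sgt.phased, ad=ad)
        sites.append(Site(key=key, alts=tuple(rec.alts), genotypes=genotypes))
    return VariantTable(samples=samples, sites=sites)


def write_variant_table(table: VariantTable, path) -> None:
    """Write a :class:`VariantTable` as VCF 4.2 with GT and AD fields."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    contigs = {}
    for site in table.sites:
        contigs[site.key.chrom] = max(contigs.get(site.key.chrom, 0), site.key.pos + 10000)
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for s in table.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in table.sites:
            rec = out.new_record(
                contig=site.key.chrom,
                start=site.key.pos - 1,
                stop=site.key.pos - 1 + len(site.key.ref),
                alleles=(site.key.ref, *site.alts),
            )
            for s in table.samples:
                call = table.genotype(site, s)
                rec.samples[s]["GT"] = call.alleles
                rec.samples[s].phased = call.phased
                if call.ad is not None:
                    rec.samples[s]["AD"] = call.ad
            out.write(rec)


def merge_variant_tables(a: VariantTable, b: VariantTable) -> VariantTable:
    """Union of sites over the disjoint union of samples.

    Samples absent at a site (private to the other table) receive a missing
    genotype there.
    """
    overlap = set(a.samples) & set(b.samples)
    if overlap:
        raise VariantIOError(f"overlapping sample ids: {sorted(overlap)}")
    merged: dict[VariantKey, Site] = {}
    for table in (a, b):
        for site in table.sites:
            if site.key not in merged:
                merged[site.key] = Site(key=site.key, alts=site.alts, genotypes=dict(site.genotypes))
            else:
                tgt = merged[site.key]
                tgt.alts = tuple(dict.fromkeys(tgt.alts + site.alts))
                tgt.genotypes.update(site.genotypes)
    return VariantTable(samples=a.samples + b.samples, sites=list(merged.values()))


def drop_multiallelic(t: VariantTable) -> VariantTable:
    """Remove multiallelic sites.

    A site is dropped when its own record carries more than one ALT, or when
    another record shares its chrom/pos with a different ALT (split
    multiallelics).
    """
    by_pos: dict[tuple[str, int], int] = {}
    for site in t.sites:
        by_pos[(site.key.chrom, site.key.pos)] = by_pos.get((site.key.chrom, site.key.pos), 0) + 1
    kept = [
        site
        for site in t.sites
        if not site.multiallelic and by_pos[(site.key.chrom, site.key.pos)] == 1
    ]
    return VariantTable(samples=list(t.samples), sites=kept)


@dataclass
class ConcordanceReport:
    """Per-sample genotype agreement plus cohort mean."""

    per_sample: pd.DataFrame  # indexed by sample
    site_union: int

    @property
    def cohort_mean(self) -> float:
        return float(self.per_sample["overall_concordance"].mean())

    def to_tsv(self, path) -> None:
        self.per_sample.to_csv(path, sep="\t")

    def to_json(self, path) -> None:
        payload = {
            "cohort_mean": self.cohort_mean,
            "site_union": self.site_union,
            "samples": self.per_sample.reset_index().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _gt_sorted(call: GenotypeCall) -> tuple:
    return tuple(sorted(call.alleles))


def genotype_concordance(test: VariantTable, truth: VariantTable, regions=None) -> ConcordanceReport:
    """Per-sample genotype concordance of ``test`` against ``truth``.

    Compared sites are the union of both tables' sites (optionally
    restricted to BED ``regions``).  A site missing from one table is
    treated as homozygous reference there; half-missing genotypes are
    excluded from the denominator.  False positives are sites non-reference
    in ``test`` but reference/absent in ``truth``; false negatives the
    converse.  SNVs and indels are split by ref/alt length.
    """
    shared = [s for s in test.samples if s in set(truth.samples)]
    if not shared:
        raise VariantIOError("no shared samples between call sets")
    if regions is not None and not isinstance(regions, list):
        regions = read_bed(regions)

    test_by_key = {s.key: s for s in test.sites}
    truth_by_key = {s.key: s for s in truth.sites}
    keys = sorted(
        set(test_by_key) | set(truth_by_key), key=lambda k: (k.chrom, k.pos, k.ref, k.alt)
    )
    if regions is not None:
        keys = [k for k in keys if _in_regions(k.chrom, k.pos, regions)]

    homref = GenotypeCall(alleles=(0, 0))
    records = []
    for sample in shared:
        counts = {
            "snv": [0, 0],  # [matches, compared]
            "indel": [0, 0],
        }
        fp = fn = half_missing = 0
        for key in keys:
            tcall = test_by_key[key].genotypes.get(sample, homref) if key in test_by_key else homref
            rcall = truth_by_key[key].genotypes.get(sample, homref) if key in truth_by_key else homref
            if tcall.is_missing:
                tcall = homref
            if rcall.is_missing:
                rcall = homref
            if tcall.is_half_missing or rcall.is_half_missing:
                half_missing += 1
                continue
            kind = "indel" if key.is_indel else "snv"
            match = _gt_sorted(tcall) == _gt_sorted(rcall)
            counts[kind][1] += 1
            counts[kind][0] += int(match)
            if tcall.is_nonref and not rcall.is_nonref:
                fp += 1
            elif rcall.is_nonref and not tcall.is_nonref:
                fn += 1
        matches = counts["snv"][0] + counts["indel"][0]
        compared = counts["snv"][1] + counts["indel"][1]
        records.append(
            {
                "sample": sample,
                "overall_concordance": matches / compared if compared else 1.0,
                "snv_concordance": counts["snv"][0] / counts["snv"][1] if counts["snv"][1] else 1.0,
                "indel_concordance": counts["indel"][0] / counts["indel"][1] if counts["indel"][1] else 1.0,
                "false_positive_count": fp,
                "false_negative_count": fn,
                "sites_compared": compared,
                "half_missing_excluded": half_missing,
            }
        )
    df = pd.DataFrame(records).set_index("sample")
    return ConcordanceReport(per_sample=df, site_union=len(keys))


def flag_discordant_samples(report: ConcordanceReport, threshold: float = 0.90) -> list[str]:
    """Samples whose overall concordance falls below ``threshold`` (sorted).

    The default separates sample-swap-grade outliers from ordinary panel
    noise: a swapped sample sits far below a concordant cohort.
    """
    if not (0 <= threshold <= 1):
        raise VariantIOError("threshold must lie in [0, 1]")
    bad = report.per_sample[report.per_sample["overall_concordance"] < threshold]
    return sorted(bad.index.tolist())
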