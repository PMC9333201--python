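"""Haplotype-to-star-allele matching and copy-number-aware diplotype calls.

The calling path mirrors a panel genotyping pipeline: phase the small
variants in the target gene (consuming pre-phased genotypes, or a
deterministic catalog-guided fallback), match each haplotype's variant set
against the gene's translation table, then fold in the structural-variant
classification and allele-fraction evidence to produce the final diplotype
-- e.g. attaching an ``x2`` copy suffix to the haplotype whose variants sit
at an elevated allele fraction, or substituting a registered hybrid allele
name for the haplotype that carries the hybrid's base variants.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from .catalog import GeneDefinition, StarAllele, TranslationTable, VariantKey, parse_copy_suffix
from .covdepth import AlleleFractionProfile
from .errors import GenotypeError
from .svcall import SV_CLASSES, SVCall
from .vario import VariantTable

__all__ = [
    "Haplotype",
    "DiplotypeCall",
    "phase_variants",
    "match_alleles",
    "assign_diplotype",
    "render_diplotype",
    "order_alleles",
]

AF_CN_TOLERANCE = 0.12  # binomial noise band at >= 100x site depth
_MAX_BRUTE_HET = 12

_FUNCTION_KNOWN = {"normal", "decreased", "no_function", "increased"}


@dataclass(frozen=True)
class Haplotype:
    """One gene copy's variant content for one sample."""

    sample: str
    copy_index: int  # 1 or 2
    variants: frozenset[VariantKey] = frozenset()


@dataclass
class DiplotypeCall:
    """Final per-sample/gene call with provenance."""

    gene: str
    sample: str
    allele1: str | None
    allele2: str | None
    indeterminate: bool = False
    reason: str | None = None
    confidence: str = "normal"
    evidence: dict = field(default_factory=dict)

    @property
    def diplotype(self) -> str:
        return render_diplotype(self)


# ---------------------------------------------------------------------------
# phasing


def _hap_match_score(variants: frozenset[VariantKey], table: TranslationTable) -> tuple[int, int]:
    """(explained - unexplained, size of best single-allele match)."""
    best = 0
    for a in table.alleles:
        if a.sv_tag != "none" or not a.defining_variants:
            continue
        if a.defining_variants <= variants:
            best = max(best, len(a.defining_variants))
    return best - (len(variants) - best), best


def phase_variants(
    t: VariantTable,
    gene: GeneDefinition,
    table: TranslationTable,
    mode: str = "match",
) -> dict[str, tuple[Haplotype, Haplotype]]:
    """Split each sample's in-gene variants onto two haplotypes.

    ``passthrough`` honors phased genotypes (first allele to copy 1) and
    refuses unphased heterozygotes.  ``match`` assigns unphased het variants
    to copies by brute force over phasings, preferring the assignment whose
    haplotypes are best explained by whole catalog alleles (largest
    explained-variant count, then most-specific single allele, then the
    lexically smallest assignment for determinism).  Homozygous-alt variants
    go to both copies either way.
    """
    if mode not in ("passthrough", "match"):
        raise GenotypeError(f"unknown phasing mode {mode!r}")
    out = {}
    for sample in t.samples:
        hom: set[VariantKey] = set()
        het: list[tuple[VariantKey, tuple]] = []
        for site in t.sites:
            if not gene.contains(site.key):
                continue
            call = t.genotype(site, sample)
            if call.is_missing or call.is_half_missing or not call.is_nonref:
                continue
            if all(a == 1 for a in call.alleles):
                hom.add(site.key)
            else:
                het.append((site.key, (call.alleles, call.phased)))
        het.sort(key=lambda kv: (kv[0].chrom, kv[0].pos, kv[0].ref, kv[0].alt))

        if mode == "passthrough":
            h1, h2 = set(hom), set(hom)
            for key, (alleles, phased) in het:
                if not phased:
                    raise GenotypeError(
                        f"{sample}: unphased heterozygote {key.render()}; use match mode"
                    )
                (h1 if alleles[0] == 1 else h2).add(key)
            assignment_sets = (h1, h2)
        else:
            n = len(het)
            if n > _MAX_BRUTE_HET:
                raise GenotypeError(
                    f"{sample}: {n} het sites exceeds the catalog-guided phaser's limit"
                )
            best_bits, best_score = 0, None
            for bits in range(2 ** n):
                h1 = set(hom) | {het[i][0] for i in range(n) if not (bits >> i) & 1}
                h2 = set(hom) | {het[i][0] for i in range(n) if (bits >> i) & 1}
                s1 = _hap_match_score(frozenset(h1), table)
                s2 = _hap_match_score(frozenset(h2), table)
                score = (s1[0] + s2[0], s1[1] + s2[1], -bits)
                if best_score is None or score > best_score:
                    best_score, best_bits = score, bits
            assignment_sets = (
                set(hom) | {het[i][0] for i in range(n) if not (best_bits >> i) & 1},
                set(hom) | {het[i][0] for i in range(n) if (best_bits >> i) & 1},
            )
        out[sample] = (
            Haplotype(sample=sample, copy_index=1, variants=frozenset(assignment_sets[0])),
            Haplotype(sample=sample, copy_index=2, variants=frozenset(assignment_sets[1])),
        )
    return out


# ---------------------------------------------------------------------------
# matching


def match_alleles(h: Haplotype, table: TranslationTable) -> list[StarAllele]:
    """Catalog alleles whose whole defining set is carried by the haplotype.

    SV-tagged alleles are excluded here -- they are only reachable through
    the SV integration step.  Candidates are ranked most-specific first
    (largest defining set), then known-function before unknown, then
    lexically.  An empty candidate list yields the reference allele.
    """
    candidates = [
        a
        for a in table.alleles
        if a.sv_tag == "none" and a.defining_variants and a.defining_variants <= h.variants
    ]
    candidates.sort(
        key=lambda a: (
            -len(a.defining_variants),
            0 if a.function in _FUNCTION_KNOWN else 1,
            a.name,
        )
    )
    return candidates or [table.reference]


# ---------------------------------------------------------------------------
# diplotype assignment


def _numeric_core(name: str):
    m = re.search(r"\*?(\d+)", name)
    return int(m.group(1)) if m else None


def order_alleles(a1: str, a2: str) -> tuple[str, str]:
    """Canonical diplotype order: smaller numeric core first, non-numeric
    names lexical, copy-suffixed forms ordered by their base allele."""

    def key(name: str):
        base, copies = parse_copy_suffix(name)
        core = _numeric_core(base)
        return (0, core, copies, name) if core is not None else (1, 0, copies, name)

    return (a1, a2) if key(a1) <= key(a2) else (a2, a1)


def render_diplotype(c: DiplotypeCall) -> str:
    """Canonical ``allele1/allele2`` string; ``Indeterminate`` when refused."""
    if c.indeterminate:
        return "Indeterminate"
    a1, a2 = order_alleles(c.allele1, c.allele2)
    return f"{a1}/{a2}"


def _indeterminate(gene, sample, reason, evidence=None) -> DiplotypeCall:
    return DiplotypeCall(
        gene=gene,
        sample=sample,
        allele1=None,
        allele2=None,
        indeterminate=True,
        reason=reason,
        evidence=evidence or {},
    )


def _split_copies(
    k: int,
    hap_alleles: tuple[StarAllele, StarAllele],
    haps: tuple[Haplotype, Haplotype],
    af: AlleleFractionProfile | None,
    catalog_variants: set[VariantKey],
):
    """Infer how k total gene copies split across the two haplotypes.

    Heterozygous catalog variants are anchored to their phased haplotype and
    must sit near (copies of that haplotype)/k; non-catalog het sites (a
    sample's personal variants) may belong to either copy and take the
    nearer expectation.  Returns (c1, c2, mean_residual, had_evidence).
    """
    fractions = af.fractions if af is not None else {}
    anchored = []  # (hap_index, fraction)
    flexible = []
    only1 = haps[0].variants - haps[1].variants
    only2 = haps[1].variants - haps[0].variants
    for key, frac in fractions.items():
        if key in catalog_variants:
            if key in only1:
                anchored.append((0, frac))
            elif key in only2:
                anchored.append((1, frac))
        else:
            flexible.append(frac)
    splits = [(c1, k - c1) for c1 in range(1, k)]
    best = None
    for c1, c2 in splits:
        resid = 0.0
        n = 0
        for hap_i, frac in anchored:
            resid += abs(frac - (c1 if hap_i == 0 else c2) / k)
            n += 1
        for frac in flexible:
            resid += min(abs(frac - c1 / k), abs(frac - c2 / k))
            n += 1
        mean_resid = resid / n if n else None
        cand = (mean_resid if mean_resid is not None else 0.0, abs(c1 - c2), c1, c2, n > 0)
        if best is None or (cand[0], cand[1]) < (best[0], best[1]):
            best = cand
    mean_resid, _, c1, c2, had = best
    return c1, c2, mean_resid, had


def _with_suffix(name: str, copies: int) -> str:
    base, _ = parse_copy_suffix(name)
    return base if copies <= 1 else f"{base}x{copies}"


def assign_diplotype(
    haps: tuple[Haplotype, Haplotype],
    sv: SVCall,
    af: AlleleFractionProfile | None,
    table: TranslationTable,
) -> DiplotypeCall:
    """Fold the SV classification and allele-fraction evidence into the call.

    * normal: top matched allele per haplotype;
    * heterozygous deletion: the remaining copy's best allele paired with the
      gene's deletion allele; homozygous deletion: deletion allele twice;
    * duplication/multiplication: the copy split is inferred from het-site
      allele fractions (expected c/k) and rendered as an ``xN`` suffix; an
      allele-fraction pattern inconsistent with the copy-number plateau
      beyond ``AF_CN_TOLERANCE`` refuses the call;
    * hybrid (and other named SV alleles): the registered allele name is
      substituted for the haplotype carrying its base variants;
    * an Indeterminate SV classification propagates to the diplotype.
    """
    sample = haps[0].sample
    gene = table.gene
    if sv.gene != gene:
        raise GenotypeError(f"SV call gene {sv.gene} does not match table gene {gene}")
    evidence = {
        "sv_class": sv.label,
        "matched_variants": sorted(v.render() for v in haps[0].variants | haps[1].variants),
    }
    if sv.indeterminate:
        return _indeterminate(gene, sample, f"SV classification indeterminate: {sv.reason}", evidence)

    registry = SV_CLASSES.get(gene, {"normal": None})
    if sv.label not in registry:
        raise GenotypeError(f"SV class {sv.label!r} not registered for {gene}")

    cand1 = match_alleles(haps[0], table)[0]
    cand2 = match_alleles(haps[1], table)[0]
    catalog_variants = {v for a in table.alleles for v in a.defining_variants}

    if sv.label == "normal":
        return DiplotypeCall(
            gene=gene, sample=sample, allele1=cand1.name, allele2=cand2.name, evidence=evidence
        )

    canonical = registry[sv.label]
    members = [table.get(name) for name in canonical]
    sv_members = [a for a in members if a.sv_tag != "none"]

    # homozygous deletion: both canonical members are the deletion allele
    if len(sv_members) == 2 and all(a.sv_tag == "del" for a in sv_members):
        d = sv_members[0].name
        return DiplotypeCall(gene=gene, sample=sample, allele1=d, allele2=d, evidence=evidence)

    m = sv_members[0]

    if m.sv_tag == "del":
        # remaining copy: every surviving variant is on it (hemizygous calls
        # present as homozygous), so both haplotypes match the same allele
        return DiplotypeCall(
            gene=gene, sample=sample, allele1=cand1.name, allele2=m.name, evidence=evidence
        )

    if m.sv_tag == "hyb" or (m.sv_tag in ("dup", "mult") and parse_copy_suffix(m.name)[1] == 1):
        # named SV allele substituted for the haplotype carrying its base variants
        if m.defining_variants and m.defining_variants <= haps[1].variants:
            other = cand1.name
        elif m.defining_variants and m.defining_variants <= haps[0].variants:
            other = cand2.name
        else:
            other = cand1.name  # no base variants to anchor on; keep copy 1's call
        if af is not None and m.defining_variants:
            obs = [af.fractions[v] for v in m.defining_variants if v in af.fractions]
            evidence["hybrid_base_af"] = obs
        return DiplotypeCall(
            gene=gene, sample=sample, allele1=other, allele2=m.name, evidence=evidence
        )

    # duplication / multiplication with an explicit copy count
    _, extra = parse_copy_suffix(m.name)
    k = extra + 1  # canonical pairs carry one normal partner
    c1, c2, resid, had_evidence = _split_copies(k, (cand1, cand2), haps, af, catalog_variants)
    evidence["total_copies"] = k
    evidence["af_residual"] = resid
    if resid is not None and resid > AF_CN_TOLERANCE:
        return _indeterminate(
            gene,
            sample,
            f"allele-fraction evidence inconsistent with copy-number plateau ({resid:.2f} > {AF_CN_TOLERANCE})",
            evidence,
        )
    if not had_evidence:
        # no het site to attribute the extra copies: duplicate the
        # reference-most allele and flag low confidence
        first, _second = order_alleles(cand1.name, cand2.name)
        c1, c2 = (k - 1, 1) if cand1.name == first else (1, k - 1)
        call = DiplotypeCall(
            gene=gene,
            sample=sample,
            allele1=_with_suffix(cand1.name, c1),
            allele2=_with_suffix(cand2.name, c2),
            confidence="low",
            evidence=evidence,
        )
        return call
    return DiplotypeCall(
        gene=gene,
        sample=sample,
        allele1=_with_suffix(cand1.name, c1),
        allele2=_with_suffix(cand2.name, c2),
        evidence=evidence,
    )
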