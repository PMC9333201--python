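"""Diplotype- and phenotype-level concordance between call sets.

Comparing a panel's star-allele calls against a published reference set
requires an *exclusion ledger*: alleles added to nomenclature after the
reference was produced are mapped to a surrogate, cell-line trisomy
artifacts drop the duplicated allele, legacy notations are canonicalized,
and swapped samples are excluded outright.  After normalization, agreement
is whole-diplotype string equality; each residual mismatch is categorized
(untargeted variant, phasing, variant calling, SV interpretation, other)
from evidence tags supplied with the calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .catalog import packaged_data_path
from .errors import ComparisonError
from .genotyper import order_alleles

__all__ = [
    "DISCREPANCY_CATEGORIES",
    "ComparisonLedger",
    "DiplotypeConcordance",
    "load_ledger",
    "normalize_for_comparison",
    "diplotype_concordance",
    "phenotype_concordance",
]

DISCREPANCY_CATEGORIES = (
    "untargeted_variant",
    "phasing",
    "variant_calling",
    "sv_interpretation",
    "other",
)


@dataclass
class ComparisonLedger:
    """Adjustments applied before counting agreement; every entry has a reason."""

    ignored_alleles: dict = field(default_factory=dict)  # gene -> {allele -> {surrogate, reason}}
    sample_adjustments: list = field(default_factory=list)
    notation_equivalences: dict = field(default_factory=dict)  # gene -> {legacy -> {canonical, reason}}
    excluded_samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for gene, table in self.ignored_alleles.items():
            for allele, entry in table.items():
                if "reason" not in entry:
                    raise ComparisonError(f"ignored allele {gene} {allele} lacks a reason")
        for entry in self.sample_adjustments + self.excluded_samples:
            if "reason" not in entry:
                raise ComparisonError(f"ledger entry {entry} lacks a reason")

    @property
    def excluded_ids(self) -> set[str]:
        return {e["sample"] for e in self.excluded_samples}

    def drops_duplicate(self, sample: str, gene: str) -> bool:
        for entry in self.sample_adjustments:
            if (
                entry.get("action") == "drop_duplicated_allele"
                and entry["sample"] == sample
                and gene in entry.get("genes", [])
            ):
                return True
        return False

    def exclude_sample(self, sample: str, reason: str) -> None:
        """Append a sample exclusion (e.g. from a variant-level swap flag)."""
        self.excluded_samples.append({"sample": sample, "reason": reason})


def load_ledger(source=None) -> ComparisonLedger:
    """Load a YAML ledger (the packaged main-text default when omitted)."""
    if source is None:
        source = packaged_data_path("comparison_ledger.yaml")
    with open(source) as fh:
        raw = yaml.safe_load(fh) or {}
    return ComparisonLedger(
        ignored_alleles=raw.get("ignored_alleles", {}) or {},
        sample_adjustments=raw.get("sample_adjustments", []) or [],
        notation_equivalences=raw.get("notation_equivalences", {}) or {},
        excluded_samples=raw.get("excluded_samples", []) or [],
    )


def normalize_for_comparison(
    diplotype: str, gene: str, ledger: ComparisonLedger | None = None, sample: str | None = None
) -> str:
    """Canonical comparison form of a diplotype string.

    Applies, in order: legacy-notation canonicalization, the trisomy
    duplicated-allele drop (for ledgered sample/gene pairs on three-allele
    calls), ignored-allele surrogacy, and canonical allele ordering.
    """
    ledger = ledger or ComparisonLedger()
    if diplotype == "Indeterminate":
        return diplotype
    parts = diplotype.split("/")
    equiv = ledger.notation_equivalences.get(gene, {})
    parts = [equiv[p]["canonical"] if p in equiv else p for p in parts]
    if len(parts) == 3 and sample is not None and ledger.drops_duplicate(sample, gene):
        for i, p in enumerate(parts):
            if parts.count(p) > 1:
                parts.pop(i)
                break
    ignored = ledger.ignored_alleles.get(gene, {})
    parts = [ignored[p]["surrogate"] if p in ignored else p for p in parts]
    if len(parts) == 2:
        parts = list(order_alleles(parts[0], parts[1]))
    else:
        parts = sorted(parts)
    return "/".join(parts)


def _as_mapping(calls) -> dict[tuple[str, str], str]:
    """Accept {(sample, gene): value} or an iterable of (sample, gene, value)."""
    if isinstance(calls, dict):
        return dict(calls)
    return {(s, g): v for s, g, v in calls}


@dataclass
class DiplotypeConcordance:
    """Whole-call agreement over shared (sample, gene) keys."""

    total: int
    concordant: int
    discrepancies: list[dict]

    @property
    def rate(self) -> float:
        return self.concordant / self.total

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in DISCREPANCY_CATEGORIES}
        for d in self.discrepancies:
            out[d["category"]] += 1
        return out


def _concordance(set_a, set_b, ledger, evidence, annotate_indeterminate=False) -> DiplotypeConcordance:
    a = _as_mapping(set_a)
    b = _as_mapping(set_b)
    ledger = ledger or ComparisonLedger()
    keys = sorted(
        k for k in (set(a) & set(b)) if k[0] not in ledger.excluded_ids
    )
    if not keys:
        raise ComparisonError("no shared (sample, gene) keys between call sets")
    evidence = evidence or {}
    concordant = 0
    discrepancies = []
    for sample, gene in keys:
        va = normalize_for_comparison(a[(sample, gene)], gene, ledger, sample)
        vb = normalize_for_comparison(b[(sample, gene)], gene, ledger, sample)
        if va == vb:
            concordant += 1
            continue
        category = evidence.get((sample, gene), "other")
        if category not in DISCREPANCY_CATEGORIES:
            raise ComparisonError(f"unknown discrepancy category {category!r}")
        rec = {"sample": sample, "gene": gene, "a": va, "b": vb, "category": category}
        if annotate_indeterminate and "Indeterminate" in (va, vb):
            rec["note"] = "one side Indeterminate (unknown/uncertain-function allele)"
        discrepancies.append(rec)
    return DiplotypeConcordance(total=len(keys), concordant=concordant, discrepancies=discrepancies)


def diplotype_concordance(set_a, set_b, ledger: ComparisonLedger | None = None, evidence=None) -> DiplotypeConcordance:
    """Diplotype agreement rate after ledger normalization.

    ``set_a``/``set_b`` map (sample, gene) to diplotype strings; ``evidence``
    optionally maps keys to a discrepancy category.
    """
    return _concordance(set_a, set_b, ledger, evidence)


def phenotype_concordance(set_a, set_b, ledger: ComparisonLedger | None = None, evidence=None) -> DiplotypeConcordance:
    """Phenotype-label agreement rate; Indeterminate-driven mismatches annotated."""
    return _concordance(set_a, set_b, ledger, evidence, annotate_indeterminate=True)
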