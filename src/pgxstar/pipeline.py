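"""End-to-end cohort genotyping: depth + variants -> diplotypes + phenotypes."""

from __future__ import annotations

import pandas as pd

from .catalog import GeneDefinition, TranslationTable
from .covdepth import (
    DepthMatrix,
    allele_fraction_profile,
    compute_control_statistics,
    copy_number_profile,
)
from .genotyper import DiplotypeCall, assign_diplotype, phase_variants
from .phenotype import SUPPORTED_GENES, predict_phenotype
from .svcall import SVClassifier, classify_sv, featurize_profile
from .vario import VariantTable

__all__ = ["genotype_cohort", "calls_to_frame"]


def genotype_cohort(
    gene_def: GeneDefinition,
    control_def: GeneDefinition,
    table: TranslationTable,
    variants: VariantTable,
    depth: DepthMatrix,
    classifier: SVClassifier,
    cohort_mode: str = "all_samples",
    no_sv_ids: list[str] | None = None,
    phasing_mode: str = "match",
    bin_bp: int = 500,
) -> dict[str, DiplotypeCall]:
    """Run the full calling path for every sample in the cohort.

    Normalizes depth to copy number, classifies the SV configuration,
    phases and matches small variants, and integrates the evidence into one
    diplotype call per sample.  Phasing-mode provenance is recorded on every
    call.
    """
    cstats = compute_control_statistics(depth, control_def)
    profiles = copy_number_profile(
        depth, gene_def, cstats, cohort_mode=cohort_mode, no_sv_ids=no_sv_ids
    )
    haplotypes = phase_variants(variants, gene_def, table, mode=phasing_mode)
    calls: dict[str, DiplotypeCall] = {}
    for sample in variants.samples:
        if sample not in profiles:
            continue
        feats = featurize_profile(profiles[sample], gene_def, bin_bp=bin_bp)
        sv = classify_sv(classifier, feats)
        af = allele_fraction_profile(variants, sample, gene_def)
        call = assign_diplotype(haplotypes[sample], sv, af, table)
        call.evidence["phasing_mode"] = phasing_mode
        call.evidence["normalization"] = profiles[sample].provenance
        calls[sample] = call
    return calls


def calls_to_frame(calls: dict[str, DiplotypeCall], with_phenotype: bool = True) -> pd.DataFrame:
    """Tabulate calls (sample, gene, diplotype, phenotype, sv_class, confidence)."""
    rows = []
    for sample, call in sorted(calls.items()):
        rec = {
            "sample": sample,
            "gene": call.gene,
            "diplotype": call.diplotype,
            "sv_class": call.evidence.get("sv_class"),
            "confidence": call.confidence,
        }
        if with_phenotype:
            if call.gene in SUPPORTED_GENES:
                rec["phenotype"] = predict_phenotype(call.gene, call.diplotype).phenotype
            else:
                rec["phenotype"] = "no phenotype table"
        rows.append(rec)
    return pd.DataFrame(rows)
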