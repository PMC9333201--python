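"""CPIC phenotype prediction from diplotypes.

Nine genes carry a genotype-phenotype table: three (CYP2C9, CYP2D6, DPYD)
use an *activity score* -- each allele contributes a value (1 normal, 0.5
decreased, 0 no function; an ``xN`` copy suffix multiplies the value by N)
and the diplotype's score is the sum over both alleles, binned into
metabolizer categories.  The other six use a direct diplotype-to-phenotype
map.  Any allele whose function is unknown or uncertain forces an
Indeterminate phenotype.  Bins and tables ship as editable data files, not
code, so alternative guideline releases can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .catalog import packaged_data_path, parse_copy_suffix
from .errors import PhenotypeError
from .genotyper import order_alleles

__all__ = [
    "SCORE_GENES",
    "SUPPORTED_GENES",
    "ActivityTable",
    "PhenotypeResult",
    "load_activity_table",
    "load_phenotype_bins",
    "load_phenotype_map",
    "activity_score",
    "predict_phenotype",
]

SCORE_GENES = ("CYP2C9", "CYP2D6", "DPYD")
MAP_GENES = ("CYP2B6", "CYP2C19", "CYP3A5", "SLCO1B1", "TPMT", "UGT1A1")
SUPPORTED_GENES = tuple(sorted(SCORE_GENES + MAP_GENES))

INDETERMINATE = "Indeterminate"


@dataclass
class ActivityTable:
    """gene -> {allele name -> activity value}; values are per single copy."""

    values: dict[str, dict[str, float]]

    def lookup(self, gene: str, allele: str) -> float | None:
        """Activity of one allele, applying the xN copy-suffix multiplier.

        Returns None when the allele (or its base form) has no assigned
        value -- unknown-function alleles never get one.
        """
        table = self.values.get(gene, {})
        if allele in table:
            return table[allele]
        base, copies = parse_copy_suffix(allele)
        if base in table:
            return table[base] * copies
        return None


def load_activity_table(source=None) -> ActivityTable:
    if source is None:
        source = packaged_data_path("activity_values.tsv")
    df = pd.read_csv(source, sep="\t", comment="#")
    values: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        if row.value < 0:
            raise PhenotypeError(f"{row.gene}{row.allele}: negative activity value")
        values.setdefault(row.gene, {})[row.allele] = float(row.value)
    return ActivityTable(values=values)


def load_phenotype_bins(source=None) -> dict[str, list[tuple[float, float, str]]]:
    """Per-gene (lo, hi, label) score bins; lo < score <= hi, first bin closed at lo."""
    if source is None:
        source = packaged_data_path("phenotype_bins.tsv")
    df = pd.read_csv(source, sep="\t", comment="#")
    bins: dict[str, list[tuple[float, float, str]]] = {}
    for row in df.itertuples(index=False):
        hi = math.inf if row.hi == "inf" else float(row.hi)
        bins.setdefault(row.gene, []).append((float(row.lo), hi, row.phenotype))
    for gene, rows in bins.items():
        rows.sort()
        if rows[0][0] != 0:
            raise PhenotypeError(f"{gene}: bins must start at 0")
    return bins


def load_phenotype_map(source=None) -> dict[str, dict[str, str]]:
    if source is None:
        source = packaged_data_path("phenotype_maps.tsv")
    df = pd.read_csv(source, sep="\t", comment="#")
    out: dict[str, dict[str, str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene, {})[row.diplotype] = row.phenotype
    return out


@dataclass
class PhenotypeResult:
    gene: str
    diplotype: str
    phenotype: str
    activity_score: float | None = None
    reason: str | None = None


def _split_diplotype(diplotype: str) -> tuple[str, str]:
    parts = diplotype.split("/")
    if len(parts) != 2:
        raise PhenotypeError(f"cannot parse diplotype {diplotype!r}")
    return parts[0], parts[1]


def activity_score(gene: str, diplotype: str, t: ActivityTable | None = None) -> float | None:
    """Sum of the two alleles' activity values, or None when undefined.

    Undefined when either allele carries no assigned value (e.g. unknown
    function).  Symmetric in allele order.
    """
    if gene not in SCORE_GENES:
        raise PhenotypeError(f"{gene} is not an activity-score gene {SCORE_GENES}")
    t = t or load_activity_table()
    a1, a2 = _split_diplotype(diplotype)
    v1, v2 = t.lookup(gene, a1), t.lookup(gene, a2)
    if v1 is None or v2 is None:
        return None
    return v1 + v2


def _bin_score(score: float, bins: list[tuple[float, float, str]]) -> str:
    for i, (lo, hi, label) in enumerate(bins):
        if (score == lo and i == 0) or lo < score <= hi:
            return label
    raise PhenotypeError(f"score {score} falls outside the configured bins")


def predict_phenotype(gene: str, diplotype: str, tables: dict | None = None) -> PhenotypeResult:
    """Translate a diplotype into its CPIC phenotype.

    ``tables`` may pre-load {"activity", "bins", "map"}.  Genes outside the
    nine supported ones raise; use batch helpers for a soft "no phenotype
    table" result.
    """
    if gene not in SUPPORTED_GENES:
        raise PhenotypeError(f"no genotype-phenotype table for {gene}; supported: {SUPPORTED_GENES}")
    tables = tables or {}
    if diplotype == INDETERMINATE:
        return PhenotypeResult(gene, diplotype, INDETERMINATE, reason="indeterminate diplotype")
    a1, a2 = _split_diplotype(diplotype)
    canonical = "%s/%s" % order_alleles(a1, a2)
    if gene in SCORE_GENES:
        activity = tables.get("activity") or load_activity_table()
        score = activity_score(gene, canonical, activity)
        if score is None:
            missing = [a for a in (a1, a2) if activity.lookup(gene, a) is None]
            return PhenotypeResult(
                gene,
                canonical,
                INDETERMINATE,
                reason=f"no activity value (unknown/uncertain function): {', '.join(missing)}",
            )
        bins = (tables.get("bins") or load_phenotype_bins())[gene]
        return PhenotypeResult(gene, canonical, _bin_score(score, bins), activity_score=score)
    mapping = (tables.get("map") or load_phenotype_map()).get(gene, {})
    label = mapping.get(canonical)
    if label is None:
        return PhenotypeResult(
            gene, canonical, INDETERMINATE, reason="diplotype absent from genotype-phenotype map"
        )
    return PhenotypeResult(gene, canonical, label)
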