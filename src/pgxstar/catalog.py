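"""Gene-panel and star-allele catalogs.

A *star allele* is a named haplotype pattern of a pharmacogene (e.g.
``CYP2D6*4``), defined by a set of SNVs/indels and/or a structural-variant
tag (whole-gene deletion, duplication, multiplication, or gene-pseudogene
hybrid).  This module loads and validates three kinds of tabular catalogs:

* the panel catalog -- one row per targeted gene with probe design, probe
  size, per-batch mean coverage, and guideline gene-drug-pair counts;
* the star-allele summary catalog -- per gene, the reference allele, the
  alleles observed in the validation cohort (with SV annotations), and the
  alleles absent from earlier publications;
* haplotype translation tables -- per gene, each allele's defining-variant
  set, function label, and SV tag, used for genotype matching.

Packaged fixtures live under :mod:`pgxstar.data`.  The translation tables
shipped there are a synthetic stand-in for an external nomenclature
resource (see the file header of ``synthetic_translation.tsv``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import CatalogError

__all__ = [
    "VariantKey",
    "StarAllele",
    "GeneDefinition",
    "PanelCatalog",
    "TranslationTable",
    "SampleInfo",
    "packaged_data_path",
    "load_gene_models",
    "load_panel_catalog",
    "load_translation_tables",
    "load_translation_table",
    "load_star_allele_catalog",
    "summarize_guideline_coverage",
    "summarize_allele_catalog",
    "parse_copy_suffix",
]

FUNCTION_LABELS = {
    "normal",
    "decreased",
    "no_function",
    "increased",
    "unknown",
    "uncertain",
    "unassigned",
}

SV_TAGS = {"none", "del", "dup", "mult", "hyb"}

# trailing copy suffix only: "*2x2" parses, "*36x2+*10" does not
_COPY_SUFFIX_RE = re.compile(r"^(?P<base>.+?)x(?P<n>\d+)$")


def parse_copy_suffix(name: str) -> tuple[str, int]:
    """Split a trailing ``xN`` copy suffix off an allele name.

    Returns ``(base_name, copies)`` where ``copies`` is 1 when no suffix is
    present.  Only a suffix at the very end of the name counts, so tandem
    hybrid names like ``*36x2+*10`` are left intact.
    """
    m = _COPY_SUFFIX_RE.match(name)
    if m:
        return m.group("base"), int(m.group("n"))
    return name, 1


@dataclass(frozen=True, order=True)
class VariantKey:
    """A biallelic variant in ``chrom-pos-ref-alt`` notation (1-based, VCF-style alleles)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise CatalogError(f"empty ref/alt in variant {self.chrom}-{self.pos}-{self.ref}-{self.alt}")
        if self.ref == self.alt:
            raise CatalogError(f"ref == alt in variant {self.chrom}-{self.pos}-{self.ref}")
        if self.pos < 1:
            raise CatalogError(f"non-positive position in variant {self!r}")

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        parts = text.strip().split("-")
        if len(parts) != 4:
            raise CatalogError(f"cannot parse variant key {text!r}; expected chrom-pos-ref-alt")
        chrom, pos, ref, alt = parts
        try:
            pos_i = int(pos)
        except ValueError as exc:
            raise CatalogError(f"non-integer position in variant key {text!r}") from exc
        return cls(chrom, pos_i, ref, alt)

    def render(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class StarAllele:
    """A named haplotype pattern with defining variants and an SV tag."""

    gene: str
    name: str
    defining_variants: frozenset[VariantKey] = frozenset()
    function: str = "unassigned"
    sv_tag: str = "none"
    sv_copies: int = 1
    sv_partner: str | None = None

    def __post_init__(self) -> None:
        if self.function not in FUNCTION_LABELS:
            raise CatalogError(f"unknown function label {self.function!r} for {self.gene}{self.name}")
        if self.sv_tag not in SV_TAGS:
            raise CatalogError(f"unknown sv tag {self.sv_tag!r} for {self.gene}{self.name}")
        if self.sv_tag == "mult" and self.sv_copies < 3:
            raise CatalogError(f"mult allele {self.gene}{self.name} must carry >= 3 copies")

    @property
    def has_sv(self) -> bool:
        return self.sv_tag != "none"


@dataclass(frozen=True)
class GeneDefinition:
    """A targeted gene: locus, probe design, and control eligibility."""

    symbol: str
    chromosome: str
    region: tuple[int, int] | None = None
    design: str = "exon"
    probe_kb: float = 1.0
    reference_allele_name: str = "*1"
    pseudogene_region: tuple[int, int] | None = None
    pseudogene_symbol: str | None = None
    control_eligible: bool = False

    def __post_init__(self) -> None:
        if self.region is not None and self.region[0] > self.region[1]:
            raise CatalogError(f"{self.symbol}: region start > end")
        if self.probe_kb <= 0:
            raise CatalogError(f"{self.symbol}: probe_kb must be positive")
        if self.pseudogene_region is not None and self.design != "custom":
            raise CatalogError(f"{self.symbol}: pseudogene capture requires the custom design")

    def contains(self, v: VariantKey) -> bool:
        """True if the variant lies in the gene (or captured pseudogene) region."""
        # tolerate "chr22" vs "22"
        if v.chrom.removeprefix("chr") != self.chromosome.removeprefix("chr"):
            return False
        for interval in (self.region, self.pseudogene_region):
            if interval and interval[0] <= v.pos <= interval[1]:
                return True
        return False


@dataclass
class PanelCatalog:
    """The full targeted panel: gene definitions plus per-gene guideline counts."""

    genes: list[GeneDefinition]
    counts: pd.DataFrame  # indexed by gene symbol

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]


@dataclass
class TranslationTable:
    """Per-gene haplotype translation table mapping variant sets to star alleles."""

    gene: str
    alleles: list[StarAllele]
    reference_name: str
    novel_alleles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.alleles]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CatalogError(f"{self.gene}: duplicate allele names {dupes}")
        refs = [a for a in self.alleles if a.name == self.reference_name]
        if len(refs) != 1:
            raise CatalogError(f"{self.gene}: reference allele {self.reference_name!r} not found exactly once")
        ref = refs[0]
        if ref.defining_variants or ref.sv_tag != "none":
            raise CatalogError(f"{self.gene}: reference allele must have no defining variants and no SV tag")

    @property
    def reference(self) -> StarAllele:
        return next(a for a in self.alleles if a.name == self.reference_name)

    def get(self, name: str) -> StarAllele:
        for a in self.alleles:
            if a.name == name:
                return a
        raise CatalogError(f"{self.gene}: no allele named {name!r}")

    @property
    def deletion_allele(self) -> StarAllele | None:
        for a in self.alleles:
            if a.sv_tag == "del":
                return a
        return None


@dataclass(frozen=True)
class SampleInfo:
    """Cohort bookkeeping: population, sequencing batch, and per-gene no-SV flags."""

    sample_id: str
    population: str = "NA"
    batch: str = "Set 1"
    known_no_sv: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# loaders


def packaged_data_path(name: str) -> Path:
    """Path to a packaged data fixture (e.g. ``panel_genes.tsv``)."""
    return Path(str(resources.files("pgxstar.data").joinpath(name)))


def _read_tsv(source) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t", comment="#", dtype=str, keep_default_na=False)


def load_gene_models(source=None) -> dict[str, GeneDefinition]:
    """Load gene/pseudogene intervals (packaged synthetic models by default)."""
    if source is None:
        source = packaged_data_path("synthetic_gene_models.tsv")
    df = _read_tsv(source)
    models: dict[str, GeneDefinition] = {}
    for row in df.itertuples(index=False):
        pseudo = None
        if row.pseudo_start and row.pseudo_end:
            pseudo = (int(row.pseudo_start), int(row.pseudo_end))
        models[row.gene] = GeneDefinition(
            symbol=row.gene,
            chromosome=row.chrom,
            region=(int(row.gene_start), int(row.gene_end)),
            design="custom" if pseudo else "exon",
            probe_kb=(int(row.gene_end) - int(row.gene_start) + 1) / 1000.0,
            pseudogene_region=pseudo,
            pseudogene_symbol=row.pseudogene or None,
            control_eligible=row.control_eligible == "1",
        )
    return models


def load_panel_catalog(source=None) -> PanelCatalog:
    """Load the panel catalog (packaged 59-gene table by default)."""
    if source is None:
        source = packaged_data_path("panel_genes.tsv")
    df = _read_tsv(source)
    required = {"gene", "chrom", "probe_kb", "design", "cpic_pairs", "cpic_a_pairs", "fda_pairs"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"panel catalog missing columns: {sorted(missing)}")
    genes = []
    rows = []
    for row in df.itertuples(index=False):
        try:
            counts = {
                c: int(getattr(row, c)) for c in ("cpic_pairs", "cpic_a_pairs", "fda_pairs")
            }
        except ValueError as exc:
            raise CatalogError(f"{row.gene}: malformed count field") from exc
        if any(v < 0 for v in counts.values()):
            raise CatalogError(f"{row.gene}: negative guideline pair count")
        genes.append(
            GeneDefinition(
                symbol=row.gene,
                chromosome=row.chrom,
                design=row.design,
                probe_kb=float(row.probe_kb),
                control_eligible=row.gene in ("EGFR", "RYR1", "VDR"),
            )
        )
        rec = {"gene": row.gene, **counts}
        for col in ("set1_mean", "set2_mean"):
            if col in df.columns:
                rec[col] = float(getattr(row, col))
        rows.append(rec)
    counts_df = pd.DataFrame(rows).set_index("gene")
    return PanelCatalog(genes=genes, counts=counts_df)


def _parse_sv_from_annotation(name: str, annotation: str | None) -> tuple[str, int, str | None]:
    base, copies = parse_copy_suffix(name)
    tag = annotation or "none"
    if tag == "dup" and copies >= 3:
        tag = "mult"
    if tag == "mult" and copies < 3:
        raise CatalogError(f"allele {name}: mult tag requires >= 3 copies")
    return tag, copies, None


def load_star_allele_catalog(source=None) -> list[TranslationTable]:
    """Load the per-gene star-allele summary catalog (packaged 27-gene table by default).

    Each row lists the gene's reference allele, every allele observed in the
    validation cohort (SV-defined ones annotated ``(del)``, ``(dup)`` or
    ``(hyb)``), and alleles absent from earlier publications.  Defining
    variants are not part of this summary, so the returned
    :class:`TranslationTable` records carry empty defining sets.
    """
    if source is None:
        source = packaged_data_path("star_allele_catalog.tsv")
    df = _read_tsv(source)
    tables = []
    seen = set()
    for row in df.itertuples(index=False):
        if row.gene in seen:
            raise CatalogError(f"duplicate gene {row.gene} in star-allele catalog")
        seen.add(row.gene)
        alleles = []
        for entry in str(row.alleles_reported).split(","):
            entry = entry.strip()
            if not entry:
                continue
            m = re.match(r"^(?P<name>.+?)(?:\s+\((?P<sv>del|dup|hyb)\))?$", entry)
            name = m.group("name").strip()
            tag, copies, partner = _parse_sv_from_annotation(name, m.group("sv"))
            alleles.append(
                StarAllele(
                    gene=row.gene,
                    name=name,
                    sv_tag=tag,
                    sv_copies=copies if tag in ("dup", "mult") else 1,
                    sv_partner=partner,
                )
            )
        novel = [s.strip() for s in str(row.alleles_previously_not_reported).split(",") if s.strip()]
        tables.append(
            TranslationTable(
                gene=row.gene,
                alleles=alleles,
                reference_name=row.reference_allele,
                novel_alleles=novel,
            )
        )
    return tables


def load_translation_tables(source=None, models: dict[str, GeneDefinition] | None = None) -> dict[str, TranslationTable]:
    """Load full haplotype translation tables (defining variants included).

    When ``models`` is given, every defining variant is checked to lie in its
    gene's (or captured pseudogene's) region.
    """
    if source is None:
        source = packaged_data_path("synthetic_translation.tsv")
        if models is None:
            models = load_gene_models()
    df = _read_tsv(source)
    required = {"gene", "allele", "defining_variants", "function", "sv_tag"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"translation table missing columns: {sorted(missing)}")
    per_gene: dict[str, list[StarAllele]] = {}
    for row in df.itertuples(index=False):
        variants = frozenset(
            VariantKey.parse(v) for v in str(row.defining_variants).split(",") if v.strip()
        )
        tag_field = row.sv_tag or "none"
        partner = None
        if ":" in tag_field:
            tag_field, partner = tag_field.split(":", 1)
        base, copies = parse_copy_suffix(row.allele)
        if tag_field == "dup" and copies < 2:
            copies = 2
        if tag_field == "mult" and copies < 3:
            raise CatalogError(f"{row.gene}{row.allele}: mult tag requires xN suffix with N >= 3")
        allele = StarAllele(
            gene=row.gene,
            name=row.allele,
            defining_variants=variants,
            function=row.function or "unassigned",
            sv_tag=tag_field,
            sv_copies=copies if tag_field in ("dup", "mult") else 1,
            sv_partner=partner,
        )
        if models and row.gene in models:
            model = models[row.gene]
            for v in variants:
                if not model.contains(v):
                    raise CatalogError(f"{row.gene}{row.allele}: variant {v.render()} outside gene region")
        per_gene.setdefault(row.gene, []).append(allele)

    tables = {}
    for gene, alleles in per_gene.items():
        refs = [a for a in alleles if not a.defining_variants and a.sv_tag == "none"]
        if not refs:
            raise CatalogError(f"{gene}: no reference allele (empty defining set, no SV)")
        tables[gene] = TranslationTable(gene=gene, alleles=alleles, reference_name=refs[0].name)
    return tables


def load_translation_table(source=None, gene: str | None = None, models=None) -> TranslationTable:
    """Load a single gene's translation table (the file's only gene, or ``gene``)."""
    tables = load_translation_tables(source, models=models)
    if gene is not None:
        if gene not in tables:
            raise CatalogError(f"gene {gene!r} not present in translation file")
        return tables[gene]
    if len(tables) != 1:
        raise CatalogError(f"file contains {len(tables)} genes; specify which one")
    return next(iter(tables.values()))


# ---------------------------------------------------------------------------
# summaries


def summarize_guideline_coverage(catalog: PanelCatalog) -> dict:
    """Column sums of guideline gene-drug-pair counts over the panel.

    Sums are computed by enumeration over rows (order-invariant).  The
    level-A sum is a raw per-gene column total; guidelines spanning several
    genes may be counted once per gene, so this total can exceed the number
    of distinct level-A pairs.
    """
    if len(catalog) == 0:
        raise CatalogError("empty panel catalog")
    sums = {c: int(catalog.counts[c].sum()) for c in ("cpic_pairs", "cpic_a_pairs", "fda_pairs")}
    sums["n_genes"] = len(catalog)
    sums["notes"] = [
        "cpic_a_pairs is a raw per-gene column sum; multigene guidelines may be counted more than once"
    ]
    return sums


def summarize_allele_catalog(tables: list[TranslationTable]) -> dict:
    """Enumerate allele counts over per-gene tables.

    Returns ``unique_alleles`` (all reported alleles), ``sv_alleles`` /
    ``sv_genes`` (SV-defined alleles and genes carrying at least one), and
    ``novel_alleles`` / ``novel_genes`` (alleles flagged as previously
    unreported).  All counts are derived by enumeration, never stored.
    """
    genes = [t.gene for t in tables]
    if len(genes) != len(set(genes)):
        raise CatalogError("duplicate gene symbols across translation tables")
    unique = sum(len(t.alleles) for t in tables)
    sv_per_gene = {t.gene: sum(1 for a in t.alleles if a.has_sv) for t in tables}
    novel_per_gene = {t.gene: len(t.novel_alleles) for t in tables}
    return {
        "unique_alleles": unique,
        "sv_alleles": sum(sv_per_gene.values()),
        "sv_genes": sum(1 for v in sv_per_gene.values() if v > 0),
        "novel_alleles": sum(novel_per_gene.values()),
        "novel_genes": sum(1 for v in novel_per_gene.values() if v > 0),
    }
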