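"""Depth-of-coverage metrics and copy-number normalization.

Copy number at a targeted position is estimated in two steps.  Intra-sample
normalization divides per-base depth by a per-sample location statistic of
depth over a control gene (a large locus with negligible copy-number
polymorphism, e.g. VDR) and scales to the diploid state::

    cn_raw(s, p) = 2 * depth(s, p) / control_stat(s)

For capture panels, whose per-position efficiency varies, inter-sample
normalization then rescales each position so that a cohort reference track
(the per-position median of ``cn_raw`` over a designated sample set) sits at
copy number 2::

    cn(s, p) = cn_raw(s, p) * 2 / median_{s' in ref set} cn_raw(s', p)

The reference set is either all samples or only samples known to carry no
structural variant in the gene -- the latter is essential for genes where
deletion carriers are the majority of the cohort (e.g. GSTT1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import GeneDefinition
from .errors import DepthError
from .vario import VariantTable, read_bed

__all__ = [
    "DepthMatrix",
    "CoverageSummary",
    "ControlStats",
    "CopyNumberProfile",
    "AlleleFractionProfile",
    "read_depth_matrix",
    "write_depth_matrix",
    "coverage_summary",
    "compute_control_statistics",
    "copy_number_profile",
    "allele_fraction_profile",
]


@dataclass
class DepthMatrix:
    """Read depths: rows are (chrom, pos) targeted positions, columns samples."""

    df: pd.DataFrame  # MultiIndex (chrom, pos) x samples

    def __post_init__(self) -> None:
        if (self.df.values < 0).any():
            raise DepthError("negative depths")
        self.df = self.df.sort_index()

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def restrict(self, gene: GeneDefinition) -> pd.DataFrame:
        """Rows inside the gene's (and captured pseudogene's) region."""
        chroms = np.array(
            [str(c).removeprefix("chr") for c in self.df.index.get_level_values(0)]
        )
        pos = self.df.index.get_level_values(1).to_numpy()
        mask = np.zeros(len(self.df), dtype=bool)
        for interval in (gene.region, gene.pseudogene_region):
            if interval:
                mask |= (
                    (chroms == gene.chromosome.removeprefix("chr"))
                    & (pos >= interval[0])
                    & (pos <= interval[1])
                )
        return self.df[mask]


def read_depth_matrix(path, bed=None) -> DepthMatrix:
    """Read a per-base depth TSV (columns: chrom, pos, one column per sample).

    Positions are 1-based (matching VCF).  When ``bed`` intervals (0-based,
    half-open) are given, positions outside them are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise DepthError("depth file must have 'chrom' and 'pos' columns")
    sample_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    if not sample_cols:
        raise DepthError("depth file has no sample columns")
    for c in sample_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise DepthError(f"non-numeric depth in column {c!r}")
    if bed is not None:
        if not isinstance(bed, list):
            bed = read_bed(bed)
        keep = np.zeros(len(df), dtype=bool)
        chrom_stripped = df["chrom"].astype(str).str.removeprefix("chr")
        for rchrom, start, end in bed:
            keep |= (
                (chrom_stripped == rchrom.removeprefix("chr"))
                & (df["pos"] > start)
                & (df["pos"] <= end)
            ).to_numpy()
        dropped = int((~keep).sum())
        if dropped:
            warnings.warn(f"dropping {dropped} positions outside target BED")
        df = df[keep]
        if df.empty:
            raise DepthError("no targeted positions after BED restriction")
    df = df.set_index(["chrom", "pos"])[sample_cols]
    return DepthMatrix(df=df.astype(float))


def write_depth_matrix(d: DepthMatrix, path) -> None:
    d.df.reset_index().to_csv(path, sep="\t", index=False)


@dataclass
class CoverageSummary:
    """Cohort and per-sample coverage plus depth-uniformity fractions."""

    mean_depth: float
    per_sample_mean: pd.Series
    fraction_ge: dict[float, float]  # threshold -> fraction of base-sample cells
    per_gene_mean: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "mean_depth": self.mean_depth,
            "per_sample_mean": self.per_sample_mean.to_dict(),
            "fraction_ge": {str(k): v for k, v in self.fraction_ge.items()},
        }


def coverage_summary(d: DepthMatrix, thresholds=(30, 100), genes: list[GeneDefinition] | None = None) -> CoverageSummary:
    """Arithmetic mean depth over all targeted base-sample cells and the
    fraction of cells at or above each threshold (monotone in threshold)."""
    if d.df.empty:
        raise DepthError("empty depth matrix")
    if any(t <= 0 for t in thresholds):
        raise DepthError("thresholds must be positive")
    values = d.df.to_numpy(dtype=float)
    fraction = {float(t): float((values >= t).mean()) for t in thresholds}
    per_gene = None
    if genes:
        per_gene = pd.DataFrame(
            {g.symbol: d.restrict(g).mean() for g in genes if not d.restrict(g).empty}
        ).T
    return CoverageSummary(
        mean_depth=float(values.mean()),
        per_sample_mean=d.df.mean(),
        fraction_ge=fraction,
        per_gene_mean=per_gene,
    )


@dataclass
class ControlStats:
    """Per-sample location statistic of depth over the control gene."""

    control_gene: str
    statistic: pd.Series  # per sample
    usable: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.usable is None:
            self.usable = self.statistic > 0


def compute_control_statistics(d: DepthMatrix, control_gene: GeneDefinition) -> ControlStats:
    """Per-sample median depth over the control locus.

    The median is robust to focal CNVs inside the control gene.  Samples
    with an all-zero control region are marked unusable.
    """
    sub = d.restrict(control_gene)
    if sub.empty:
        raise DepthError(f"control gene {control_gene.symbol} absent from depth matrix")
    stat = sub.median()
    return ControlStats(control_gene=control_gene.symbol, statistic=stat)


@dataclass
class CopyNumberProfile:
    """Per-position copy-number estimates for one sample over one gene region."""

    sample: str
    gene: str
    positions: np.ndarray  # 1-based
    values: np.ndarray  # copy number, NaN at masked positions
    provenance: dict = field(default_factory=dict)

    def mean_over(self, start: int, end: int) -> float:
        sel = (self.positions >= start) & (self.positions <= end)
        return float(np.nanmean(self.values[sel]))


def copy_number_profile(
    d: DepthMatrix,
    gene: GeneDefinition,
    c: ControlStats,
    cohort_mode: str = "all_samples",
    no_sv_ids: list[str] | None = None,
    dropout_fraction: float = 0.5,
) -> dict[str, CopyNumberProfile]:
    """Two-step copy-number normalization for every usable sample.

    ``cohort_mode`` selects the inter-sample reference set: ``all_samples``
    or ``no_sv_samples`` (requires ``no_sv_ids``, samples known to be
    diploid-normal in this gene).  Positions with zero depth in more than
    ``dropout_fraction`` of samples are masked as capture dropouts.  Copy
    numbers are reported unrounded.
    """
    if cohort_mode not in ("all_samples", "no_sv_samples"):
        raise DepthError(f"unknown cohort mode {cohort_mode!r}")
    if cohort_mode == "no_sv_samples" and not no_sv_ids:
        raise DepthError("no_sv_samples mode requires a non-empty no_sv_ids list")
    sub = d.restrict(gene)
    if sub.empty:
        raise DepthError(f"gene {gene.symbol} absent from depth matrix")

    usable = [s for s in sub.columns if c.usable.get(s, False)]
    skipped = [s for s in sub.columns if s not in usable]
    if skipped:
        warnings.warn(f"excluding samples with zero control statistic: {skipped}")
    if not usable:
        raise DepthError("no usable samples (control statistic is zero everywhere)")
    sub = sub[usable]

    # intra-sample normalization
    cn_raw = 2.0 * sub / c.statistic[usable]

    # capture-dropout mask
    masked = (sub == 0).mean(axis=1) > dropout_fraction

    # inter-sample normalization against the cohort reference track
    ref_ids = usable if cohort_mode == "all_samples" else [s for s in no_sv_ids if s in usable]
    if not ref_ids:
        raise DepthError("no usable reference samples for inter-sample normalization")
    reference = cn_raw[ref_ids].median(axis=1)
    masked |= reference <= 0
    cn = cn_raw.mul(2.0 / reference.where(~masked), axis=0)
    cn[masked] = np.nan

    positions = sub.index.get_level_values(1).to_numpy()
    provenance = {
        "control_gene": c.control_gene,
        "cohort_mode": cohort_mode,
        "reference_statistic": "per-position median",
        "n_reference_samples": len(ref_ids),
    }
    return {
        s: CopyNumberProfile(
            sample=s,
            gene=gene.symbol,
            positions=positions,
            values=cn[s].to_numpy(dtype=float),
            provenance=dict(provenance),
        )
        for s in usable
    }


@dataclass
class AlleleFractionProfile:
    """Alt-allele fractions at non-homozygous-reference sites with depth."""

    sample: str
    gene: str
    fractions: dict  # VariantKey -> float in [0, 1]
    skipped_sites: int = 0


def allele_fraction_profile(t: VariantTable, sample: str, gene: GeneDefinition) -> AlleleFractionProfile:
    """Alt fraction ``alt / (ref + alt)`` at each non-hom-ref site in the gene.

    Sites with a missing AD field or zero total depth are skipped (counted).
    Fraction clusters discriminate copy configurations: e.g. a duplicated
    haplotype's variants sit near ``extra_copies / total_copies``.
    """
    if sample not in t.samples:
        raise DepthError(f"sample {sample!r} not in variant table")
    fractions: dict = {}
    skipped = 0
    for site in t.sites:
        if not gene.contains(site.key):
            continue
        call = t.genotype(site, sample)
        if call.is_missing or not call.is_nonref:
            continue
        if call.ad is None or sum(call.ad) == 0:
            skipped += 1
            continue
        ref_n, alt_n = call.ad
        fractions[site.key] = alt_n / (ref_n + alt_n)
    return AlleleFractionProfile(sample=sample, gene=gene.symbol, fractions=fractions, skipped_sites=skipped)
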