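"""Synthetic targeted-capture cohorts with ground truth.

The generator emulates the statistical structure the genotyping pipeline
assumes from a hybrid-capture panel:

* per-base depth = base depth x per-sample library-size factor x
  per-position capture efficiency x (copy number / 2), with
  negative-binomial overdispersion (``dispersion`` = 0 gives the exact
  deterministic limit);
* the control locus is always simulated at copy number 2;
* genotypes carry each allele's defining variants, with allelic depths
  drawn binomially with success probability = (copies carrying the
  variant) / (total copies) at that position -- so a duplicated haplotype's
  variants cluster at 2/3, and a 1:3 tandem-multiplication configuration at
  1/4 and 3/4;
* each haplotype additionally carries one "personal" non-catalog marker
  variant (as real haplotypes do), which is what lets downstream logic
  distinguish copy splits such as 1+3 from 2+2 when the catalog variants
  themselves are homozygous.

All randomness flows from a single seed through spawned generators; every
output embeds the seed in its provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import GeneDefinition, TranslationTable, VariantKey, load_gene_models
from .covdepth import DepthMatrix
from .errors import PgxError
from .svcall import (
    SV_CLASSES,
    CNFeatureVector,
    diplotype_cn_track,
    haplotype_cn_track,
)
from .vario import GenotypeCall, Site, VariantTable

__all__ = [
    "SimGeneModel",
    "SimTruth",
    "SimConfig",
    "build_sim_model",
    "simulate_depth",
    "simulate_variant_table",
    "simulate_cohort",
    "make_training_set",
]

DEFAULT_CONTROL = "VDR"


@dataclass
class SimGeneModel:
    """Target-gene capture model: gene/pseudogene/control intervals, stride, efficiency."""

    gene: GeneDefinition
    control: GeneDefinition
    stride: int = 100
    efficiency: dict | None = None  # position -> multiplicative capture efficiency

    def positions(self, include_control: bool = True) -> list[tuple[str, int]]:
        out = []
        for gdef in (self.gene,) + ((self.control,) if include_control else ()):
            for interval in (gdef.region, gdef.pseudogene_region):
                if interval is None:
                    continue
                out.extend(
                    (gdef.chromosome, p) for p in range(interval[0], interval[1] + 1, self.stride)
                )
        return out

    def eff(self, pos: int) -> float:
        if self.efficiency is None:
            return 1.0
        return float(self.efficiency.get(pos, 1.0))

    def gene_frac(self, pos: int) -> float:
        start, end = self.gene.region
        return (pos - start) / (end - start + 1)

    def pseudo_frac(self, pos: int) -> float:
        start, end = self.gene.pseudogene_region
        return (pos - start) / (end - start + 1)


def build_sim_model(gene: str, models: dict[str, GeneDefinition] | None = None, stride: int = 10) -> SimGeneModel:
    """Capture model for one gene using the packaged synthetic gene intervals."""
    models = models or load_gene_models()
    if gene not in models:
        raise PgxError(f"no gene model for {gene!r}")
    return SimGeneModel(gene=models[gene], control=models[DEFAULT_CONTROL], stride=stride)


@dataclass
class SimConfig:
    """Cohort-level simulation settings."""

    n_samples: int = 100
    mean_depth: float = 250.0
    dispersion: float = 0.1  # NB overdispersion; 0 = deterministic limit
    library_sigma: float = 0.2  # lognormal sd of per-sample library factors
    personal_markers: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise PgxError("mean depth must be positive")
        if self.dispersion < 0:
            raise PgxError("dispersion must be >= 0")


@dataclass
class SimTruth:
    """Ground truth for one simulated cohort at one gene."""

    gene: str
    diplotypes: dict[str, tuple[str, str]]  # sample -> (allele1, allele2)
    library_factors: dict[str, float]
    seed: int

    @property
    def samples(self) -> list[str]:
        return list(self.diplotypes)

    def cn_track(self, sample: str, model: SimGeneModel):
        """Expected (gene, pseudogene) copy-number arrays over model positions."""
        gene_pos = np.arange(model.gene.region[0], model.gene.region[1] + 1, model.stride)
        gfr = np.array([model.gene_frac(p) for p in gene_pos])
        pfr = None
        if model.gene.pseudogene_region:
            ppos = np.arange(
                model.gene.pseudogene_region[0], model.gene.pseudogene_region[1] + 1, model.stride
            )
            pfr = np.array([model.pseudo_frac(p) for p in ppos])
        return diplotype_cn_track(self.gene, self.diplotypes[sample], gfr, pfr)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": s,
                "gene": self.gene,
                "allele1": d[0],
                "allele2": d[1],
                "library_factor": self.library_factors[s],
                "seed": self.seed,
            }
            for s, d in self.diplotypes.items()
        ]
        return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Overdispersed counts with var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return mean.copy()  # exact deterministic limit
    r = 1.0 / dispersion
    out = np.zeros_like(mean)
    pos = mean > 0
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def make_truth(gene: str, diplotypes: list[tuple[str, str]], cfg: SimConfig) -> SimTruth:
    """Wrap a list of truth diplotypes with seeded library-size factors."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    samples = [f"S{i:04d}" for i in range(len(diplotypes))]
    factors = np.exp(rng.normal(0.0, cfg.library_sigma, size=len(samples)))
    return SimTruth(
        gene=gene,
        diplotypes=dict(zip(samples, diplotypes)),
        library_factors=dict(zip(samples, factors.round(6))),
        seed=cfg.seed,
    )


def simulate_depth(cfg: SimConfig, model: SimGeneModel, truth: SimTruth) -> DepthMatrix:
    """Simulate a per-base depth matrix over the gene + control positions."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    positions = model.positions()
    control_region = model.control.region
    columns = {}
    for sample in truth.samples:
        gene_cn, pseudo_cn = truth.cn_track(sample, model)
        cn_by_pos: dict[tuple[str, int], float] = {}
        gene_pos = np.arange(model.gene.region[0], model.gene.region[1] + 1, model.stride)
        for p, cn in zip(gene_pos, gene_cn):
            cn_by_pos[(model.gene.chromosome, p)] = cn
        if pseudo_cn is not None:
            ppos = np.arange(
                model.gene.pseudogene_region[0], model.gene.pseudogene_region[1] + 1, model.stride
            )
            for p, cn in zip(ppos, pseudo_cn):
                cn_by_pos[(model.gene.chromosome, p)] = cn
        lib = truth.library_factors[sample]
        means = []
        for chrom, p in positions:
            if chrom == model.control.chromosome and control_region[0] <= p <= control_region[1]:
                cn = 2.0
            else:
                cn = cn_by_pos.get((chrom, p), 2.0)
            means.append(cfg.mean_depth * lib * model.eff(p) * cn / 2.0)
        columns[sample] = _nb_draw(rng, np.array(means), cfg.dispersion)
    idx = pd.MultiIndex.from_tuples(positions, names=["chrom", "pos"])
    return DepthMatrix(df=pd.DataFrame(columns, index=idx))


def _variant_copies(gene: str, allele: str, v: VariantKey, table: TranslationTable, model: SimGeneModel) -> float:
    """Copies of ``v`` contributed by one haplotype carrying ``allele``."""
    record = table.get(allele)
    if v not in record.defining_variants:
        return 0.0
    frac = model.gene_frac(v.pos)
    g, _ = haplotype_cn_track(gene, allele, np.array([frac]), None)
    return float(g[0])


def _personal_marker_keys(model: SimGeneModel, table: TranslationTable) -> list[VariantKey]:
    """Two fixed non-catalog marker positions (one per haplotype)."""
    start, end = model.gene.region
    span = end - start + 1
    catalog_pos = {v.pos for a in table.alleles for v in a.defining_variants}
    keys = []
    for frac, (ref, alt) in ((0.45, ("A", "G")), (0.55, ("C", "T"))):
        pos = start + int(frac * span)
        while pos in catalog_pos:
            pos += 1
        keys.append(VariantKey(model.gene.chromosome, pos, ref, alt))
    return keys


def simulate_variant_table(
    truth: SimTruth,
    table: TranslationTable,
    depth: DepthMatrix,
    model: SimGeneModel,
    cfg: SimConfig,
) -> VariantTable:
    """Genotypes + allelic depths consistent with the truth diplotypes.

    At each site, a sample's ALT depth is Binomial(site depth, c/k) where c
    copies of k total carry the variant; genotypes are het for 0 < c < k and
    hom-alt for c = k.  Samples with no gene copy at a site get a missing
    genotype there.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
    for s, (a1, a2) in truth.diplotypes.items():
        for a in (a1, a2):
            table.get(a)  # raises on unknown allele names

    site_keys: set[VariantKey] = set()
    for a1, a2 in truth.diplotypes.values():
        for a in (a1, a2):
            site_keys.update(table.get(a).defining_variants)
    markers = _personal_marker_keys(model, table) if cfg.personal_markers else []
    ordered = sorted(site_keys | set(markers), key=lambda v: (v.chrom, v.pos, v.ref, v.alt))

    gene_pos_index = depth.df.index
    sites = []
    for key in ordered:
        genotypes = {}
        for sample in truth.samples:
            a1, a2 = truth.diplotypes[sample]
            frac = model.gene_frac(key.pos)
            g1, _ = haplotype_cn_track(truth.gene, a1, np.array([frac]), None)
            g2, _ = haplotype_cn_track(truth.gene, a2, np.array([frac]), None)
            total = float(g1[0] + g2[0])
            if key in markers:
                hap = markers.index(key)  # marker 0 on haplotype 1, marker 1 on haplotype 2
                carrying = float((g1 if hap == 0 else g2)[0])
            else:
                carrying = _variant_copies(truth.gene, a1, key, table, model) + _variant_copies(
                    truth.gene, a2, key, table, model
                )
            if total <= 0:
                genotypes[sample] = GenotypeCall()  # no gene copy: nothing to call
                continue
            # site depth from the nearest simulated position
            snapped = key.pos - (key.pos - model.gene.region[0]) % model.stride
            try:
                dp = int(depth.df.loc[(key.chrom, snapped), sample])
            except KeyError:
                dp = int(cfg.mean_depth)
            alt_n = int(rng.binomial(dp, min(1.0, carrying / total))) if dp > 0 else 0
            if carrying == 0:
                gt = (0, 0)
                alt_n = 0
            elif carrying >= total:
                gt = (1, 1)
                alt_n = dp
            else:
                gt = (0, 1)
            genotypes[sample] = GenotypeCall(alleles=gt, ad=(dp - alt_n, alt_n))
        sites.append(Site(key=key, alts=(key.alt,), genotypes=genotypes))
    _ = gene_pos_index
    return VariantTable(samples=truth.samples, sites=sites)


def simulate_cohort(
    gene: str,
    diplotypes: list[tuple[str, str]],
    cfg: SimConfig,
    table: TranslationTable,
    model: SimGeneModel | None = None,
):
    """Convenience wrapper: truth + depth + variant table for one gene."""
    model = model or build_sim_model(gene)
    truth = make_truth(gene, diplotypes, cfg)
    depth = simulate_depth(cfg, model, truth)
    variants = simulate_variant_table(truth, table, depth, model, cfg)
    return truth, depth, variants


def make_training_set(
    gene: str,
    classes: list[str],
    n_per_class: int,
    cfg: SimConfig,
    seed: int | None = None,
    table: TranslationTable | None = None,
    model: SimGeneModel | None = None,
    bin_bp: int = 500,
) -> tuple[list[CNFeatureVector], list[str]]:
    """Labeled CN feature vectors for a gene's registered SV classes.

    Simulates ``n_per_class`` samples per class (each class's canonical
    carrier diplotype), runs the real normalization path (control-gene
    intra-sample step, then inter-sample normalization referenced on the
    cohort's normal-class samples), and bins the profiles.
    """
    from .covdepth import compute_control_statistics, copy_number_profile
    from .svcall import featurize_profile

    registry = SV_CLASSES.get(gene)
    if registry is None:
        raise PgxError(f"no SV classes registered for gene {gene!r}")
    for cls in classes:
        if cls not in registry:
            raise PgxError(f"class {cls!r} not registered for {gene}")
    if table is None:
        from .catalog import load_translation_tables

        table = load_translation_tables()[gene]
    model = model or build_sim_model(gene)
    if seed is not None:
        cfg = SimConfig(**{**cfg.__dict__, "seed": seed})

    diplos = [registry[cls] for cls in classes for _ in range(n_per_class)]
    labels = [cls for cls in classes for _ in range(n_per_class)]
    truth = make_truth(gene, diplos, cfg)
    depth = simulate_depth(cfg, model, truth)
    cstats = compute_control_statistics(depth, model.control)
    normals = [s for s, lab in zip(truth.samples, labels) if lab == "normal"]
    mode = "no_sv_samples" if normals else "all_samples"
    profiles = copy_number_profile(depth, model.gene, cstats, cohort_mode=mode, no_sv_ids=normals or None)
    features = [featurize_profile(profiles[s], model.gene, bin_bp=bin_bp) for s in truth.samples]
    return features, labels
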