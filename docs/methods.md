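# Methods

## Scope

`pgxstar` genotypes star alleles in pharmacogenes from two inputs a
targeted-capture (or WGS) pipeline produces anyway: a multi-sample VCF of
SNVs/indels with allelic depths, and a per-base depth-of-coverage table
over the panel's target regions. It covers catalog management, variant-set
comparison, copy-number normalization, SVM-based structural-variant (SV)
classification, haplotype matching and diplotype assignment, CPIC
phenotype prediction, call-set concordance with an exclusion ledger, and a
synthetic-data generator that exercises the whole path. Read alignment,
variant calling from reads, statistical population phasing, and HLA typing
are out of scope; phased VCFs are consumed when available and a
deterministic catalog-guided phaser is provided otherwise.

## Copy-number normalization

Intra-sample step: per-base depth over a gene is divided by the sample's
median depth over a control gene and scaled to the diploid state,
`cn_raw(s,p) = 2·depth(s,p)/control_stat(s)`. The median (not the mean) is
used as the control statistic because it is robust to focal CNVs inside
the control locus; VDR is the default control. The entire per-sample
library-size factor cancels in this ratio, which makes the profiles
exactly invariant to rescaling any sample's full depth row (tested to
1e-9).

Inter-sample step: capture efficiency varies by position, so each position
is rescaled by `2 / r(p)` where `r(p)` is the per-position median of
`cn_raw` over a reference sample set. The reference set is either the
whole cohort or only samples known to carry no SV in the gene. The second
mode exists because the median collapses to the *deleted* state when
carriers are the cohort majority — with 75% deletion carriers the
all-samples mode inflates diploid samples to an apparent four copies,
which the test suite demonstrates explicitly. Normalization operates per
position (not per gene aggregate) so that hybrid breakpoints survive into
the features; the choice is recorded in each profile's provenance.

Positions with zero depth in more than half the samples are masked as
capture dropouts before normalization; copy numbers are reported
unrounded, and integerization happens only inside SV classification, so
the 1:3-vs-2:2 evidence is preserved for the genotyper.

## SV classification

Features are mean copy number per 500 bp bin over the gene span followed
by the captured pseudogene span (where one exists); masked positions are
ignored within bins and empty bins are imputed from their flanking bins.
The gene+pseudogene span is used (rather than gene-only) because hybrid
alleles convert gene material into pseudogene-like material past the
fusion breakpoint — the reciprocal step in the pseudogene track is half
the signature.

Each gene declares a closed class set (e.g. CYP2D6: normal, whole_del,
whole_dup, hyb_36_10, hyb_36x2_10, hyb_68_4; GSTT1: normal, del_het,
del_hom), each class with a canonical carrier diplotype and a piecewise
copy-number template. Configurations that share a copy-number track share
a class: `*7/*7x3` and `*7x2/*7x2` both present the whole-gene four-copy
plateau and are separated later by allele fractions, and `*2x2`/`*4x2`
both map to the duplication class with the allele identity supplied by
variant matching.

The classifier is a one-vs-rest SVM with an RBF kernel (`gamma="scale"`).
An RBF kernel is a necessity, not a tuning choice: interior classes along
the copy-number axis (a heterozygous deletion at ~1 copy, between normal
~2 and homozygous deletion ~0) are not one-vs-rest separable by any linear
decision function, which degenerates the margins of exactly the classes
that matter most. Training data come from the simulator (no labeled real
cohort ships with the package), with at least three examples per class
required and fifty per class used by the validation studies.

**Indeterminate escape hatch.** A profile is refused rather than
misassigned when (a) the top one-vs-rest margin falls below a per-class
floor calibrated as the training minimum minus 1.0, or (b) the
standardized distance to the winning class centroid (per-bin z-scores
against training spread, floored at 0.15 CN) exceeds 1.5× — at least 1.5
absolute — the class's 99.5th training percentile. Both thresholds are
calibrated on the training set because interior classes legitimately sit
at negative one-vs-rest margins; a fixed zero threshold flags a third of
correct calls. Novel configurations (partial deletions, unregistered
hybrids) sit many CN-widths from every centroid and fall out reliably; the
Indeterminate rate on simulated diploid-normal cohorts is ≤1% by test.

## Phasing and haplotype matching

Pre-phased VCFs are consumed directly (`passthrough` mode; the first GT
allele goes to copy 1, unphased heterozygotes are an error). The fallback
`match` mode brute-forces all 2^n phasings of a sample's het variants
(n ≤ 12) and picks the assignment whose haplotypes are best explained by
whole catalog alleles: maximize explained-minus-unexplained variant count,
then the largest single-allele match (so the `*80`+`*28` pair lands cis as
`*80+*28` while two independent single-variant alleles land trans), then
the lexically smallest assignment for determinism. Phasing-strategy
provenance is recorded on every call because incorrect statistical phasing
is a known discrepancy source in panel-vs-reference comparisons.

Matching ranks candidate alleles whose entire defining set is contained in
the haplotype: largest defining set first, known-function before unknown,
then lexical; an empty candidate list yields the reference allele.
SV-tagged alleles are excluded from variant matching — they are reachable
only through the SV integration step, which prevents `*7` / `*7x2` /
`*7x3` (identical defining sets) from colliding.

## Diplotype assignment

The SV class gates the final call. Heterozygous deletions pair the
surviving haplotype's allele with the gene's deletion allele; homozygous
deletions return it twice. Hybrids and named partial-SV alleles (`*S1`
style) substitute the registered allele name on the haplotype carrying its
base variants. Duplications/multiplications infer the copy split (c1, c2)
with c1+c2 = k total copies by minimizing the residual between observed
het-site allele fractions and the expected c/k — catalog variants are
anchored to their phased haplotype, non-catalog ("personal") het variants
may belong to either copy — and render the result as an `xN` suffix. A
mean residual above 0.12 refuses the call (binomial allele-fraction noise
at ≥100× site depth stays well inside that band); with no het evidence at
all, the extra copies go to the reference-most allele and the call is
flagged low-confidence. Canonical rendering orders alleles by numeric
core, then copy count, then lexically (`*36x2+*10/*41`, `*7/*7x3`);
refused calls render as `Indeterminate`.

## Phenotype prediction

CYP2C9, CYP2D6 and DPYD use activity scores; CYP2B6, CYP2C19, CYP3A5,
SLCO1B1, TPMT and UGT1A1 use direct diplotype maps. Scores, map entries
and score bins ship as editable TSVs, not code, so another guideline
release can be swapped in without touching the package. The CYP2D6 bins
are 0 poor, (0,1] intermediate, (1,2.25] normal, >2.25 ultrarapid; bins
tile [0,∞) exactly and the suite asserts it. Any allele without an
assigned value (unknown/uncertain function, e.g. CYP2D6*106) forces an
Indeterminate phenotype; genes outside the nine-gene set report "no
phenotype table" in batch output rather than erroring.

## Call-set comparison

Agreement is whole-diplotype string equality after ledger normalization —
no partial credit. The YAML ledger holds, each entry with a reason:
alleles to map to a comparison surrogate (named after the reference set
was produced), per-sample/gene trisomy adjustments that drop a duplicated
allele from three-allele calls, legacy-notation equivalences
(`(*36+)10` → `*36+*10`), and whole-sample exclusions (which
`flag_discordant_samples` can feed directly, preserving the audit trail
from variant-level evidence to comparison-level exclusion). Residual
mismatches are categorized from caller-supplied evidence tags
(untargeted_variant, phasing, variant_calling, sv_interpretation, other);
category counts sum to the discrepancy total by construction.

Variant-level concordance is computed per sample over the union of sites:
a site absent or missing in one table counts as homozygous reference
there (making false positives/negatives well-defined under a union-based
comparison), half-missing genotypes are excluded from the denominator and
logged, and indels are split from SNVs by ref/alt length. The report
exposes both the per-sample compared-site counts and the union size, since
either denominator convention is defensible. The default swap-flagging
threshold of 0.90 sits between a concordant cohort (≈0.96) and a
swap-grade outlier (≈0.77).

## Synthetic-data generator

The simulator emulates the statistical structure the pipeline assumes
from deep targeted capture:

* **Depth**: `depth(s,p) ~ NB(mean = D·L(s)·E(p)·cn(s,p)/2)` with base
  depth D (default 250×, the deep-panel regime), lognormal library factors
  L (σ = 0.2), capture efficiency E (default 1.0), and negative-binomial
  overdispersion (`var = μ + φμ²`, default φ = 0.1; φ = 0 is the exact
  deterministic limit). The control locus is always simulated diploid.
* **Copy tracks**: per-haplotype piecewise templates (deletion 0,
  duplication N, hybrids stepping between gene-like and pseudogene-like
  levels at a configurable breakpoint fraction), summed over the two
  haplotypes.
* **Genotypes**: each carried defining variant draws ALT depth
  Binomial(site depth, c/k) with c of k copies carrying it, so a
  duplicated haplotype's variants cluster at 2/3 and a 1+3 configuration
  at 1/4 and 3/4. Each haplotype also carries one fixed-position
  non-catalog "personal" marker variant, as real haplotypes do; these are
  what let the genotyper separate 1+3 from 2+2 when the catalog variants
  are homozygous.
* **Determinism**: all randomness flows from one seed through spawned
  generators; truth tables embed the seed.

One depth row is generated per 10 bp of target (the package's desk-scale
stand-in for per-base depth), giving 50 depth values per 500 bp feature
bin — enough that bin-level noise matches what per-base deep-coverage
panels show. Gene and pseudogene intervals are compact synthetic stand-ins
(6–32 kb on the real chromosomes); the shipped translation tables are
likewise synthetic except for the handful of literature-documented
variants, and are labelled as such in the data files.

What passing the simulation studies does **not** show: robustness to
GC-driven capture bias, misalignment between a gene and its pseudogene
(the simulator models the copy-level consequence of hybrids, not the
read-level ambiguity), indel representation differences (matching is
exact-string), population phasing errors, or reference-material
idiosyncrasies. Real-cohort concordance validation requires external
sequencing data and is deliberately outside the package.

## Validation studies and problem sizes

`pgxstar.validation` regenerates seeded cohorts and scores the pipeline
end to end; `scripts/acceptance.py` reports the results. The studies use
per-gene classifiers trained on 50 simulated profiles per class; SV-class
recall is scored over 10 carrier replicates of each of the 19 SV-defined
alleles (9 genes) alongside 20 diploid anchors per gene; diplotype
recovery uses 200 mixed-truth samples per gene over CYP2D6, CYP2E1, GSTT1
and UGT2B17, including the `*7/*7x3`-vs-`*7x2/*7x2` disambiguation. Both
studies run in seconds on one CPU at these sizes.

## Known limitations

* Class sets are closed per gene; genuinely novel SVs are refused
  (Indeterminate), never named.
* Suballele resolution (`*2A` vs `*2B`) is limited to catalog contents.
* No indel left-normalization: defining variants must match the caller's
  representation exactly.
* The catalog-guided phaser is exponential in the per-gene het count
  (capped at 12 sites) and resolves ties deterministically rather than
  probabilistically.
* Duplication attribution without any het evidence defaults to the
  reference-most allele and is flagged low-confidence rather than refused.
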