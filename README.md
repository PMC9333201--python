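# pgxstar

Copy-number-aware star-allele genotyping for targeted pharmacogene
sequencing panels, with CPIC phenotype prediction and a concordance
framework for validating one call set against another.

## The problem

Clinical pharmacogenetics reports a patient's *diplotype* — the pair of
named haplotype patterns (*star alleles*, e.g. `CYP2D6*4`) carried at a
pharmacogene — because star alleles, not individual variants, are the units
that guideline bodies attach drug-dosing recommendations to. Calling them
from targeted sequencing is hard for two reasons: an allele may be defined
by a *phase-dependent combination* of SNVs and indels, and several
clinically critical alleles are defined by *structural variants* (SVs) —
whole-gene deletions (`GSTT1*0`), duplications (`CYP2A6*1x2`), higher-order
multiplications (`CYP2E1*7x3`), and gene–pseudogene hybrids
(`CYP2D6*36+*10`) — that are invisible to ordinary small-variant calling.

`pgxstar` implements the full calling path for panel data: per-base depth
is converted to copy number, a per-gene classifier recognizes the SV
configuration, small variants are phased and matched against haplotype
translation tables, and allele-fraction evidence disambiguates copy
splits. It is aimed at people building or validating PGx sequencing panels
and at method developers who need a self-contained, simulation-backed
reference implementation.

## The model

**Copy number.** Depth at position *p* in sample *s* is normalized in two
steps. Intra-sample, against a control gene with negligible copy-number
polymorphism (default VDR):

    cn_raw(s, p) = 2 · depth(s, p) / median_control(s)

Inter-sample, each position is rescaled so the cohort reference track (the
per-position median of `cn_raw` over a designated sample set) sits at the
diploid value:

    cn(s, p) = cn_raw(s, p) · 2 / median_{s'∈ref} cn_raw(s', p)

The reference set is either all samples or only samples known to carry no
SV in the gene — the latter is essential where deletion carriers are the
cohort majority (GSTT1, GSTM1, UGT2B17).

**SV classification.** Profiles are binned (500 bp means over the gene and
its captured pseudogene) and classified with a one-vs-rest SVM over each
gene's registered configuration set. Profiles matching no trained
configuration fall to an *Indeterminate* call rather than a wrong one.

**Diplotype assignment.** Each haplotype's variant set is matched against
the gene's translation table (most-specific allele first). The SV call is
then folded in: deletions substitute the deletion allele, hybrids the
registered hybrid allele, and duplications attach an `xN` suffix to the
haplotype whose het-site allele fractions sit at the expected c/k — this
is what resolves `*7/*7x3` (fractions 1/4 and 3/4) from `*7x2/*7x2`
(fractions 1/2).

**Phenotype.** CYP2C9, CYP2D6 and DPYD use the CPIC activity score — each
allele contributes a value (1 normal, 0.5 decreased, 0 none; `xN`
multiplies by N) and the diplotype score is the sum, binned into
metabolizer categories (CYP2D6: 0 poor, ≤1 intermediate, ≤2.25 normal,
else ultrarapid). Six further genes use direct diplotype→phenotype maps.
Unknown-function alleles force an Indeterminate phenotype.

## Worked example

```bash
python examples/call_diplotypes.py
```

trains a CYP2D6 SV classifier on simulated profiles, simulates an
eight-sample cohort, and runs the full calling path:

```
sample   gene     diplotype    sv_class confidence                phenotype         truth
 S0000 CYP2D6         *1/*1      normal     normal       Normal Metabolizer         *1/*1
 S0002 CYP2D6         *4/*5   whole_del     normal         Poor Metabolizer         *4/*5
 S0004 CYP2D6       *1/*2x2   whole_dup     normal   Ultrarapid Metabolizer       *1/*2x2
 S0006 CYP2D6 *36x2+*10/*41 hyb_36x2_10     normal Intermediate Metabolizer *41/*36x2+*10
 S0007 CYP2D6      *29/*106      normal     normal            Indeterminate      *29/*106
```

Every diplotype matches its simulated truth: the `*4/*5` sample combines a
nonfunctional SNV allele with the whole-gene deletion (activity score 0,
poor metabolizer), the tandem hybrid `*36x2+*10` is recovered from the
four-copy plateau plus the 1:3 allele-fraction signature, and `*29/*106`
is phenotype-Indeterminate because `*106` has no assigned enzyme function.
The other `examples/` scripts each demonstrate one capability: catalog
summaries, variant concordance with sample-swap flagging, the
deletion-heavy-cohort normalization trap, phenotype scoring, and ledgered
call-set comparison.

A thin CLI mirrors the library (`pgxstar simulate`, `train-sv`, `run`,
`phenotype`, `compare-variants`, `compare-calls`, `metrics`,
`control-stats`).

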