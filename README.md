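# diallel

Quantitative genetics of diallel hybrid panels: combining-ability and
heritability decomposition, mid-parent inheritance-mode classification, and
dual-encoding mixed-model GWAS on in-silico hybrid genotypes — with a
synthetic-data generator that emulates a yeast diallel built from
homozygous natural isolates, so the whole pipeline is testable end to end
without any external download.

## Who this is for

A diallel cross — all pairwise matings among a set of parents — is a
classical design for splitting phenotypic variance into additive and
non-additive genetic components, and, when the parents are fully homozygous
(as stable diploid yeast isolates are), it doubles as a GWAS panel whose
hybrid genotypes can be written down *in silico* from the parental genomes.
Crossing also *boosts* alleles that are rare in the source population:
in a half matrix plus diagonal from N founders, each founder contributes
N+1 allele copies, so a variant carried by even 3 of 34 founders reaches a
panel MAF of ~9% and becomes mappable.  This package implements that whole
analysis path for anyone working with such panels (or wanting to simulate
them).

## The models

**Combining abilities (Griffing).** Each heterozygous hybrid phenotype is
decomposed as

    z_ij = μ + g_i + g_j + s_ij + e

with GCA estimates ĝ_i = (N−1)/(N−2) · (z̄_i· − μ) and SCA
ŝ_ij = z_ij − ĝ_i − ĝ_j − μ over the C(N,2) half diallel (homozygous
self-crosses excluded).  Variance components give narrow- and broad-sense
heritability:

    h² = σ²A / (σ²A + σ²SCA + σ²e),   H² = (σ²A + σ²SCA) / (σ²A + σ²SCA + σ²e)

where σ²A = Var(ĝ_i + ĝ_j) over crosses and σ²e is the sampling variance
of a cross phenotype (mean replicate variance / n).

**Inheritance modes.** Each cross × condition is placed among seven ordered
bands — underdominance, dominance toward either parent, partial dominance,
additivity, overdominance — anchored at the worse parent P1, the mid-parent
value (P1+P2)/2 and the better parent P2, with replicate-sd tolerances; the
seven-way call requires the parents themselves to separate
(P1 + σP1 < P2 − σP2), otherwise only over/underdominance can be called.

**Association.** Sites are filtered (biallelic, no missing or heterozygous
founder calls), long-range perfect-LD block artifacts pruned, hybrids
encoded *additively* (minor-allele dosage 0/1/2) and *overdominantly*
(heterozygote indicator), phenotypes inverse-normal transformed, and each
site tested in a single-random-effect mixed model y = μ + gβ + u + ε,
u ~ N(0, σ²_g K) with leave-one-chromosome-out kinship.  Family-wise
significance thresholds come from phenotype permutations (5th smallest of
100 genome-wide minimum p-values at α = 0.05).  Per-site effect sizes are
Cohen's d (heterozygotes vs major-allele homozygotes, or vs all homozygotes
under the overdominant encoding) and variance explained is the squared
genotype–phenotype correlation.

## Worked example

```bash
python examples/02_combining_abilities.py
```

```
additive data:    mu = 15.0
  GCA: {'A': -4.5, 'B': -0.5, 'C': 1.5, 'D': 3.5}
  max |SCA| = 1.78e-15  ->  h2 = 1.0, H2 = 1.0
perturbed z_CD=24: mu = 15.667
  GCA: {'A': -5.5, 'B': -1.5, 'C': 2.5, 'D': 4.5}
  SCA(C,D) = 1.3333  (the +4 shock minus what GCAs absorb)
```

The six phenotypes 10..20 are exactly additive, so every cross is
reconstructed by μ + ĝ_i + ĝ_j, all SCA terms vanish, and both
heritabilities are 1.  Bumping one cross (C×D) by +4 moves μ and every GCA,
and leaves a cross-specific residual ŝ_CD = +4/3 — the share of the shock
that the additive terms cannot absorb.

The other scripts in `examples/` walk through the simulator
(`01_simulate_diallel.py`), inheritance-mode classification
(`03_inheritance_modes.py`), GWAS with a boosted low-frequency variant
(`04_gwas_low_frequency.py`, which recovers a planted variant with source
MAF 0.02 at panel MAF 0.088 as the top additive hit), and the end-to-end
pipeline with its manifest (`05_full_pipeline.py`).  The same pipeline runs
from the shell:

```bash
diallel init-config cfg.yaml
diallel all --config cfg.yaml --out run/ --seed 1
```

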