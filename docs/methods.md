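# Methods

## Problem setting

A diagnostic assay amplifies the phenylalanine hydroxylase gene (*PAH*,
13 exons, chromosome 12) in nine long PCR products (1.5–5 kb), sequences
them on an Oxford Nanopore instrument, and calls pathogenic variants in
phenylketonuria (PKU) patients. PKU is autosomal recessive: a diagnosis is
genetically explained by one homozygous pathogenic variant or by two
different pathogenic variants in trans (compound heterozygosity). This
package implements the computational layer of that workflow: panel
validation by virtual PCR, zygosity calling from allele fractions, genotype
→ phenotype classification, and cohort statistics — all exercised on the
packaged 40-patient cohort table and on synthetic data.

## Zygosity from allele fraction

Long-read amplicon data from this assay show variant allele fractions well
below diploid expectations (homozygous calls down to 0.58, heterozygous
calls 0.18–0.56), a known consequence of mapping/alignment bias on noisy
long reads. A call is classified homozygous iff its allele fraction is
**≥ t** (inclusive); the default `t = 0.58`.

`derive_threshold` recovers *t* from a cohort rather than assuming it.
Candidates are the observed allele fractions of single-variant patients —
the only fractions that can anchor a homozygous call. Constraints come from
record structure alone:

* *must stay heterozygous*: every call of a two-variant patient (at most two
  pathogenic alleles under a bi-allelic model), and single-variant records
  with no recorded genotype-level phenotype value (the record itself marks
  the genotype unexplained);
* *must be homozygous*: single-variant records carrying a recorded
  genotype-level value (the genotype was treated as two identical alleles).

The returned threshold is the smallest candidate minimizing the number of
violated constraints (ties → smaller value, so the result is the smallest
fraction classified homozygous). On cleanly separated data this yields zero
violations; on the real cohort exactly three records conflict with *any*
single cutoff (one two-variant patient with a 0.67 fraction, and two
single-variant patients whose printed genotype-level values imply
homozygosity at fractions 0.36/0.31). These conflicts are reported in the
result object, never silently dropped; the minimizer is unique at 0.58.
Violation-minimisation was chosen over a hard separating rule precisely
because the real table contains these contradictions: a hard rule either
fails or needs per-patient exceptions, whereas the soft rule is total,
deterministic, order-invariant, and reduces to the intuitive
"smallest homozygous fraction" whenever the data separate.

Genotype assembly: one homozygous call → *homozygous* (explained); two
heterozygous calls → *compound heterozygous* (explained; phasing is not
performed, so trans configuration is an assumption and is flagged on the
profile); one heterozygous call → *single heterozygous* (unexplained). A
two-variant patient with a homozygous-classified fraction is kept in the
compound category but flagged `inconsistent` — three pathogenic alleles are
impossible under the model — so batch runs survive contradictory inputs.

## Phenotype classification

Each *PAH* allele carries an allelic phenotype value APV ∈ [0, 10]
(0 = most severe), transcribed from the cohort table (the package never
queries the external database these values originate from). The genotypic
phenotype value is GPV = max(APV₁, APV₂) — in a recessive disease the milder
allele determines residual enzyme activity. Bins: 0–2.7 classic PKU,
2.8–6.6 mild PKU, 6.7–10.0 mild hyperphenylalaninemia; values are rounded
to one decimal before binning so the printed bin gaps (2.7→2.8, 6.6→6.7)
cannot swallow a value. Single-heterozygous genotypes and genotypes with a
missing APV are *unpredictable*, not defaulted.

Biochemical classification from pre-treatment phenylalanine: > 1200 µmol/L
classic, 600–1200 µmol/L (inclusive) mild; below 600 is outside the
two-class scheme and an error. Qualitative entries (historical Guthrie
screening results, "not determined") are preserved as markers — no
conversion factor to µmol/L exists — and are unclassifiable.

Concordance between predicted and recorded labels is computed only under an
explicit, caller-supplied label mapping which is echoed in the result; the
default maps clinical classic↔recorded classic and clinical mild↔{recorded
mild, mild HPA}. This is deliberate: no single obvious mapping reproduces
the concordance count reported for this cohort elsewhere, so the mapping is
configuration, not a hidden constant.

Known data contradictions, asserted as such in the test suite: one patient's
printed genotype value contradicts the max rule (pair 10/9.7 printed as
9.7), and one patient's printed value bins to classic while the recorded
majority type is mild. Two further patients print genotype-level values as
if homozygous although their fractions classify heterozygous; profiles carry
the threshold-based category and the printed value side by side.

## Panel validation (virtual PCR)

Primer specificity is sequence-level: a primer binds a window when its
3′-terminal `anchor_len` bases (default 3) match exactly and at most
`max_mismatch` (default 2, a permissive virtual-PCR setting) of the
remaining bases mismatch; IUPAC ambiguity codes in primers match their base
sets; both strands are searched. Thermodynamics (Tm, dimers, multiplex
interactions) are out of scope. Amplicons are all forward/reverse site
combinations with product length in [1500, 5000] bp; off-target products
are flagged, not dropped. Coverage is interval arithmetic on half-open
intervals; targets are the 13 exons, both UTRs, ±25 bp junction flanks, and
explicit deep-intronic points carrying reported variants. Pooling is greedy
interval coloring — no two overlapping products in one tube (overlapping
long amplicons would cross-prime) — deterministic by (start, length) order.

The real assay's primer sequences are unpublished, so the package ships a
*generated* panel satisfying the same printed constraints: nine pairs
(24-mers lifted from the toy reference at tiling positions), products of
3.8 kb tiling the gene with ~430 bp neighbour overlap, complete target
coverage, two pools. The toy reference is synthetic: a random ~31.6 kb
contig whose 13 exon CDS spans match the real *PAH* transcript annotation
(so printed intron-offset positions such as c.1066-11 and c.168+5 fall at
true junction offsets), with the base at every cohort variant position
patched to the variant's reference allele. The transcript map is a checked
bijection between CDS coordinates (with intron offsets up to the intron
midpoint) and genomic positions; the gene is placed on the plus strand for
simplicity (the real gene is minus-strand; nothing downstream depends on
orientation).

## Simulator

The unit of observation is the per-site (depth, alt-count) pileup — what
the assay reports per call — not reads; basecalling error profiles,
homopolymer effects and read lengths are out of scope. Depth ~
⌊log-uniform(50, 2000)⌋, reflecting the assay's depth spread without
modeling per-amplicon bias. Alt count ~ beta-binomial: a latent fraction
p ~ Beta(cμ, c(1−μ)) with zygosity-specific center μ (defaults μ_hom = 0.72,
μ_het = 0.38, the cohort's empirical means) and concentration c = 35, then
alt ~ Binomial(depth, p). The concentration is a method-of-moments fit to
the *within-variant* replicate spread of the cohort (e.g. the six
homozygotes of the most common variant give c ≈ 36); the larger
cross-variant spread conflates per-variant systematic mapping bias with
sampling noise and would overstate per-assay noise. Under these defaults
the 0.58 cutoff recovers true zygosity for ≈ 97 % of simulated calls
(≈ 96 % of homozygous calls at depth ≥ 500).

Synthetic cohorts draw each patient's genotype from a frequency table
(default: the packaged cohort's empirical genotype distribution, so marginal
carrier frequencies such as 15/40 for the common intronic variant are
reproduced in expectation), attach a pileup per call, and store truth labels
on the record. Genotype-level phenotype values are filled in for explained
genotypes with known APVs, so threshold derivation sees the same
explained/unexplained structure as the real table. Limitation: a synthetic
homozygote of a variant with unknown APV would be treated as unexplained by
`derive_threshold`; no such genotype exists in the default table.

What passing simulator-based tests shows — and does not. They validate the
decision rule against the declared noise model at the declared parameters;
they do not validate the noise model itself against raw reads (the package
contains no basecalling or alignment), nor per-variant systematic bias,
which real data exhibit and the simulator deliberately averages away.

## Numerical and formatting choices

* Percentages: one decimal, rounded half away from zero — reproduces the
  printed cohort style (17/36 → 47.2).
* Zygosity threshold comparison is inclusive (≥).
* Pileup caller: minimum depth 50× inclusive (50× is adequate), minimum
  allele fraction 0.15 — just below the smallest fraction the assay's own
  pipeline retained (0.18).
* Consanguinity: "yes, degree unknown" counts as consanguineous; "unknown"
  is excluded from the denominator (the only reading consistent with the
  printed 47.2 %).
* VCF output is 1-based, left-anchored (deletion REF includes the anchor
  base); BED interchange is 0-based half-open. The writer is a minimal
  deterministic text emitter; tests read it back with pysam as an
  independent check.
* HGVS support is a deliberate subset (substitution, deletion, delins,
  intron offsets); duplications, insertions and inversions raise a
  dedicated "unsupported kind" error rather than being skipped.
* Depths printed in the cohort exceed the simulator's 50–2000× range for
  two calls (2082×, 3626×); the fixture transcribes them as printed, the
  simulator keeps the stated range.

## Problem sizes

Monte-Carlo checks use 1 000–10 000 pileup draws or 10 000-patient
synthetic cohorts with seeded generators; calibration assertions use
3-standard-error bands. The full test suite runs in well under a minute on
one CPU.

## Known limitations

* No phasing: compound heterozygosity is an assumption, flagged per
  profile.
* ACMG evidence codes are stored and round-tripped but not combined into a
  classification (the table's transcribed class is used).
* The panel module validates primer placement, not chemistry; a panel that
  passes here can still fail in the lab.
* Structural variants and deep-intronic discovery beyond the explicitly
  targeted sites are out of scope, as they are for the assay itself.
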