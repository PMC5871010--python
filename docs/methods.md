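# Methods

## The problem

Tumor-only exome sequencing yields call sets in which somatic mutations are
a small minority among germline variation and platform artifacts. With no
matched normals, somatic status must be inferred by subtraction against
population resources, and downstream analyses — microsatellite-instability
(MSI) classification, allelic-imbalance (AI) calling, mutational-signature
decomposition, and cohort association statistics — inherit whatever error
that subtraction leaves behind. This package implements that full path as a
reusable library, with a synthetic-cohort generator standing in for
controlled-access patient data so every stage can be scored against known
truth.

## Somatic filter cascade

Stages run in a fixed order, each producing a subset of its input:

1. **Hard filters** — GATK's published recommended thresholds per variant
   class (SNV: QD ≥ 2, FS ≤ 60, MQ ≥ 40, MQRankSum ≥ −12.5,
   ReadPosRankSum ≥ −8, SOR ≤ 3; indels: QD ≥ 2, FS ≤ 200,
   ReadPosRankSum ≥ −20, SOR ≤ 10). Missing annotations pass; thresholds
   are shipped configuration, overridable per run.
2. **Population-specific whole-genome set** — exact-key matches (SNVs) or
   footprint overlaps (indels) removed regardless of allele frequency.
3. **Population allele frequency** — SNVs with resource AF strictly above
   10⁻⁴ removed on exact (chrom, pos, ref, alt) match; indels removed on
   any overlap with known population indel footprints.
4. **In-house panel** — exact-key matches removed (platform/pipeline
   artifacts recurrent in unrelated normal genomes).
5. **Pooled normals** — an SNV is removed when the pool of normal blood
   genomes holds ≥ 3 mutant reads at its key; an indel when ≥ 2 pooled
   samples each show > 3 supporting reads within 100 bp (one read length)
   of the locus.
6. **Target restriction** — the leftmost affected base must lie inside the
   merged capture intervals.

Coordinates are 1-based inclusive in memory; BED I/O converts from 0-based
half-open at the boundary. An insertion's reference footprint is the base
before the insertion point; a deletion's is the deleted span. The stage
order is part of the contract (the AF and population-set stages have
different semantics, so stages do not commute) and is asserted by the
per-stage count table.

## MSI/MSS classification

MSI tumors combine an extreme mutation burden with indel overrepresentation
at microsatellite loci. A sample is MSI iff burden ≥ 10 mut/Mb **and**
microsatellite-indel fraction ≥ 0.3 (conjunction). The cutoffs are not
prescribed anywhere; they were placed once in the wide empty margin between
the two classes (~4.3 vs ~64 mut/Mb; minority vs dominant microsatellite
overlap among indels) and are exposed in configuration. With no indels the
fraction is defined as 0. Classification is confirmed against signature
exposures: an MSI label is concordant when the MSI-signature share of the
sample's exposure vector exceeds 0.5; discordant samples are flagged, not
reclassified.

## Allelic imbalance

Input SNPs must satisfy five criteria: rs-coded, coverage ≥ 10, not flagged
somatic, inside the capture target, and not overlapping the blacklist.
BAF = ALT reads / total reads; mBAF = max(BAF, 1−BAF).

Per chromosome the segmentation pipeline: (1) mirrors BAF; (2) drops
presumed-homozygous points (mBAF ≥ 0.97); (3) applies a triplet filter —
an informative point with mBAF > 0.8 is dropped unless an adjacent
informative neighbor also exceeds 0.8; (4) finds the exact least-squares
change-point partition of the remaining mBAF series (O(n²) dynamic program
minimizing total within-segment squared error plus a per-breakpoint
penalty); (5) reports segments with mean mBAF ≥ 0.6 over ≥ 4 SNPs, merging
adjacent qualifying segments. The four named parameters (non_informative
0.97, ai_threshold 0.6, ai_size 4, triplet_threshold 0.8) are the published
operating point; the change-point machinery between them is this package's
own concrete contract, chosen so that short series are exactly solvable and
testable against exhaustive enumeration.

The breakpoint penalty defaults to 10·σ̂²·log n, with σ̂ estimated robustly
from the median absolute first difference of the series
(median|Xᵢ₊₁−Xᵢ| ≈ 0.954 σ for Gaussian noise). The constant 10 was fixed
from a signal-to-noise argument before any cohort-level evaluation: at 40×
coverage the mBAF noise gives σ² ≈ 0.004, so the penalty (~0.25 for a
1000-point chromosome) sits several-fold above the expected spurious gain
of a noise split and several-fold below the gain of a real ≥ 4-SNP shift of
0.25. Ties in the dynamic program resolve toward fewer segments.

Log-R uses `log2(varCoverage / (sampleMedian · chromNormalize[chr]))`.
Chromosome coefficients come from a control analysis of normal exomes:
coefficient = (median coverage on the chromosome across normals) / (global
autosomal median). The X coefficient uses female samples only and is left
undefined (flagged) without them; male X is excluded from tumor AI calling
outright. The same control panel drives the blacklist: regions called AI in
≥ 10% of normals (a configurable recurrence fraction; no published value
exists) are merged and excluded from tumor analysis.

Tumor samples are segmented twice: pass 1 locates AI regions so the sample
median — and hence log-R — can be recomputed from balanced territory only;
pass 2 produces the reported segments. Since segmentation depends only on
mBAF, the two passes yield the same segments; the refinement changes the
gain/loss classification, which is median logR > 0.1 → gain, ≤ 0.1 → loss.
Copy-neutral LOH is deliberately not a separate class: it satisfies the
loss rule.

## Mutational signatures

Somatic SNVs are tallied into the standard 96 channels (six
pyrimidine-centered substitutions × 16 flank contexts,
substitution-major/5′/3′ lexicographic order), reverse-complementing
purine-reference calls. Extraction is multi-restart NMF with the
Kullback–Leibler objective (scikit-learn's multiplicative-update solver;
best-of-restarts kept; deterministic given a seed); signature rows are
normalized to probability vectors. Exposures are per-sample nonnegative
least squares onto the weight matrix, in mutation-count units. Matching to
a reference catalogue minimizes the symmetric mean KL divergence
[D(p‖q)+D(q‖p)]/2 with natural logarithms after flooring both vectors at
10⁻⁹ and renormalizing; the log base and zero handling are free choices
since the matching only uses divergence *rankings*, which are
base-invariant. Matching is per-signature, not forced bijective. The number
of signatures k is the caller's choice; `rank_scan` provides an advisory
reconstruction-error and stability profile. The pipeline driver runs the
analysis twice as the study design dictates — all samples (to detect the
MSI signature) and then MSS-only.

KL-objective NMF is identifiable only when some samples are nearly pure in
each signature; interior-mixture cohorts admit rotated factorizations with
identical fit. The recovery tests therefore use sparse (Dirichlet)
exposure profiles, which is also what real cohorts look like.

The bundled reference catalogue
(`data/synthetic_reference_signatures.tsv`) is **synthetic**: eight
96-channel probability vectors whose shapes qualitatively emulate familiar
mutational processes (CpG deamination for "1A", a mismatch-repair-deficiency
profile for "6", a T>G-at-CTT profile for "17", APOBEC-like "2"/"13", flat
"5", and broad "U1"/"U2"), with pairwise symmetric KL ≥ 2.6 so matching is
well-conditioned. Any same-channel-order TSV (e.g. a published human
catalogue) can be supplied instead; signature names are data, not code.

## Exact statistics

Both Fisher-type tests and the exact binomial test use the
minimum-likelihood two-sided convention — the sum of outcome probabilities
no larger than the observed one — because that is what R's `fisher.test`
and `binom.test` report, and the cohort statistics being reproduced were
computed in R. The 2×2 estimate is the conditional maximum-likelihood odds
ratio under the noncentral hypergeometric model with an exact 95% CI
(scipy.stats implementations; cross-checked in the tests against direct
hypergeometric enumeration). The 2×K test enumerates all tables with the
observed margins (bounded at 500 total by default) in log space with the
same relative slack (1+10⁻⁷) R uses for probability comparisons; larger
tables use a seeded multivariate-hypergeometric Monte Carlo sampler. Zero
cells yield 0/∞ odds-ratio estimates with one-sided CIs; an all-zero margin
is an error.

## Synthetic cohort generator

The generator defines the study conditions the pipeline is tested under:

| parameter | default | rationale |
|---|---|---|
| n_samples / msi_fraction | 106 / 15⁄106 | cohort composition being emulated |
| target_mb | 94 | declared capture size (coding + UTRs) |
| mean_depth | 40× | median exome depth, negative-binomial dispersion 8 |
| mss / msi burden | 4.3 / 63.6 mut/Mb | printed class burdens; counts ~ Poisson(burden·target_mb) |
| burden dispersion | lognormal σ = 0.15 | per-sample variability; no published value, a free knob |
| signature mix | MSS: 1A/17/U2; MSI: 6-dominated | class-specific mutagenesis |
| purity | 0.7 | single tumor-purity scalar |
| germline het SNPs | 6000 | desk-scale (see below) |
| invented germline rate | 0.02 | residual rare germline variation |

Coordinates live on a 22+X karyotype with human chromosome proportions
scaled down 100-fold, tiled with deterministic 300-bp exon-like target
intervals; the reference sequence is a seeded random genome, fixed
independently of the cohort seed. The declared `target_mb` (used for
burden arithmetic) is the emulated capture size, while physical coordinates
are compressed — burdens and densities therefore scale correctly even
though base-pair positions do not correspond to any real assembly.

Germline heterozygous SNPs are drawn from the population resource
AF-weighted (a carried variant is common with probability proportional to
its frequency, as in a real genome) with probability 0.98, and invented
rs-less otherwise — the invented 2% models the residual rare germline
variation that tumor-only filtering cannot remove and that the approach
concedes. Somatic variants are guaranteed absent from the resource; their
trinucleotide contexts are sampled from the class signature mixture via a
per-context position index of the target territory, so extracted
signatures can be compared with generating truth. MSI samples receive an
elevated indel fraction (0.25 vs 0.06) with 80% (vs 10%) of indels at
microsatellite loci. AI events (0.55 loss / 0.30 gain / 0.15 CNN-LOH)
shift both the binomial BAF sampling probability and the coverage mean:
with purity p, a loss has major-allele fraction 1−(1−p)/(2−p) and coverage
factor (2−p)/2; a gain (1+p)/(2+p) and (2+p)/2; CNN-LOH (1+p)/2 and 1.
Chromosome-specific depth multipliers (a fixed platform property, chr16 at
30/38) apply to tumors and normal panels alike, so the normalization stage
has something real to remove. Artifact loci recur across samples and are
backed by pooled-normal read evidence or the in-house panel. Every emitted
variant is recorded exactly once in the truth tables.

**Desk-scale choices.** Defaults emulate the study conditions; the default
het-SNP count (6000) follows the 100× genomic compression rather than a
real exome's ~40,000, keeping generation fast while preserving the SNP
density that segmentation sees. Tests and the acceptance script shrink
n_samples, target_mb, population-locus counts and (further) the karyotype;
rates and mixture parameters are never changed. The test suite runs ~100
seeded cohorts for classification accuracy (5 samples × 3 Mb each), 8
cohorts for AI scoring, and 100 NMF recovery runs at 25 samples each.

**What the generator does not model** — and hence what passing tests do not
demonstrate about real data: read-level errors and mapping artifacts
(depth and allele counts are drawn from clean parametric distributions),
subclonality beyond the single purity scalar, linkage between neighboring
variants, sequence-context-dependent microsatellite slippage, real gene
annotation (genes are coordinate tiles; consequences are sampled
categorically), and germline homozygous variants (the non-informative mBAF
filter is exercised by construction in tests, not by the generator).

## Numerical and degenerate-input choices

- Change-point ties resolve toward fewer segments; qualifying segments
  separated only by dropped (non-informative) points merge.
- A chromosome with fewer informative SNPs than ai_size yields no segments
  (not an error); zero-coverage points are dropped with a log count.
- Rank-1 KL-NMF converges to the normalized column-sum profile; this is
  used as a closed-form check of the extraction path.
- Monte Carlo 2×K p-values use the (hits+1)/(B+1) estimator, so P > 0.
- Multi-allelic VCF records are split into biallelic calls at ingest, with
  per-allele AD.

## Known limitations

- The filter cascade's germline-removal rate (~97–98% on synthetic
  cohorts) leaves residual rare germline variants that inflate measured
  MSS burdens above the simulated rate, as in real tumor-only calling;
  classification absorbs this through the conjunction rule.
- Low-purity gains shift mBAF by only (1+p)/(2+p)−0.5 (≈ 0.13 at p = 0.7)
  and are frequently below the detection threshold; sensitivity claims are
  restricted to shifts ≥ 0.25.
- Adjacent same-direction AI events separated by short balanced gaps can
  merge into one called segment.
- The exact 2×K test is exponential in K; it is bounded and intended for
  the small clinical tables it reproduces.
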