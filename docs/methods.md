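# Methods

This note documents the statistical models, the synthetic study design, the
numerical choices, and the known limitations of `ocrenrich`.

## Risk loci and LD

A risk locus is an index variant plus all panel variants on the same
chromosome within a window (default 1 Mb, index-to-proxy distance,
inclusive) whose squared LD correlation with the index strictly exceeds a
threshold (default r² > 0.8). r² is computed from *phased haplotypes*:

    D = p_AB − p_A p_B,   r² = D² / (p_A(1−p_A) p_B(1−p_B)).

Using haplotypes avoids EM haplotype-frequency estimation; the synthetic
panel is phased by construction. MAF is always min(f, 1−f) recomputed from
the panel, never supplied externally. One panel serves both enrichment
tests (real analyses of this design have sometimes used different reference
panels per tool; we deliberately do not emulate that discrepancy).

The extended MHC filter removes loci whose **index** position lies in the
half-open interval chr6:[26,000,000, 34,000,000) — the region's unusual LD
structure makes locus-based enrichment counts there unreliable. The filter
is idempotent and applied to the index only, since the locus is the counting
unit.

## Locus-shift permutation test

Observed statistic: the proportion of loci whose index or proxy lies inside
the annotation. Null: independently per locus and per permutation, all
annotation intervals within the locus window are circularly shifted by one
shared uniform offset in [0, W); a shared offset preserves the local
annotation density and spacing. The locus window is the span of
index + proxies extended on both sides by a flank equal to the larger of
50 kb and the longest annotation interval intersecting the span — this
guarantees that every interval that currently covers a variant can also
shift off it, avoiding degenerate always-overlapping nulls. The window is
clipped at position 0; intervals longer than the window are clipped with a
warning.

Implementation: for each locus the set of offsets under which at least one
variant is covered is itself a union of intervals in offset space (for a
variant at p and an interval [s, e), the covering offsets are
[p−e+1, p−s+1) mod W). Shifting-and-recomputing is therefore replaced by
membership queries of random offsets in this precomputed set — identical
statistic, O(1) per locus per permutation. The permutation p-value uses the
add-one estimator (1 + #{null ≥ observed}) / (1 + N), so p is never 0; ties
count toward rejection. An exhaustive mode (single locus) enumerates all W
offsets; it exists for unit testing and exact small-case work.

## Matched-control test

Observed statistic: the count S of overlapping loci. For each study locus,
controls are all pool loci in the same covariate bin triple — number of LD
proxies, MAF, distance to nearest gene TSS — excluding the study index
itself and pool variants in LD with it. Each locus contributes
pᵢ = (fraction of its controls overlapping), floored at 1/(nᵢ+1) and capped
at nᵢ/(nᵢ+1) (no locus is ever impossible or certain under the null). The
p-value is the exact upper tail P(X ≥ S) of the Poisson-binomial
distribution over the pᵢ, computed by convolution; exactness was preferred
over a normal approximation because S is small (tens of loci).

Default matching bins (full-scale): LD-count bins {0, 1, 2–5, 6–10, 11–25,
26–50, >50}, MAF bins of width 0.05, gene-distance bin edges {0, 1 kb,
10 kb, 100 kb, 1 Mb, ∞}, minimum 500 controls per index. These mirror
common practice for SNP-matched enrichment; all are configurable
(`MatchingBins`). A zero-proxy bin is included because a locus can have no
proxies at all.

## Multiple testing and the dual-test rule

Within each analysis stage, both tests' p-values are Bonferroni-multiplied
by the number of annotations (stage 1) or subsets (stage 3) actually tested
in that stage; the factors are emergent counts, not constants. An
annotation is reported enriched only when **both** adjusted p-values fall
below alpha (default 0.05). The two tests have nearly independent failure
modes (local-structure permutation vs covariate-matched resampling), so
requiring both guards against artefacts of either null.

## Motif machinery

**Background model.** Order-0 base frequencies estimated from the scanned
sequences (with a pseudocount so no frequency is 0). When scanning both
strands the background is symmetrized (A/T and C/G averaged) so that the
reverse-complement PWM has the identical score distribution and one
calibration serves both orientations. The model order is a deliberate
simplification; the field's scanners default to low-order Markov backgrounds
and the exact-p-value dynamic program below is cleanest at order 0.

**Exact score p-values.** PWM scores are log₂ odds against the background,
discretized to integer multiples of 0.01 bits. The distribution of a random
background word's score is built by convolving the four-point per-position
score distributions; p(score) is the tail sum. Scanning uses the same
integer scores, so window p-values agree exactly with the DP distribution
(and with brute-force 4^w enumeration, which the tests verify up to w = 8).
Windows containing N are skipped. The default occurrence threshold is
p ≤ 1e-4; note a 6 bp motif cannot pass it (min p = 4⁻⁶ ≈ 2.4e-4), which
reproduces the known behaviour that very short motifs yield no scannable
occurrences.

**De novo discovery.** For every literal k-mer (k = 6–8) present in the
target sequences — a pattern and its reverse complement are one candidate —
we count target and background sequences containing it (ZOOPS: a sequence
counts once) and apply a one-sided Fisher exact test (hypergeometric tail).
E-value = p × number of candidates evaluated across all k in the run.
Results are ranked by E-value, truncated at E ≤ 0.05 and 25 motifs, and
greedily deduplicated (Hamming distance ≤ 1 to a better-ranked equal-length
motif, either orientation). This is a deliberately simple discriminative
stage in the spirit of short-motif discovery tools: no wildcard refinement,
no GC-matched background weighting beyond the user-supplied background
collection. The default workflow background is a per-sequence base shuffle
of the targets (composition-preserving).

**Known-motif matching.** Best ungapped alignment of query and library PWMs
over all offsets and both orientations, scored as the mean per-column
Pearson correlation of probability columns over the overlap (minimum 4
columns). This is a similarity surrogate without p-value machinery; a match
requires score ≥ 0.8 by default. Constant columns (e.g. uniform N
positions) correlate 1 with equal columns and 0 otherwise.

**Peak subsetting.** A peak belongs to a motif's subset when it contains at
least one occurrence fully inside the peak (offset ≥ 0 and
offset + width ≤ peak length). Motifs are excluded, and logged, by three
rules with precedence: no known-motif match (when the known-match track is
requested), no significant occurrences, subset smaller than `min_subset`.
`noMotif` is the complement of the union of *included* subsets, so subsets
plus `noMotif` always cover the peaks and `noMotif` is disjoint from every
subset; `noMotif` is itself tested (it is a negative control) and is not
subject to `min_subset`.

## Synthetic study design

The generator emulates the shape of a GWAS-versus-open-chromatin study at
desk scale. Defaults (all configurable in `SyntheticConfig`):

| parameter | default | meaning |
|---|---|---|
| genome | 2 chromosomes × 2 Mb, i.i.d. bases, GC 0.41 | human-like composition, no repeat structure |
| peaks | 500 disjoint intervals, Gamma-distributed lengths, mean 500 bp | ATAC-peak-like geometry |
| planted motifs | `GCAGCTGC` (E-box core, palindromic), `GGATTACA` | one exact consensus instance per chosen peak, uniform offset, random strand |
| plant rate | 0.45 per motif | fraction of peaks receiving each motif |
| panel | 200 haplotypes × 2,000 common variants | candidate sites oversampled, MAF ≥ 0.05 retained |
| LD blocks | 10 kb; 2–4 founders per block; per-site mutation 0.02 | high within-block, low between-block r² |
| risk loci | 60 index variants, LD-independent | the study variant set |
| effect | 0 (calibration) or as requested | fraction of indices placed so the locus overlaps the target subset |
| controls | 2 variant sets of 60, effect = 0 | negative-control "other-trait" sets |
| genes | 40 TSS | for distance matching |
| decoy annotations | 2 extra interval sets, same geometry | stage-1 non-target annotations |

The planted enrichment acts at index-placement level: a fraction `effect`
of indices is drawn only from variants whose locus overlaps the peaks
carrying the first planted motif. Index variants are drawn only from
matching bins that can supply the required controls, and are chosen
LD-independent of one another (as real GWAS signals are); study and control
draws are conditioned identically, so the effect = 0 configuration is an
exchangeable null and the tests' type-I error can be read off directly.

Because the panel holds 2,000 variants rather than millions, the scaled
study conditions use coarser matching bins and `min_controls = 20`
(`MatchingBins.scaled_default()`), and the workflow preset
(`AnalysisConfig.scaled_synthetic`) uses 1,000 permutations and
`min_subset = 50` (of 500 peaks, proportionally matching a 1,000-of-76,145
full-scale cut). The block length (10 kb), mean peak width (500 bp) and
plant rate (0.45) were fixed once so that an effect of 0.5 — thirty
LD-independent overlapping indices — is realizable across seeds.

**What the generator does not emulate** (hence what passing tests do not
show about real data): repeat and GC-heterogeneous genome structure,
coalescent-accurate LD and allele-frequency spectra, association summary
statistics (indices are placed, not mapped), realistic peak-width
distributions, or motif degeneracy beyond exact consensus planting.
Calibration and recovery results demonstrate correctness of the statistical
machinery under the stated generative model, not field performance on real
cohorts.

## Numerical and degenerate-input choices

- Intervals are BED 0-based half-open; bookended intervals merge during
  normalization (Jaccard depends on this and it is asserted in tests).
- Jaccard of two empty sets is 0, keeping pairwise matrices total.
- Chromosome names are opaque strings; no "chr1"/"1" aliasing.
- Permutation and Poisson-binomial p-values are clamped to (0, 1];
  `p_adjusted = min(1, p_raw × n_tests)`.
- Score discretization is 0.01 bits; all scan/DP comparisons happen on the
  integer scale, so they are exact rather than tolerance-based.
- All randomness flows through `numpy.random.Generator` seeded from the
  configuration; identical seeds give byte-identical fixtures and reports.
- `run_workflow` draws per-stage child seeds from one master generator, so
  adding annotations to one stage does not perturb another stage's draws
  within a run shape.

## Problem sizes used in validation

The shipped validation runs use 200 effect-free replicates (60 loci, 500
peaks, 2,000 variants, 1,000 permutations) for null calibration, 20
effect = 0.5 replicates of the full workflow for recovery and control
false-flag rates, and one planted fixture (~450 instances) for scan
recovery. These sizes give binomial 95% intervals tight enough to detect
meaningful miscalibration while keeping a full validation run in minutes on
one CPU.

## Known limitations

- The locus-shift window rule (50 kb minimum flank) is a design choice;
  published annotation-shifting tools do not document a single canonical
  boundary rule, and different flanks change the effective null density.
- The matched-control test treats control loci as independent draws; LD
  among controls within a bin is ignored (as is standard).
- The discovery stage tests literal k-mers only; degenerate motifs are
  found via their most enriched literal word, not as IUPAC patterns.
- Known-motif similarity has no p-value; the 0.8 correlation cutoff is a
  heuristic.
- Genotype phasing, imputation and population structure are out of scope;
  LD comes only from a supplied (or simulated) phased panel.
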