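# Methods

`tcrep` analyzes TCR-β immune repertoires from the CDR3 region: it turns
sequencing reads into clonotype frequency tables and computes the
clonal-expansion, diversity, usage, sharing and amplification-bias
statistics used to contrast autoimmune (T1D-like) repertoires with near-even
(T2D/control-like) ones.  Because raw study data of this kind are rarely
released, the package ships a ground-truthed synthetic repertoire generator
that reproduces the statistical regimes the analysis targets; every
statistical claim the test suite makes is made against that generator or an
independent oracle.

## Germline reference and CDR3 convention

A rearrangement is V–(trimmed D / N insertions)–J.  The CDR3 is delimited by
the conserved V-segment cysteine and the J-segment phenylalanine of the
F-G-X-G motif (tryptophan admissible by configuration); both anchor
positions are explicit per-segment metadata rather than rediscovered by
motif scanning, since reference numbering fixes them once.  The CDR3 is
reported *without* its anchor residues — no leading C, no trailing F —
which matches how expanded clones are conventionally printed (e.g.
`ATAGLAGETQY`).  A read is **productive** when the anchor-to-anchor span
preserves the reading frame (CDR3 nucleotide length divisible by 3) and the
translation contains no stop.  Coordinates are 0-based half-open
internally.

Allele-level segments collapse to the gene family (`TRBV15*01` →
`TRBV15`) for clonotype identity and all usage statistics; family lists are
ordered by locus nomenclature so usage vectors align across samples.

The packaged toy reference is synthetic: 8 V families (TRBV15 with two
alleles), 2 D segments and 6 J families with deterministic pseudo-random
framework regions.  It is not an IMGT release; it only guarantees correct
anchors, mutual distinguishability under alignment, and the motifs needed
for the worked examples (TRBJ2-5 encodes …E-T-Q-Y-F…).

## Read annotation

Paired-end mates are merged at the highest-scoring overlap of at least
`min_overlap` bases whose mismatch rate does not exceed
`max_mismatch_rate`; at a mismatching overlap position the base with higher
Phred quality wins (ties go to mate 1).

V and J calls come from dynamic-programming alignment (match +1, mismatch
−1, linear gap −2) of the read against every V segment, then every J
segment on the read suffix 3′ of the V match.  The alignment is *overlap*
(glocal): terminal gaps are free, so the alignment extends until one
sequence is exhausted at each end.  Identity is matches / aligned columns
(×100) over the region between the first and last matched pair.  This makes
the identity filter meaningful: a best-*local* alignment of an unrelated
read always contains a short near-perfect core with inflated identity,
whereas a spanning alignment of an unrelated read sits near the random
match rate (~50–60 %), well below threshold.  Aligned regions shorter than
15 columns are treated as no alignment (identity 0) to exclude spurious
corner overlaps.  Score ties between segments resolve to the
lexicographically smallest segment id.

Reads with `min(v_identity, j_identity)` below 70 % are excluded.  The
boundary is **inclusive**: exactly 70 % is kept.  (Descriptions of this
filter are ambiguous between "> 70 % selected" and "< 70 % excluded"; the
exclusion reading is applied literally.)  D segments are not called — no
D-level statistic is computed downstream — and no somatic hypermutation
handling is needed for TCRs.

## Clonotypes

Clonotype key: (CDR3 nucleotide sequence, V family, J family).  Only
productive, filter-passing reads enter; frequencies are normalized over
those reads, because a clone frequency expressed against "the total number
of CDR3 sequences" can only be a fraction of reads that have a CDR3.
Tables are sorted by descending count with lexicographic CDR3 tie-break.
No error correction or clustering of near-identical CDR3s is applied, so
substitution sequencing error inflates singleton clonotypes; recovery tests
therefore run at error rate 0 and the documentation flags the inflation for
error-bearing runs.  Amino-acid-level aggregation (summing counts of
synonymous nucleotide clonotypes) is a separate view used by the sharing
analysis.

## Expansion and diversity statistics

A **highly-expanded clone (HEC)** is a clonotype with within-sample
frequency ≥ 1 % (inclusive); the HEC ratio is the summed frequency of HECs.
Diversity is the normalized Shannon entropy

    H = − Σᵢ p(xᵢ) log p(xᵢ) / log n ,

with p(xᵢ) the clone frequency and n the number of *observed* clonotypes
(no richness extrapolation).  H ∈ [0, 1]; 1 means perfectly even, 0 means a
single clone — the n = 1 case is defined as 0 by convention since log 1 =
0.  Natural log is used internally; the base cancels.  Entropy is computed
on nucleotide-level clonotypes by default (the finest observed partition),
with an amino-acid-level flag for sensitivity analysis.  One caveat worth
stating: pooling two clones never increases the *raw* Shannon entropy
(concavity), but the *normalized* index can increase under pooling because
n shrinks too; the test suite asserts monotonicity on the raw entropy.

## Usage structure

Usage vectors, VJ-combination matrices and CDR3-length spectratypes are
read-weighted (clone counts weighted by read count), since expanded clones
are the phenomenon of interest; a clone-weighted flag exists for
sensitivity.  VJ-matrix margins equal the usage vectors exactly.  Pairwise
sample similarity is Pearson correlation of usage vectors; a zero-variance
vector has no defined correlation and is reported as missing, never as 0.
No per-family over-usage test is computed: the choice of test, threshold
and multiplicity correction for that question is genuinely open, and
guessing one would manufacture an unstated method.

## Shared-clone analysis

Sharing is at the amino-acid level only — a public clone is the same CDR3
protein sequence regardless of the nucleotide rearrangement encoding it —
and restricted to sequences that are a HEC in at least one case-group
sample.  Per sample a sequence is HEC (≥ 1 %), LEC (present, < 1 %) or
absent.  Classification: **type 1** = expanded in ≥ 1 case sample and
present (HEC or LEC) in ≥ 1 non-case sample; **type 2** = expanded in ≥ 1
case sample and absent from every non-case sample.  These are exhaustive
and mutually exclusive for recorded clones.  Records are ranked by the
number of case samples in which the clone is expanded; "shared by more than
half" counts strictly more than half.  The ranked list is emitted in full —
any truncation is a plotting parameter, not a statistic.

## Cohort comparison

Group summaries are median (midpoint convention for even n) and range.
Significance uses the unpaired two-tailed two-sample t-test with pooled
variance (Student) by default.  Welch's form is available via a flag; note
that R's `t.test` defaults to Welch, so an analysis citing "the t-test in
R" without detail is ambiguous between the two — the choice is therefore
surfaced prominently rather than hidden.  Degenerate inputs: both groups
constant and equal → t = 0, p = 1 by convention; both constant and unequal
→ error.  No multiple-testing correction is applied across the comparisons;
all raw p-values are reported together so users can correct as they
prefer.

## PCR amplification bias

Multiplex PCR amplifies each clone with a slightly different efficiency,
and the deviation compounds multiplicatively per cycle: a per-cycle bias b
grows to b^Δc over Δc cycles (1.076¹⁰ ≈ 2.09).  Two components are modeled
separately:

* **Within one amplification** (`simulate_reads`): independent per-cycle
  lognormal factors, accumulated log-sd σ·√cycles.  This is the stochastic
  cycle-to-cycle component; it perturbs cohort samples without the
  unbounded clone-specific jackpots that a fully correlated 25-cycle
  compounding would produce.
* **Across repeated amplifications of the same template**
  (`simulate_cycle_series`, the validation design): the clone's
  sequence-determined efficiency is the same in both runs, so the
  *difference* between a c₁- and a c₂-cycle amplification isolates the
  fixed component compounding as exp((c₂−c₁)·δ), δ ~ N(0, σ).  This is the
  only reading under which the accumulated bias obeys k = b^(c₂−c₁), and it
  is the component the estimator below inverts.

The estimator (one admissible reading of a prose-only description):
depth-normalize (expected c₂ count = c₁ count × total₂/total₁), compute
per-clone fold variation v = max(obs/exp, exp/obs), bin clones by c₁ count
on a log scale with ≥ 20 clones per bin, and fit the least-squares constant
k to the bin means (their unweighted mean); per-cycle bias = k^(1/(c₂−c₁)).
Two known inflations are deliberately *not* subtracted: the Poisson
sampling-noise floor (dominant at low counts), and a selection effect —
clones observed with few c₁ reads are enriched for negative efficiency
deviations, so low-count bins sit above the unconditional mean.  k is
therefore an upper bound on pure PCR bias, tightest at high counts and deep
coverage.  V-gene usage stability between cycle points is the mean absolute
relative usage deviation over the top-n families at the high-cycle point.

## Synthetic-data generator

What it emulates, with defaults:

| feature | model | default |
|---|---|---|
| clone abundances, control/T2D-like | normalized exp(Normal(0, σ)) | σ = 1 |
| clone abundances, T1D-like | n_e expanded clones share mass M via symmetric Dirichlet(2) over a 1 % floor; lognormal background | n_e = 22, M = 0.77 |
| richness | distinct clones per sample | 10⁴ control-like, 5×10³ T1D-like at study scale; smaller in desk-scale demos |
| junction structure | V suffix + N1 + trimmed D + N2 + J prefix | geometric trims, mean 2 nt per flank; each insertion uniform 0–10 nt |
| productivity | rejection sampling until in-frame, stop-free | on |
| sequencing error | per-base substitution only (no indels) | 10⁻³ |
| PCR bias | as above | σ = 0.076/cycle, 25 cycles |

The T1D-like defaults (22 expanded clones holding 77 % of reads) are the
case-group medians the analysis is designed around; the expanded-clone
construction `0.01 + spare·Dirichlet(2)` guarantees every expanded clone
meets the HEC definition while leaving variability.  The 1 % floor times
n_e must not exceed M, else the configuration is rejected.  Trimming means
and insertion ranges were chosen once to center CDR3 length near 11–13
amino acids (anchors excluded), the range typical printed clones occupy.
Clone identity in the truth table is the nucleotide junction plus V/J
family, so two clones may share an amino-acid CDR3 — required to exercise
amino-acid-level sharing.

What it does **not** capture, hence what passing tests do not show about
real data: thymic selection and HLA restriction (segment and junction
choices are uniform, so real usage biases are absent); allelic and
copy-number structure of a true germline locus; indel sequencing error and
chimeric/crossover PCR artifacts; primer-specific (non-random) efficiency
differences; UMI-based deduplication (the emulated protocol used none);
and the age/sex structure of a real cohort.

## Numerical choices and degenerate inputs

* Frequencies must sum to 1 within 1e-9 (truth tables, clonotype tables,
  usage vectors); entropy inputs are renormalized when within 1e-6.
* Geometric trims are capped so anchors survive; a rearrangement draw that
  fails productivity 1000 times raises rather than looping.
* Deterministic tie-breaks everywhere ordering matters: alignment ties by
  segment id, clonotype ordering by (count desc, CDR3 lexicographic),
  sharing ranks by (n_case_hec desc, CDR3 lexicographic).
* Identical read sequences are annotated once and cached; on deep
  error-free repertoires this reduces alignment work from reads to clones.
* All randomness flows through `numpy.random.Generator` seeds; pipeline
  runs are byte-identical given (config, seed).

## Problem sizes in the shipped checks

The test suite and demo run at desk scale, chosen so the full suite
finishes in a few minutes on one CPU while keeping every statistical check
well-powered: clonotype-recovery at 2×10⁵ reads over 10³ clones (total
variation < 0.02); annotation recovery at 10⁴ reads over 300 clones
(≥ 99 %); t-test calibration over 2000 simulated null cohorts of 9 + 6
samples with 10³ clones each; power over 100 case/control cohorts at study
group sizes (9, 6); bias recovery at 10⁴ clones and 10⁶–2×10⁶ reads per
cycle point.  The demo cohort (9 T1D-like + 4 T2D-like + 6 control-like
samples) uses 300–600 clones and 1000 reads per sample.

## Known limitations

* The alignment stage is exact dynamic programming intended for small
  references and desk-scale read counts, not a heuristic-seeded aligner
  for production-depth data against a full locus.
* k from the bias estimator conflates PCR bias with sampling noise at low
  counts (documented above); it validates, it does not correct frequencies.
* Entropy comparisons across samples of very different sequencing depth
  inherit the usual observed-richness dependence of normalized entropy;
  no rarefaction is applied.
* The identity filter, while meaningful under spanning alignment, is a
  simplification of E-value-based significance filtering.
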