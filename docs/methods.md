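# Methods

This note documents the models and procedures implemented in `epicircuit`,
the parameters that matter, the design choices made where the analysis was
genuinely open, and what the synthetic validation does and does not show.

## CpG dinucleotide merging and cohort filters

A WGBS caller reports the two cytosines of a CpG separately. They are merged
as a coverage-weighted mean of the per-strand methylation levels,
m = (m₁c₁ + m₂c₂)/(c₁ + c₂), with merged coverage c = (c₁² + c₂²)/(c₁ + c₂).
The coverage formula is a self-weighted mean — an unusual statistic that lies
between the arithmetic mean and the maximum of the two strand coverages — and
is implemented exactly in that form; the `CpGDinucleotide` invariants
((c₁+c₂)/2 ≤ c ≤ max(c₁,c₂)) are property-tested. The per-strand inputs are
interpreted as methylation *levels* (fractions), not methylated-read counts:
a level-weighted mean is only meaningful for levels, and the merge keeps m
inside [min(m₁,m₂), max(m₁,m₂)].

Cohort filters: CpGs overlapping a variant with minor allele frequency
strictly above 0.25 are removed (a CpG-disrupting SNP makes the methylation
call allele-specific); CpGs with fewer than 3 reads in strictly more than
50 % of samples are removed. Both boundaries are exclusive and both filters
are idempotent. Missing betas are carried as NaN with coverage 0 and are
never imputed here; smoothing/imputation belongs to upstream tooling and is
out of scope.

## Methylome segmentation and DMV/LMR/PMD calling

Segmentation is a two-stage rule:

1. **Distance blocks.** A new block starts whenever the gap to the previous
   CpG exceeds `gap_max` (default 1,000 bp).
2. **Methylation runs.** Within each distance block, every CpG receives a
   class — low (β ≤ 0.3), high (β ≥ 0.7), else intermediate — from a running
   *median* of the raw betas (window 5 CpGs, truncated at block edges), and
   maximal same-class runs become the final blocks. The median filter is
   edge-preserving: a single noisy CpG neither splits a hypomethylated run
   nor shifts its boundary, while boundaries between genuinely different
   regions stay sharp. Block mean/SD are computed on the raw betas (sample
   SD, n−1; single-CpG blocks get SD 0) and the block class is re-derived
   from the raw mean.

The methylation-based second stage is this package's own design: with
distance-only blocks, a CpG-dense chromosome collapses into one block and no
intra-block feature can ever be found. The class thresholds (0.3/0.7), DMV
minimum width 5 kb with mean β ≤ 0.15, and LMR mean β ≤ 0.5 with ≥ 4 CpGs
follow the hypomethylated-region literature and are all configurable through
`SegmentationParams`. Two rules are treated as fixed by the method: PMDs
require ≥ 10 kb width, and neighbouring LMRs merge when strictly less than
1 kb apart.

Feature calls operate on runs of same-class blocks (runs may bridge CpG-free
gaps up to `feature_merge_gap`, default 2 kb, so a short CpG desert inside a
valley does not split it): low runs become DMVs (wide + low mean) or LMRs;
intermediate runs become PMDs when the pooled mean lies in (0.3, 0.7), the
pooled sample SD is ≥ 0.1 (PMDs are *disordered*, not merely intermediate)
and the width reaches 10 kb. PMD calling is deliberately an interval rule,
not an HMM: the simpler rule is transparent, testable against planted truth,
and sufficient for domains whose defining property is a wide intermediate,
high-variance methylation profile.

**Consensus and sharing.** Consensus regions are built genomecov-style:
per-base support counting over the per-sample (per-class) feature stacks,
then merging maximal runs above threshold. Two modes reflect two published
rules — an absolute cross-sample coverage of ≥ 4, and, per subtype, support
in strictly more than 50 % of that subtype's samples. Sharing fractions
partition the union of the subtype consensus sets by the number of subtypes
covering each base; they are non-negative, sum to 1 and are symmetric under
subtype relabelling (property-tested).

## Chromatin-state enrichment

The overlap statistic is the base-pair Jaccard s = bp(a∩b)/bp(a∪b) on merged
sets. The permutation null relocates the query features into a
CpG-content-matched background:

* window size w = 25th percentile of feature widths (linear-interpolation
  quantile), rounded half-away-from-zero to the nearest 1,000 bp — in that
  order — then clipped to [1 kb, 10 kb];
* features are split into w-windows; fragments narrower than w/4 are dropped
  (their CpG content estimate would be too noisy);
* each window's CpG content p = CpG sites per kb; the genome is tiled into
  w-windows and those with p inside [P5, P95] of the feature windows' p form
  the background.

Shuffling follows genome-arithmetic semantics restricted to an inclusion
set: the background windows are merged into maximal runs and each feature
lands uniformly over every position that keeps it inside one run. Features
may overlap each other; a feature wider than every run is rejected with a
diagnostic. Because calibration features can be drawn with the *same*
placement routine, the null is exact by construction — the acceptance suite
verifies mean z ≈ 0 and uniform empirical p over 100 replicates. The
empirical p uses the (1+k)/(1+n) estimator so it can never be zero; z is
reported as NaN when σ = 0 (e.g. an empty state set).

ChromHMM conveniences: state collapse (E01–E04 → TSS, E07–E11 → Enh, rest →
other), per-peak annotation by largest overlapping state (ties to the lowest
state index, deterministic), and the ≥ 50 % modal consensus state after
re-cutting all samples on their common breakpoint grid (ties break
lexicographically).

## Superenhancers and core regulatory circuits

Peaks with gaps ≤ 12.5 kb are stitched transitively; per-sample signal is
summed over constituents. For SE calling, enhancers are ranked ascending by
signal, both axes are min-max scaled to [0, 1], and the cutoff is the signal
at the point minimising y − x — the point where a slope-1 line is tangent to
the curve from below, the standard rank-curve elbow. Enhancers strictly
above the cutoff are SEs; a flat curve has no elbow and yields none. The
call is invariant to positive rescaling of the signal (tested). TSS-proximal
exclusion during stitching is available as an option but off by default.

Subtype SEs: classic one-way ANOVA on the linear signal across subtypes,
BH adjustment across SEs, per-subtype log₂ fold change of the subtype mean
over the mean of all other samples (pseudo-count 10⁻⁶), assignment to the
argmax-logFC subtype iff adjusted p ≤ 0.1 and that logFC ≥ 1. All-constant
SEs are flagged and left untested. The MES-vs-RTK I comparison statistic is
a per-sample Welch t between the sample's signals over the two subtype SE
sets.

Target assignment: candidates are genes with a TSS within 500 kb of the SE
boundary *and* in the same TAD as the SE midpoint; the highest Spearman
correlation (average ranks for ties) between SE signal and gene expression
wins, with ties broken by TSS distance then gene id. Constant vectors have
undefined ρ and are excluded. CRC cliques: autoregulatory TFs (own SE
contains own motif) form a graph with an edge when each TF's SE carries the
other's motif; circuits are the maximal cliques, enumerated via
networkx and verified against exhaustive subset search for ≤ 12 TFs.

## Master-regulator activity and single-cell scoring

MR activity (NES) is consumed as a matrix; network inference and enrichment
scoring are upstream tools' jobs and the consensus logic over their outputs
is what is implemented here. An MR's subtype is the argmax of its per-subtype
mean activity (ties flagged, lexicographic). Consensus MRs must satisfy, in
both networks: adjusted p < 0.01, same subtype, same sign of the signed
activity score.

Per-cell calls z-score each MR across cells (population SD; constant rows
dropped with a flag) and take the subtype with the maximum mean z. Signature
scores match, per signature gene, the 100 non-signature genes closest in
*dataset-wide* mean expression, subtract the background mean cell-wise and
sum over the signature. Dataset-mean matching (rather than per-cell
matching) keeps the background fixed across cells; per-cell matching would
make the control set cell-dependent and combinatorially unstable. The score
is invariant to global additive shifts (tested to 10⁻⁹).

CNA classes use the thresholds −1, −0.2, 0.2, 1 on the processed log-ratio.
The published intervals are open and leave the boundary values undefined;
boundaries are assigned to the lower-magnitude class (x = −1 → loss,
x = ±0.2 → no change, x = 1 → gain), configurable in principle and recorded
here as the package's convention.

## Synthetic data: what it emulates, what it does not

No published noise model exists for any of these data types, so the
generators use deliberately simple, configurable laws:

* **Methylomes** — CpG positions with geometric inter-CpG gaps (mean 100 bp,
  shared across the cohort); per-CpG beta = planted regional mean (baseline
  0.8 elsewhere) plus Gaussian noise (SD 0.05) censored to [0, 1], with a
  beta-distributed option; planted PMDs draw per-CpG means from
  N(target, 0.12) to produce the disorder PMD calling requires; coverage is
  negative binomial (mean 10, dispersion 0.3), matching WGBS overdispersion.
* **State annotations** — geometric segment lengths, iid states at requested
  proportions (realised bp fractions converge for Mb-scale chromosomes).
* **SE cohorts** — log-normal H3K27ac signal; subtype SEs shifted by the
  planted log₂ FC; target-gene expression follows the SE's standardised log
  signal at latent correlation ρ (decoys independent); geometry guarantees
  each target is within 500 kb and the same TAD as its SE.
* **Activity matrices** — standard-normal background with a +effect·SD shift
  in the planted subtype's samples.
* **Single-cell expression** — gene baselines uniform on [2, 8], unit
  Gaussian cell noise, signature genes shifted in the planted positive cells.

These cohorts do **not** emulate read-level artefacts, bisulfite conversion
error, copy-number confounding of methylation, CpG-island clustering (beyond
an optional densification hook), batch structure, or single-cell dropout.
Passing the recovery suite therefore demonstrates that the *rules* are
implemented correctly and are robust to calibrated noise — not that the
thresholds are optimal for any particular real cohort.

## Validation scenarios and problem sizes

The canonical scenarios (in `epicircuit.scenarios`) fix the simulated study
conditions; only the seed varies between runs:

* methylome recovery — one 2 Mb chromosome, ~20,000 CpGs, 4 subtypes × 3
  samples, noise SD 0.05, coverage 10; per class, 60 % of planted width in
  all four subtypes, 20 % in two, 20 % in one (so sharing fractions have
  known truth 60/20/20/0 for k = 4/2/1/3);
* enrichment — a 1 Mb toy genome, 30 % enhancer state; null calibration over
  100 replicates × 200 permutations, power at 1,000 permutations;
* SE targets — 20 SEs, 10 candidate genes each, 40 samples, ρ = 0.9;
* MR assignment — 100 MRs, 500 samples, 1.5 SD effect (and a zero-effect
  null whose assignment frequencies must be uniform);
* signature scoring — 500 cells, 2,000 genes, 30-gene signature, 1 SD shift
  in half the cells.

These sizes keep a full reproduction run under a minute on one CPU while
leaving the planted effects at realistic, not saturating, magnitudes.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open throughout; book-ended intervals merge.
Quantiles use numpy's linear interpolation. Empty interval sets: Jaccard of
two empty sets is undefined (raised), an empty state set gives s = 0 with
σ = 0 and NaN z; an empty sharing union is raised. Sample SD (n−1) for
block statistics, population SD for cell z-scores. Ties: lowest state index
(annotation), lexicographic subtype (MR assignment) and state (consensus),
TSS distance then gene id (targets). Determinism: every stochastic routine
takes an explicit seed and identical configuration + seed reproduces
byte-identical output.

## Known limitations

* The DMV/LMR neighbour rules and block thresholds beyond the fixed 10 kb /
  1 kb constants are literature-informed defaults, not fitted values.
* PMD calling by interval rule will differ from HMM-based callers near
  boundaries and in short, noisy domains.
* The SE elbow uses the geometric tangent on the scaled curve; external SE
  tools differ in smoothing details, so absolute SE counts are not expected
  to match other implementations exactly.
* Enrichment matches CpG content only (not GC content), as specified by the
  background construction it implements.
* The consensus-MR stage consumes significance records; it inherits whatever
  multiple-testing behaviour the upstream enrichment tool applied.
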