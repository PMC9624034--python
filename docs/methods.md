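# Methods

This note records the statistical model behind each stage, the
conventions and defaults, what the synthetic generator does and does
not emulate, and the design choices made where more than one
reasonable convention exists.

## Coordinates and annotation

All internal coordinates are 0-based half-open. GTF input is 1-based
inclusive and converted on ingest (start−1, end); the probe manifest
is declared 0-based (a `one_based` flag converts 1-based extracts).
The promoter window covers strand-relative offsets [−2500, +1000)
around the TSS. On the plus strand the TSS is the transcript start;
on the minus strand it is the last transcribed base (end−1) — the
standard antisense convention — giving the genomic window
[tss−downstream+1, tss+upstream+1). Windows are clipped at the
chromosome origin; unclipped windows are exactly 3500 bp on either
strand, and the construction is exactly symmetric under coordinate
reflection. Probes are joined to promoters per transcript by half-open
containment, ignoring probe strand (a CpG is strand-symmetric), and
(probe, gene) pairs are deduplicated, so multi-TSS genes union their
promoters — the most inclusive, deterministic reading.

CpG islands use the Gardiner–Garden criteria: a 200-bp window (step
1 bp) passes when GC fraction ≥ 0.5 and observed/expected CpG
= (#CG · L)/(#C · #G) ≥ 0.6; overlapping or touching passing windows
merge into maximal islands, and each merged island is re-validated
against all three thresholds (and dropped in the rare case the merged
statistics fall below them). N bases count toward window length but
not toward base counts. Island boundaries therefore extend up to one
window length beyond the CpG-dense core, as with any sliding-window
island finder.

## Rank tests and FDR

Group differences (per-gene DE, per-probe DM, BSP group comparison)
use a two-sided Mann–Whitney U test: the exact null distribution when
n₁+n₂ ≤ 12 with no ties, otherwise the normal approximation with tie
and continuity corrections. Degenerate inputs (all values identical)
are assigned p = 1 rather than an error. Multiple testing is
controlled by Benjamini–Hochberg across all tested features. The
paired BSP comparison uses the Wilcoxon signed-rank test; note its
two-sided p is bounded below by 2/2ⁿ, so very small cohorts cannot
reach p < 0.001 regardless of effect size.

Expression is normalized to counts per million with a pseudocount in
both numerator and denominator,
CPM[g,s] = (c[g,s]+pc) / (lib[s]+2·pc·G) · 10⁶ with pc = 0.5 by
default, keeping values strictly positive; log2 fold change is the
log ratio of group mean CPMs, and "fold change ≥ 2" maps to
|log2FC| ≥ 1. The package deliberately ships a single built-in
rank-test DE engine rather than wrapping edgeR/limma/DESeq2;
externally produced DE tables can be imported in the same schema and
intersected with the built-in results by `consensus`, which by
default also requires direction concordance (a flag disables it,
since a pure set intersection is equally defensible).

## DMR detection

Region calling is a bumphunter-style candidate + permutation scheme
with two documented simplifications: no loess smoothing (the raw
per-probe Δβ is the statistic) and area = Σ|Δβ| over member probes.
Probes are clustered per chromosome at inter-probe gap ≤ 500 bp (not
a universal constant; exposed as `max_gap`), candidates are maximal
same-sign runs with |Δβ| ≥ 0.2 and ≥ 2 probes, and the null
distribution permutes the sample labels 100 times, recording the
maximum candidate area per permutation. The empirical p uses +1
smoothing, p = (1 + #{null max ≥ area})/(B+1), so p > 0 always and
p ∈ {k/(B+1)}. Missing betas are imputed as the observed group mean
for permutation rounds only, keeping the permutation null
exchangeable while the reported Δβ uses observed values. Changing B
never changes which candidates exist, only their p. This matches the
stated operating parameters of array bump hunting (cutoff 0.2,
resamples 100, ≥ 2 probes) without claiming bit-for-bit equality with
any specific array package.

## Integration

A methylation-driven pair requires the probe significant in the DM
screen, the gene significant in the DE screen, and the probe inside
the gene's promoter. Direction concordance (hyper+down / hypo+up) is
OFF by default — both discordant configurations are biologically
reportable — and available as a flag. "Top-k" rankings represent each
gene by its max-|Δβ| promoter probe, rank by |Δβ| descending and
break ties lexicographically by gene id. Spearman ρ between promoter
beta and expression uses average ranks; its p-value is computed by
exhaustive permutation for n ≤ 8 and by the t-approximation above
that. Fewer than 3 complete pairs, or a zero-variance vector, yields
a missing ρ rather than an error.

## BSP clone analysis

Only the bisulfite top strand is modelled (C→T). Against the
reference amplicon, each CpG cytosine reads C = methylated,
T = unmethylated, anything else (including a deletion) = ambiguous;
ambiguous calls are excluded from both numerator and denominator of
all rates, to avoid letting sequencing errors bias them. The
conversion rate is the fraction of non-CpG reference cytosines read
as T; clones below 0.95 fail QC (the conventional threshold class;
an unconverted clone has rate 0 and always fails). Clones with indels
are first projected onto reference coordinates with a global
Needleman–Wunsch alignment (match +1, mismatch −1, gap −2, with ref-C
vs clone-T and ref-G vs clone-A scored as matches so conversion never
penalizes the alignment). Sample rates pool passing clones; fewer
than 10 passing clones warns (the protocol's expectation) and zero is
an error.

## ROC and Youden cut-off

Thresholds are the midpoints between consecutive distinct marker
values plus ∓∞ sentinels, making the cut-off independent of sample
order; a sample is positive iff value ≥ threshold (high methylation =
tumor by default; a flag reverses the direction, with thresholds
still reported ascending on the marker's own scale). The AUC is the
trapezoid area of (1−specificity, sensitivity), which equals the
tie-aware U-statistic U/(n₁·n₀) with half credit per tie. The Youden
optimum maximizes J = sens + spec − 1; ties are broken toward higher
sensitivity, then the lower cut-off. The reported cut-off is the
midpoint threshold itself.

## Survival

Markers are dichotomized at the median (average-of-middle-two), with
"high" meaning strictly greater; the quantile is configurable.
The Kaplan–Meier estimator uses the convention that a subject
censored exactly at an event time is still at risk at that time; with
no censoring the curve equals the empirical survivor function
exactly. The log-rank test is the standard 1-df chi-square with
hypergeometric variance; it is checked against lifelines in the test
suite but implemented here so the at-risk and split conventions are
explicit. Cox regression and time truncation are out of scope; an
optional truncation would be a trivial pre-filter on the records.

## Synthetic data model

Each generator draws from its own stream derived from the master seed
by a fixed offset, so outputs are byte-identical across runs and a
single generator can be rerun in isolation. Defaults define the study
conditions: 20 tumor vs 20 normal arrays, 120 lncRNA genes on two toy
chromosomes, 800 probes of which 10% of genes are drivers carrying a
5-probe promoter block (80 bp spacing) with planted |Δβ| = 0.5
(70% hypermethylated); null probes draw Beta(2,2) in both groups.
Counts are negative-binomial with dispersion 0.2 around lognormal
baselines (median ≈ 200); in linkage mode (default) a driver's mean
is scaled by 2^(−k·β̄prom) with k = log2FC/Δβ, so the planted
two-fold change emerges from the methylation draws themselves and
drivers show negative Spearman ρ. BSP clones (18 tumor/normal pairs,
10 clones each over a 360-bp, 20-CpG amplicon) methylate each CpG
with probability 0.361 (tumor) or 0.055 (normal) and convert
cytosines with efficiency 0.99 — effect sizes chosen to echo the
regimes reported for validated promoter biomarkers. Survival times
are exponential with baseline median 60 months and hazard ratio 3 for
the high-methylation group; with probability equal to the censoring
rate (0.3) a subject is censored at a uniform fraction of its event
time, making the censoring fraction exact in expectation.

What the generator does **not** emulate: Infinium I/II probe-type
bias, array normalization artefacts and cell-type composition;
RNA-seq library-preparation and gene-length effects; sample-level
heterogeneity in clone methylation probabilities (all samples of a
group share one p, so the synthetic BSP classifier separates more
cleanly than clinical cohorts do); and any dependence between the
molecular and survival generators beyond the group labels. Passing
tests therefore demonstrate correctness of the computations and
calibration of the tests under the assumed model, not performance on
real cohorts.

## Numerical and degenerate-input choices

- Exact/asymptotic Mann–Whitney switch at combined n = 12; exact
  Spearman permutation up to n = 8 — both balance exactness against
  cost and are documented constants, not tuned values.
- Probes with fewer than 2 non-missing betas in either group are
  skipped and counted, not errored.
- A zero-total library, single-class ROC labels, all-equal markers,
  zero passing clones, or an empty group each raise a named error;
  empty DMR or pair sets are valid results, not errors.
- Problem sizes in the test suite and acceptance script (hundreds of
  probes/genes, tens of samples, ≤ 100 permutations) are chosen so
  the planted-truth recovery properties are comfortably powered while
  the whole suite runs in well under a minute; they are the package's
  own defaults, scaled versions of the same model.
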