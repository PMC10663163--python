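# Methods

## The cryptic-transcription score

Cryptic transcription (CT) — initiation at intragenic, non-promoter sites —
adds reads to a gene's 3′ exons without touching its first exon. The score
exploits this asymmetry. For each gene we select the transcript with the
largest summed exonic length (ties broken by lexicographically smallest
transcript id, so selection is deterministic) and rank its exons in
transcription order: rank 1 is the promoter-proximal exon on either strand.
Coordinate-order ranking is available as a config switch
(`rank_order="coordinate"`), but it would misassign "first exon" for
minus-strand genes, which is half the genome, so transcription order is the
default. Internally all coordinates are 0-based half-open; GTF input
(1-based inclusive) is converted at the boundary.

Intermediate exons are ranks 4 through penultimate. A transcript therefore
needs at least five exons to have a non-empty intermediate set; four-exon
genes are retained in the model but can never score. The score is

  ratio = pooled intermediate density / first-exon density,

where the pooled density sums counts over summed lengths
(coverage-weighted). This matches the read-level expectation under uniform
coverage within exons; an unweighted per-exon-mean variant is available
(`aggregate="mean"`) but is not the default. No pseudocounts are used:
a zero first-exon count yields status `no_first_signal`, a zero pooled
intermediate count `no_intermediate_signal`, and such entries simply drop
out of downstream medians rather than contributing an arbitrary value.

### Gene filters

Two dataset-level filters run before scoring: fewer than four exons, or
mean RPKM across **all** samples below exp(−2) ≈ 0.1353. Reading the filter
as a disjunction (either condition discards) makes both clauses
independently meaningful, and using the pooled mean (rather than
per-sample RPKM) keeps the scored gene universe constant across samples of
one dataset — so a single gene count describes a whole study. A per-sample
variant of the expression filter is deliberately not the default. RPKM uses
the chosen transcript's exonic length, consistent with the length used by
transcript selection.

## Comparisons

The analysis unit is the per-sample median of log2 ratio over scored genes,
optionally within expression strata. Strata are rank-based quantile bins of
mean RPKM (deciles for expression-resolved plots, terciles for ChIP rows);
sizes differ by at most one, with the remainder allocated to the upper
strata so "top tercile" has ⌈n/3⌉ genes, and ties resolve by stable gene-id
order so the partition is permutation-invariant.

Three comparison engines are provided:

- **Wilcoxon rank-sum**, two-tailed, unpaired. Exact enumeration when the
  pooled sample count is ≤ 20 and tie-free; otherwise the normal
  approximation with continuity and tie corrections. The cutoff at 20 keeps
  exact enumeration cheap while covering the sample sizes this assay
  actually produces.
- **Student t-tests** (pooled, Welch, paired) for day-vs-baseline
  comparisons in time courses.
- **OLS on the medians** with a condition factor (dummy-coded against a
  declared reference: control / untreated / day 0) and nuisance
  covariables — categorical ones dummy-coded, numeric ones linear. Each
  non-reference level yields a treatment-vs-reference contrast (estimate,
  se, t, residual df, two-sided p). Rank-deficient designs raise an error
  naming the aliased columns rather than silently dropping them. No
  multiplicity adjustment is applied to condition contrasts; a
  Benjamini–Hochberg step-up is available separately where set-level
  screening wants it.

For human-cohort-style designs the response is the median per
(sample, decile) cell with decile entering as a categorical covariable —
the only reading under which an expression quantile is a meaningful
covariable of a median.

## Rescued-gene selection, enrichment, reprogramming score

Selection takes two per-gene CT fold-change vectors on the natural ratio
scale: induction (reprogrammed vs baseline) and rescue (treated vs
reprogrammed). Genes in the upper 25% of the first AND the bottom 25% of
the second are selected. Quantiles are empirical with linear interpolation
and boundaries are inclusive; a fully degenerate input (all deltas equal)
selects everything and emits a warning instead of failing.

Over-representation uses the exact hypergeometric upper tail
P(X ≥ k) with N = scored-gene universe, m = in-universe set size, n =
selection size. Sets with in-universe size outside [8, 499] are skipped;
rows are ranked by unadjusted p (default report threshold p < 0.005), with
a BH column alongside for convenience. The scored-gene universe (not the
whole annotation) is the default background, since only scored genes could
ever be selected.

The reprogramming score of a sample is the mean over signature genes of
per-gene z-scores (ddof = 1) of a variance-stabilised expression matrix.
The default transform is log2(CPM + 1); the transform is an injection
point, so a regularised-log matrix computed elsewhere can be passed in
unchanged (`transform=None`). Signature genes missing from the matrix or
with zero cross-sample variance are dropped with a warning. Signatures are
built from a differential table by FDR < 0.05 and fold change strictly
greater than 2, one-sided as stated by the source of the signature (an
absolute-value option exists but is off by default).

## ChIP gene-body profiling

Coverage is handled as run-length tracks. Binning computes per-window mean
depth with "w0" semantics — uncovered bases contribute zeros to the
denominator — and the terminal partial window is averaged over its actual
width, so coverage mass is exactly conserved (tested to 1e-9). The
meta-gene matrix uses 1,000-bp flanks in 50-bp bins and a gene body
linearly rescaled to 100 bins by mass-preserving averaging (the bin count
is a free choice; 100 keeps body resolution comparable to the flanks while
making conservation testable). Minus-strand rows are reversed so the 5′
flank is always leftmost. The gene-body fraction is the coverage mass
inside merged gene bodies over total mass; it is scale-invariant by
construction, and a per-million variant is a scaling flag away. Rows are
split by mean RNA-seq RPKM terciles with the same stratifier as the
expression analysis.

## The simulator

The generator emulates the statistical structure of a multi-condition
exon-count study. Per gene: exon count uniform on 3–12, exon lengths
log-uniform on 80–1,200 bp (realistic mammalian exon scales), expression
λ_g log-normal (default median 0.2 reads/bp, σ = 1, giving tens of reads
on a typical exon at unit size factor). Canonical transcription puts
λ_g·L_j·s expected reads on exon j; a condition with cryptic rate θ adds
θ·λ_g·L_j·s to every exon at or downstream of the cryptic start rank. The
start rule is either fixed (default rank 4, the first intermediate exon) or
uniform over ranks 2…n. Cryptic transcripts contribute nothing upstream of
their start and full density downstream — a deliberate simplification (no
partial overlap of the first cryptic exon) that makes the expected ratio
exact in closed form: 1 + θ for a fixed start ≤ 4, and a length-weighted
mixture 1 + θ·ΣL_j·(j−1)/(n−1)/ΣL_j for the uniform rule (e.g. 1.35 at
θ = 0.5, n = 6, equal lengths).

Counts are negative-binomial with variance = mean + α·mean²; α = 0
degenerates to Poisson. The default α = 0.1 is a typical bulk RNA-seq
dispersion and is also the value used by the recovery studies. Metadata
emulate the study designs around the assay: named conditions, alternating
sex, day parsed from condition names like "D6", and a two-cage structure
whose cage-B membership can be skewed toward non-reference conditions by a
confounding weight (realised as exact counts, so planted confounding is
deterministic). A cage batch effect enters the cryptic rate
multiplicatively on the (1+θ) scale, i.e. additively on log2, which is the
scale the covariable model works on. A planted-gene mechanism gives a
chosen subset of scoreable genes its own per-condition rate schedule — the
ground truth for selection/enrichment recovery. All randomness flows from
one seed through independent per-table child streams, so every emitted
artifact is byte-reproducible.

What the simulator does **not** model: read-level effects (GC, positional
bias, mappability), isoform switching, partial first-cryptic-exon overlap,
between-sample composition shifts beyond a scalar size factor. Passing
recovery tests therefore demonstrates the pipeline's correctness under the
generative model it assumes, not robustness to alignment- or
library-preparation artefacts in real data.

## Validation studies and problem sizes

The acceptance studies (tests and `scripts/acceptance.py`) use desk-scale
designs chosen to finish in seconds while keeping the statistics
interpretable:

- Recovery: θ ∈ {0, 0.2, 0.5}, 200 genes, 6 samples/condition, α = 0.1,
  50 replicates; monotonicity of per-condition mean medians and power of
  the θ = 0.5 contrast.
- Closed-form agreement: 120 six-exon genes at high depth (λ median 2
  reads/bp, α = 0.01), fixed- and uniform-start rules, 3-standard-error
  band.
- Type-I calibration: equal θ in both groups, 8 samples per condition,
  1,000 replicates. The exact Wilcoxon test is discrete, so its attainable
  size depends on group sizes; for 8 vs 8 the attainable two-sided size at
  nominal 5% is 0.0499 (computed from the exact null U distribution),
  which is why this design uses 8 — at 6 vs 6 the attainable size is
  0.0411 and the test would look conservative for reasons that have
  nothing to do with the pipeline.
- Confounding: injected shift δ = 0.3 log2 units, cage effect γ = 0.4,
  cage-B membership 1/6 vs 5/6 (planted bias γ·2/3 ≈ 0.267), 200
  replicates, 100 genes.
- Planted rescue: 200 genes, 25 planted, background θ 0 / 0.15 / 0.15 and
  planted θ 0 / 0.8 / 0.05 across baseline / induced / treated, 50 seeds.

## Known limitations

- The score presumes uniform within-exon coverage; strong 3′ bias in the
  library would shift ratios for all genes and should be compared only
  within one protocol.
- The exact Wilcoxon branch caps at 20 pooled observations; beyond that
  the corrected normal approximation is used, which is standard but not
  exact.
- RPKM is the only normalisation offered (by design — the ratio is
  internally normalised per sample); datasets needing between-sample
  composition correction should pre-normalise counts upstream.
- The log2(CPM+1) transform is a stand-in for a regularised-log transform
  in the reprogramming score; at low counts its variance stabilisation is
  cruder, which is why the transform is pluggable.
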