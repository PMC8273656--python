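# Methods

## Model and procedure

`cbcnv` is a depth-of-coverage caller: under uniform sequencing, the read
count of a genomic window scales with its copy number, so a tumor region at
copy number `c` in a sample of tumor purity `TP` has expected depth

    f(c, TP) = (TP·c + (1−TP)·2) / 2

times the diploid baseline. Rather than fitting a depth distribution and
thresholding it, the caller embeds read-depth *segments* in a 2-D feature
space and finds outliers there.

Each sample (tumor and normal) is processed independently through the same
pipeline; the matched design enters only at the end, when tumor calls are
classified somatic or germline by overlap with the normal's calls.

### Preprocessing

Per-bin mean depths are computed on fixed non-overlapping bins; any bin
containing an `N` reference base is masked (reads cannot map there, and
such bins mimic homozygous deletions). GC bias is corrected stratum-wise,
`RD'_i = RD_i · RD_m / RD_gc`, with GC rounded to 1% strata — the common
convention; the correction leaves each stratum's mean equal to the global
mean and preserves the global mean exactly. Correction follows masking,
i.e. abnormal bins are removed first.

The corrected profile is denoised by the 1-D fused lasso
(`½Σ(y−β)² + λΣ|Δβ|`), solved *exactly* by a single-pass direct algorithm
(`cbcnv._tv`). Exactness matters: maximal runs of equal fitted values are
the segments, so an approximate iterative solver would fragment runs.
Correctness is certified in the tests two independent ways — a dual
box-constrained least-squares solve and a KKT optimality certificate
(`u = cumsum(y−β)` must stay inside `[−λ, λ]`, vanish at the end, and sit
on the boundary with the matching sign at every jump).

### Feature transform

With `RDS_i` the segment values and `RDS_m` their mean, each segment maps
to `(CN_i, RDSD_i)`, where `CN_i = 2·RDS_i/RDS_m` and `RDSD_i` is the mean
absolute difference between the segment's ratio `RDSR_i = RDS_i/RDS_m` and
its `L` left/right neighbours. The five boundary cases of the window
definition are implemented verbatim, including its two idiosyncrasies:
the interior window nominally includes the (zero) self term but the
denominator `2L` counts only neighbours, and the fourth case's window ends
at element `n−1`, excluding the final element. Profiles shorter than a
full window clip the range to valid indices and divide by the count of
actual non-self terms. Both features are invariant to rescaling all
depths, so coverage differences between samples do not matter.

### Scoring and calling

k-means (k-means++ seeding, `n_init = 10`, fixed seed) partitions the
feature points. Clusters sorted by descending size are split at the
smallest boundary `θ` whose leading clusters hold at least a fraction
`x` of all segments *and* whose boundary cluster is at least `y` times the
next one; when no `θ < k` satisfies both, the mass rule alone decides
(the original cluster-based outlier formulation treats the two conditions
disjunctively; a strict mode raises instead). Scores: small-cluster
members take the Euclidean distance to the nearest large-cluster centre,
large-cluster members the distance to their own centre.

Calls are segments with score strictly above the upper Tukey fence
`T = Q3 + w·(Q3−Q1)` (quartiles by linear interpolation); ties are normal.
Adjacent called segments merge into one region (score = members' max,
depth = bin-weighted mean). Typing compares each call's mean depth with
the bin-weighted mean depth of all *uncalled* segments: `≥ baseline` is a
gain (ties deliberately gain, per the rule's "greater than or equal"),
otherwise a loss. A tumor call with ≥50% reciprocal overlap with any
normal-sample call is annotated germline (not removed), otherwise somatic.

## Parameters

| name | default | meaning |
|---|---|---|
| `bin_size` | 2,000 bp | window width; resolution limit of the caller |
| `L` | 10 | RDSD neighbour half-width (valid range 5–20) |
| `k` | 5 | k-means cluster count |
| `x` | 0.9 | large-cluster cumulative mass ratio |
| `y` | 5 | large/small size-gap multiple |
| `w` | 1.5 | Tukey abnormal weight |
| `λ` | data-driven | fused-lasso penalty |

`λ` defaults to the universal-threshold rule `2·σ̂·√(log n)` with
`σ̂ = 1.4826·median(|Δy|)/√2`, a robust noise-scale estimate from first
differences that is insensitive to the (sparse) true jumps. A fixed `λ`
can be supplied (`--lam`); `λ = 0` reduces segmentation to the identity.

Open design points and how they were resolved:

* **`RDS_m` convention** — "mean over segments" is ambiguous; the default
  is the bin-weighted mean (equals the mean corrected bin depth, since the
  fused-lasso fit preserves the signal total, and is invariant to how a
  constant stretch is split into segments). `weighting="segment"` gives the
  unweighted alternative.
* **Quartiles** — linear interpolation between order statistics, the
  ubiquitous default; configurable only in the sense that scores are
  exposed and any fence can be recomputed.
* **Germline test** — "exists in both samples" is concretized as ≥50%
  reciprocal overlap, consistent with the 50% rule used for evaluation.
* **Merged-call monotonicity** — the set of called *segments* shrinks as
  `w` grows (T is non-decreasing in `w`); the number of merged intervals
  can transiently rise when a middle segment drops out and splits a run,
  which is why the monotonicity tests assert on membership.

## Simulator

`cbcnv.simulate` emulates the benchmark protocol: one 40 Mb chromosome in
2 kb bins, 22 CNVs per tumor sample — 12 gains (copy number drawn
uniformly from 3–6; the gain multiplicities are this package's choice),
4 heterozygous (CN 1) and 6 homozygous (CN 0) losses — with lengths drawn
from the six evaluated levels {2, 6, 10, 30, 50, 100} kb, placed disjointly
with at least one diploid bin between events. The diploid baseline is
`coverage·bin_size/read_length` reads per bin (200 at 10×/2 kb/100 bp).

Counts are negative binomial with `Var = μ + d·μ²` (`d = depth_noise`,
default 0.005, ≈10% CV at the baseline; `d = 0` gives Poisson). GC is a
smooth profile in [0.3, 0.6] (long-wavelength sinusoid plus smoothed
noise) with a quadratic depth response peaked at 45% GC (≈16% depth drop
at the extremes), so the GC-correction step is exercised non-trivially —
a flat GC profile would make it untestable. A synthetic reference FASTA
whose per-bin GC matches the profile exactly can be emitted to exercise
the FASTA-based binning path.

What the simulator does **not** model: read-level artifacts (it draws bin
counts, not reads), mappability bias, replication-timing waves, subclonal
heterogeneity, and germline CNVs shared by both samples. Passing recovery
tests therefore demonstrates that the statistical chain works under
purity-diluted, GC-biased, overdispersed depth signals — not that the
caller is robust to every artifact of real libraries.

## Problem sizes and numerical choices

The recovery tests and the acceptance script use the full protocol scale
(20,000 bins per sample, 10 samples per purity at 0.2 and 0.3); each
sample takes well under a second, the segmentation being linear-time.
Observed behaviour at these settings: 100 kb events are recovered with
sensitivity ≳0.9 at purity 0.3 while single-bin 2 kb events fall below the
default `λ`'s resolution; overall FDR stays near 0.1; sensitivity rises
with purity, as the mixture model predicts.

Degenerate inputs are handled explicitly: a constant profile yields one
feature point (2, 0), k is lowered (with a warning) when there are fewer
distinct points than clusters, a zero-IQR score profile yields `T` equal
to the common score and hence zero calls, zero-depth GC strata are masked
with a warning, and typing fails loudly if every segment is called
(no baseline exists). Equal cluster sizes are ordered stably by cluster id
when sorting descending, which can affect `θ` only in exact ties.

## Limitations

Resolution is bounded by the bin width and by `λ` — events shorter than a
few bins are usually absorbed into their background segment. The caller
assigns no integer copy number to calls (the CN feature is an estimate,
not a genotype), does not estimate purity or ploidy, and processes one
chromosome at a time. Tukey's fences always labels the tail of the score
distribution, so a completely CNV-free sample will still produce a few
calls; the matched design mitigates this for somatic interpretation but
the normal sample's own call set should not be read as germline CNVs
without corroboration.
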