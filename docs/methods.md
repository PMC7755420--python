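# Methods

## Weighted univariate clustering (WUC)

Given sorted values `x_0 ≤ … ≤ x_{n-1}` with non-negative weights `y_i`, a
k-clustering is a partition into `k` contiguous index intervals with
boundaries `j_0 = −1 < j_1 < … < j_k = n−1`.  The objective is the
weighted within-cluster sum of squared distances

```
SSQ = Σ_q s(j_q+1, j_{q+1}),   s(j,i) = Σ_{l=j..i} y_l (x_l − μ(j,i))²,
μ(j,i) = Σ y_l x_l / Σ y_l.
```

Because the data are sorted, an optimal clustering consists of intervals,
and dynamic programming over `S[q,i]` (optimal cost of clustering the
first `i+1` points into `q+1` clusters) is exact:

```
S[q,i] = min_{q ≤ j ≤ i} S[q−1, j−1] + s(j, i)
```

with `J[q,i]` the *largest* argmin (the tie rule used everywhere; it makes
the output a deterministic function of the input).  Fixing `q`, the matrix
`A_{i,j} = S[q−1,j−1] + s(j,i)` is totally monotone because `s` satisfies
the concave quadrangle inequality, so each DP row is filled in `O(n)` by
the SMAWK algorithm: candidate columns are pruned to at most the number of
rows (`reduce_min_in_place`), odd rows are solved recursively, and even
rows are filled by scanning surviving columns between the bracketing
odd-row argmins.  Total time `O(kn)`; the full `S`/`J` tables are kept
(`O(kn)` space) so solving at `kmax` yields the optimal clustering for
every smaller `k` by backtracking.

Numerical choices:

* Interval statistics come from prefix sums of `y`, `y·x`, `y·x²` with all
  values shifted by the weighted median before accumulation; tiny negative
  `s` from cancellation is clamped to 0.
* The infeasible region `j > i` of `A` is padded with values of the form
  `BIG·(1 + (j − i))`, `BIG` exceeding any attainable cost.  Padding that
  *increases* with `j` is required: constant padding plus the
  largest-index tie rule would break 2×2 monotonicity in all-padded
  submatrices.
* `kmax` is clamped to the number of distinct values; zero-weight points
  are legal and ride along in whichever interval contains them (a
  zero-weight interval has SSQ 0 and midpoint mean).
* The quadratic solver evaluates costs with arithmetic identical
  op-for-op to the SMAWK path, so the two agree bitwise — this is used as
  a cross-check, not merely up to tolerance.

Reference solvers: `brute_force_oracle` enumerates all `C(n−1, k−1)`
boundary placements (n ≤ 16) and resolves SSQ ties to the boundary vector
that is lexicographically largest from the last split backwards, which is
exactly what backtracking the max-index `J` produces.

## Choosing k

Each cluster parameterizes one Gaussian component: proportion
`p_c = W_c/W`, mean = cluster center, variance = within-cluster SSQ/`W_c`
floored at `g²/12` where `g` is the smallest positive gap between distinct
values (the variance of a uniform on one grid cell; it keeps degenerate
one-value clusters from producing infinite likelihood).  The criterion is

```
BIC(k) = loglik(k) − ½ (3k − 1) ln n_eff
```

with the *full mixture* weighted log-likelihood
`Σ_i ỹ_i log Σ_c p_c φ(x_i; μ_c, σ_c²)`.  The classification
(hard-assignment) likelihood was implemented first and rejected: truncated
within-cluster densities systematically over-reward splitting one broad
component, and on a single Gaussian with `kmin = 2` it chose the range
floor in only half of the seeds, while the full-mixture likelihood does so
essentially always and recovers well-separated 5-component mixtures in
50/50 seeds.  Weights are normalized to sum to `n` (`n_eff = n`) inside
this computation, making the selection exactly invariant to positive
rescaling of all weights and identical to the standard BIC for unweighted
input.  Ties go to the smallest k.

## Zone mapping

Genes are positioned at their TSS (start coordinate on `+`, last covered
base on `−`; all internal coordinates 0-based half-open, GTF conversion
happening once at the reader) and weighted by the sum of their CPM over
*all* pooled tumor and normal profiles of every patient.  Per chromosome,
k is selected in `[2, kmax]` with
`kmax = max{20, min{⌊G/5⌋, ⌈L/r⌉}}` (`G` genes, `L` chromosome length,
resolution `r = 1 Mb` — the typical TAD scale; `r` only caps the cluster
count, actual cluster widths adapt to the data).

Clusters become zones by adaptive histogram rules: a cluster spanning
`[a, b]` with largest internal consecutive-TSS gap `g` tentatively covers
`[a − g, b + g]`; if the midpoint with a neighboring cluster falls inside
a tentative zone, that boundary shrinks to the midpoint; residual gaps
become *empty zones*, as do uncovered chromosome ends, so zones always
tile `[0, L)`.  A cluster whose TSS are all identical has no internal gap
and is treated like a singleton (`g = ∞`): its boundaries resolve to the
midpoints with its neighbors.  Zone boundaries are real-valued
(midpoints); the BED writer emits them as decimal text so write→read
round-trips are exact.

Bootstrap stability resamples patients with replacement, scales each
sample's weight contribution by the patient's multiplicity, rebuilds the
map, and reports zone-count spread plus the fraction of original internal
boundaries reproduced within ±100 kb (the tolerance is this package's
documented default; "identical boundary" is not otherwise defined).

## Polarity statistics

A matched pair is positive when `log((tumor+1)/(normal+1)) > log 1.05`,
negative below `−log 1.05`, otherwise none — strict inequalities, so a
ratio of exactly 1.05 is no call.  The observation unit is the
(gene, patient-pair): every patient contributes exactly one matched pair
(deterministically the lexicographically smallest sample ids when several
profiles exist).  Zone polarity is the sign of `n_pos − n_neg`.
Significance is Pearson's chi-squared (1 df, no continuity correction) on

```
[ n_pos in zone   n_pos outside ]
[ n_neg in zone   n_neg outside ]
```

with "outside" the genome-wide totals over all zones of the cancer type.
Tables with a zero marginal are untestable and excluded from the
Benjamini–Hochberg adjustment rather than assigned p = 1.  Outstanding
means adjusted p ≤ 0.05 *and* a non-none polarity.

SCNA zones use the segment-length-weighted mean copy number per sample,
clipped to the zone; the 5% rule is applied literally (including the +1
offsets) to the (zone, patient) tumor/normal copy-number pair.  Doubling
both members of a pair can turn a call into none but never flips + to −.

The outstanding-count permutation test shuffles the gene→zone assignment
uniformly — preserving each zone's size in genes and each gene's own
observation profile — and recomputes the outstanding count;
`p = (1 + #{perm ≥ obs}) / (B + 1)`.  The vectorized permutation path
uses the closed-form 2×2 Pearson statistic (asserted equal to
`scipy.stats.chi2_contingency`).

## Pan-cancer loci

Loci are the intervals between consecutive breakpoints of the union of all
per-type zone boundaries on a chromosome; each locus inherits, per type,
the polarity and outstanding flag of its enclosing zone.  A locus is
conserved with sign `s` when `≥ ⌈0.8·T⌉` of `T` types carry `s` (14 of 17);
by default only outstanding calls count, matching the stricter reading of
"shared polarity" — a flag switches to raw signs.  Adjacent loci with
identical profiles are *not* merged, so locus counts are a reproducible
function of the inputs.  The conservation permutation test shuffles each
type's (polarity, outstanding) labels across that type's zones,
preserving per-type composition.

## Synthetic cohorts

`simulate_cancer_dataset` emulates a matched cohort: two 60 Mb
chromosomes, 20 TSS groups of 15 genes each per chromosome with a 10 Mb
gene-free centromere stretch, 20 patients (mid-range of real matched
tumor–normal cohort sizes, which run roughly 8–112 pairs), log-normal
baseline CPM (median ≈ 30) with multiplicative log-normal noise
(σ = 0.2), and four planted polarized zones.  In a planted zone each
(gene, patient) observation moves in the zone's direction with probability
`p_up = 0.8` by factor 1.5 (well past the 5% threshold) and against it
otherwise; background genes are null.  The per-observation (rather than
per-gene) draw is deliberate: it makes *concentration* of signal in a zone
the detectable feature, so dispersing genes by permutation destroys
significance — with per-gene fixed effects every displaced gene remains
individually extreme and the permutation null would be inflated by
construction.  Copy-number segments tile each chromosome between group
midpoints; tumors carry CN 3 / 1 (Gaussian noise σ = 0.05) in planted
gain/loss zones, normals hover at CN 2.

What the generator does *not* model: count-level (negative-binomial)
dispersion, library-size variation, GC/length biases, correlated genes,
subclonal copy number, or real gene density.  Passing tests therefore
demonstrate correctness of the algorithms and calibration of the
statistics under the stated model, not performance on real cohorts; the
polarity statistic depends only on the sign of the log ratio relative to
±log 1.05, which is why simple multiplicative noise suffices for
calibration.

## Problem sizes used in validation

Oracle checks use 200 instances with n ≤ 12, k ≤ 4 (exhaustive
enumeration is exact there); cross-solver checks 50 instances up to
n = 2000, k ≤ 25; BIC recovery 50 seeds of the 5-component, n = 251
mixture; pipeline power/calibration six cohorts each of the planted and
null configurations; scaling is measured at n = 2.5×10⁵ vs 5×10⁵ with
k = 5.  These sizes exercise every code path while keeping the whole
validation run around a minute.

## Known limitations

* The log-linear `O(kn lg n)` solver variant is not implemented; the
  quadratic row-fill is the designated cross-check.
* Expression input is expected at CPM scale (or raw counts via the
  `--raw-counts` path, which applies only the 8-million-read depth filter
  and CPM scaling); upstream GC/quantile normalization is out of scope.
* Zone polarity treats genes as exchangeable within a zone; no
  gene-length or dispersion modeling.
* The silhouette implementation is O(n²) and intended for validation-size
  inputs.
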