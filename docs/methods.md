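# Methods

## The statistic

The package measures the complexity of a scalar time series as the largest
eigenvalue, λ_max, of a convolutional fuzzy recurrence plot. The chain is:

1. **Embedding.** x_i = (t_i, t_{i+τ}, …, t_{i+(m−1)τ}), i = 1…M,
   M = N − (m−1)τ. For the eigenworm-style analysis m = 4 (matching the
   four principal posture modes of *C. elegans*), τ = 1; for gait swing
   intervals m = 1, τ = 1. The package does not select m, τ, or c
   automatically — they are fixed inputs, as in the study design it
   follows.
2. **Fuzzy c-means.** Standard FCM (Euclidean distances, fuzzifier f = 2,
   random row-stochastic membership initialization from a seeded
   generator, stop when max|ΔU| < 1e−5 or 300 iterations). Default c = 3.
   The objective Σ u_ij^f ‖x_i − v_j‖² is non-increasing over iterations,
   and a fixed seed gives a bitwise-identical partition.
3. **FRP.** R[i,k] = max_j min(u_ij, u_kj); diagonal forced to 1. R is
   symmetric with entries in [0, 1]; crisp (one-hot) memberships recover
   the binary recurrence plot.
4. **Reduction.** Sharpen with w = [[0,−1,0],[−1,5,−1],[0,−1,0]]
   (cross-correlation, zero padding, same-size output), ReLU, then iterate
   2×2 max pooling in ceil mode until the side length equals n (default 2).
   λ_max is the algebraically largest eigenvalue of the final symmetric
   matrix (eigvalsh; asymmetry beyond 1e−9 relative is an error, not a
   warning, because it can only arise from a convention bug upstream).

## Design choices that were genuinely open

**One sharpening pass, not one per level.** A plausible reading of the
reduction is to re-convolve at every pooling level. We default to a single
convolution + ReLU followed by pooling only (`ConvConfig(conv_every_step=True)`
restores the per-level loop) for three reasons. The sharpening kernel has
unit DC gain but a high-frequency gain of up to 9; interleaved with max
pooling, which re-concentrates local maxima, the per-level loop multiplies
contrast at every scale and drives λ_max to ~10⁶ for a 900-point series —
five orders above the scale on which cohort differences live, and
empirically the regular/irregular separation disappears (λ_max becomes
non-monotonic in noise level). Under a single pass every entry of the
reduced matrix is bounded by 9, λ_max lands in the 5–7 range for realistic
signals, grows monotonically with noise, and series with fewer reduction
levels (shorter records) can legitimately score higher — all three
behaviors consistent with published cohort values for this family of
statistics. Both paths are implemented and tested; the size trajectory
(e.g. 897→449→225→113→57→29→15→8→4→2) is identical in both.

**Pooling geometry.** Window 2, stride 2, ceil mode (partial edge windows
kept). Ceil mode is what guarantees every side > 2 maps to ⌈side/2⌉ ≥ 2
and lands exactly on n = 2; floor mode would jump from 3 to 1. Window,
stride, and the per-level-convolution switch are all configurable so other
conventions can be matched empirically.

**Zero-distance FCM memberships.** When a point coincides with a cluster
center the membership update is 0/0. We assign crisp membership to the
lowest-index zero-distance center. The payoff is the correct degenerate
limit: a constant series embeds to identical points, all centers coincide,
every membership row is the same one-hot vector, and the FRP is all ones —
a perfectly recurrent signal, which is what a constant series is. (The
uniform-1/c alternative yields an FRP of 1/c off the diagonal, which would
make the "complexity" of a constant series depend on c.) Empty clusters
that arise from crisp reassignment are re-centered at the data mean.

**The matrix convolved is μ, not 1−μ.** Grayscale rendering conventions
(recurrence = black) invert the matrix for display only; the composition
matrix itself is what enters the reduction.

## Sample entropy

SampEn = −ln(A/B), where B counts pairs of delayed m-templates within
Chebyshev distance δ (self-matches excluded), A the same for
(m+1)-templates, and both counts run over the same template index range so
A ≤ B always. δ = k·σ with σ the sample SD (n−1 denominator) of the series
as analyzed (after preprocessing, for gait). Defaults: worms m = 4,
k ∈ {0.1, 0.2, 0.3}; gait m = 2, k = 0.3 — with m = 1, some 120-sample
gait series have no (m+1)-matches, A = 0, and SampEn is infinite. The
infinity is an explicit sentinel; cohort statistics refuse to average it
(the remedy is a larger m, not a silent drop). An optional z-normalization
is provided for archives that store unnormalized traces; it does not
change SampEn because δ rescales with σ.

Gait preprocessing: third-order (width-3) median filter treating the
signal as zero beyond the endpoints, applied to the full record, then
truncation to the first 120 samples (the shortest record length in the
gait database). Filtering before truncation can differ from the reverse
order only at the final retained sample.

## Cohort statistics

Mean, SD (n−1), a two-sided one-sample Student-t test of the cohort mean
against zero, and t-based confidence intervals
mean ± t_{n−1,(1+level)/2}·sd/√n at 95% and 99%. The t (not normal)
quantile is required: published intervals for n = 16 cohorts correspond to
t₁₅ = 2.131, not 1.96, and the published p-values (e.g. 2.7660e−13 for an
n = 16 gait cohort, 5.5114e−91 for a 109-worm cohort) emerge from their
printed moments under exactly this test. `summary_from_moments` exposes
the same formulas on (mean, sd, n) so printed table rows can be verified
without raw data.

Cohort distance for trees is |mean_i − mean_j| (the distance definition
behind published dendrograms is unstated; mean difference is the simplest
choice that reproduces their described topologies, and the hook accepts
any precomputed matrix). UPGMA uses size-weighted average linkage
(scipy's `linkage(method="average")`) with node heights at half the merge
distance, so the tree is ultrametric; newick serialization carries branch
lengths.

## Synthetic data: what it does and does not show

The generator emulates labeled cohorts of scalar series with controllable
regularity. Families: harmonic (unit sinusoid, period 60 samples — about
15 cycles per 900-sample record, resembling multi-cycle undulation traces
— with uniform random phase and additive Gaussian noise), AR(1)
(stationary, unit innovations), and logistic map (chaotic at rate 3.9,
with a 100-step transient discarded). The default two-class spec is 30
series per class, length 900, noise SD 0.05 ("regular") vs 0.5
("irregular"). Generation is a pure function of spec + seed.

These cohorts establish that the pipeline is order-preserving in a known
complexity dial (noise level) at realistic sample sizes: the irregular
class scores a higher mean λ_max, separable by a Welch test at α = 0.01
across generator seeds. They do not emulate the autocorrelation structure,
nonstationarity, or measurement artifacts of real eigenworm or gait
recordings, so passing tests show internal correctness and sensitivity,
not clinical discriminative power. Replication against the public archives
runs automatically when the eigenworm table is placed at
`data/eigenworms.txt`; the acceptance bar there is containment of
per-class mean λ_max in the published 95% intervals, not bit-exact means,
since FCM initialization and pooling conventions admit variation.

## Numerical notes

- FRP composition is exact (min/max only); the composed matrix is
  symmetrized with an elementwise max purely to remove any reduction-order
  ambiguity.
- Inside the reduction, the convolved matrix is averaged with its
  transpose before the ReLU: mathematically it is already symmetric
  (symmetric input, symmetric kernel), and the averaging removes
  summation-order round-off so symmetry checks can be exact.
- Squared distances in FCM are clipped at zero against catastrophic
  cancellation; memberships are renormalized per row.
- Problem sizes in tests and the acceptance script (series of length 900,
  30 per class) match the synthetic study conditions; the full archive
  replication (258 worm series) runs only when the archive is present.

## Known limitations

- No automatic embedding selection (false-nearest-neighbors, mutual
  information) and no recurrence quantification analysis; the statistic is
  λ_max only.
- The per-level-convolution variant is provided for convention matching
  but its λ_max scale is dominated by kernel gain, not signal complexity.
- SampEn is O(M²) in time and memory via pairwise distances; fine at the
  record lengths used here (≤ 900), not intended for very long records.
- UPGMA on |Δmean| ignores cohort spread; two cohorts with equal means are
  indistinguishable to the tree regardless of their variances.
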