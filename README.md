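# recureig

Recurrence eigenvalues of movement time series.

`recureig` quantifies the complexity of a scalar movement signal — the
first-eigenworm amplitude trace of a crawling *C. elegans*, or the left/right
swing intervals of human gait — as a single number: the largest eigenvalue of
a convolutional fuzzy recurrence plot. It is aimed at researchers in
behavioral genetics and movement-disorder physiology who need a scalar
complexity marker that separates wild-type from mutant worm strains, or
healthy controls (HC) from Parkinson's (PD), Huntington's (HD), and ALS
cohorts, without training a classifier.

## Method

Given a scalar series **t** = (t₁, …, t_N):

1. **Time-delay embedding.** Reconstruct the phase space
   X = (x₁, …, x_M)ᵀ with xᵢ = (tᵢ, t_{i+τ}, …, t_{i+(m−1)τ}) and
   M = N − (m−1)τ.
2. **Fuzzy recurrence plot (FRP).** Soft-partition X into c clusters with
   fuzzy c-means, giving membership grades μ_{ij} ∈ [0, 1]. The FRP is the
   M×M matrix of max–min composed similarities
   μ_{ik} = max_j min(μ_{ij}, μ_{kj}), with μ_{ii} = 1 (reflexivity) and
   μ_{ik} = μ_{ki} (symmetry).
3. **Convolutional reduction.** Sharpen the FRP with the 3×3 kernel
   w = [[0,−1,0],[−1,5,−1],[0,−1,0]], apply a ReLU, then iterate 2×2
   max pooling (ceil mode) until the matrix is n×n (default n = 2).
4. **λ_max.** The largest eigenvalue of the final n×n matrix is the
   complexity statistic. More irregular dynamics produce sharper, more
   fragmented recurrence texture and a larger λ_max.

The package also provides the sample-entropy baseline
SampEn = −ln(A/B) (Chebyshev matching at tolerance δ = k·σ), gait
preprocessing (third-order median filter with zero end padding, truncation
to 120 samples), cohort statistics (mean ± SD, one-sample t p-value, 95%/99%
t-confidence intervals), and UPGMA dendrograms over cohort mean distances.

## Worked example

Cohort-level separation on two synthetic classes that differ only in noise
level (unit sinusoid, Gaussian noise SD 0.05 vs 0.5, 30 series of length
900 per class):

```sh
$ recur-eig all --seed 0 --count 30 --length 900 --out demo
irregular: lambda_max 6.1307 +/- 0.2105 (n=30)
regular: lambda_max 5.8664 +/- 0.2948 (n=30)
```

The noisier cohort scores a higher mean λ_max (6.13 vs 5.87; a Welch test
on the per-series values gives p ≈ 2e-4), i.e. the statistic reads the
noise-dominated series as more complex. The output directory contains the
per-series CSV, cohort summary CSV, a newick tree, and a JSON run manifest
that fully reproduces the run.

Cohort statistics can also be computed directly from published moments
(mean, SD, n) without raw data:

```sh
$ recur-eig cohort --from-moments "HC:5.9875:1.0132:16" --out demo2
HC: 5.9875 +/- 1.0132  p=2.7668e-13  95% CI (5.4476, 6.5274)  99% CI (5.2411, 6.7339)
```

Here the one-sample t-test and t-based intervals for a healthy-control gait
cohort (n = 16 subjects) are recovered exactly from its printed mean ± SD.

The same operations are available as a library:

```python
from recureig import EmbeddingConfig, recurrence_eigenvalue

res = recurrence_eigenvalue(series, EmbeddingConfig(m=4, tau=1), c=3, seed=0)
res.lambda_max                      # the complexity statistic
res.final_matrix.size_trajectory    # e.g. [897, 449, 225, 113, 57, 29, 15, 8, 4, 2]
```

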