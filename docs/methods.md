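# Methods

## Model

Each concept manifold is summarized by its first two moments: a centroid
`x₀ ∈ ℝ^V` and a covariance with eigenvalues `λᵢ` and orthonormal
eigenvectors `uᵢ`. The per-direction radii are `rᵢ = √λᵢ`, the squared
total radius is `R² = Σᵢ rᵢ²` (the total variance), and the Dimensionality
is the participation ratio `D = (Σᵢ rᵢ²)² / Σᵢ rᵢ⁴`, which counts the
effective number of variance-carrying directions (`D = k` exactly for `k`
equal eigenvalues; `D = 1.8` for the spectrum `(λ, λ/2)`).

For an ordered pair `(a, b)` all quantities are expressed relative to
manifold `a`: the normalized centre difference is `Δx = (x₀ᵃ − x₀ᵇ)/Rₐ`
and both radius-weighted direction matrices `Uᵃ = [rᵢᵃuᵢᵃ]/Rₐ`,
`Uᵇ = [rᵢᵇuᵢᵇ]/Rₐ` are normalized by `Rₐ`. Signal, Bias and the three
Overlaps follow as in the README; they compose into

    SNR(m) = ½ (S + b/m) / sqrt( (1/Dₐ + Nᵇ + Nᵃᵇ)/m + Nᵃ ),

keeping only terms linear in `1/m`, and the predicted m-shot error is the
standard normal upper tail `H(SNR)`. Useful identities: the self-pair has
`S = b = 0` and `Nᵃᵃ = 1/Dₐ`; all quantities are invariant under global
scaling and orthogonal rotation of the activation space; the combined
Overlap `N(m) = (Nᵇ + Nᵃᵇ)/m + Nᵃ` is decreasing in `m` whenever
`Nᵇ + Nᵃᵇ > 0`.

### Accuracy of the truncated theory

`error = H(SNR)` is a concentration result: it becomes exact as the number
of contributing directions grows. Brute-force simulation of Gaussian
manifold pairs (fresh exemplars, no estimation) shows the residual of the
1/m-truncated expression at `m = 5`, low SNR, is about −0.046 in error at
`D = 3`, −0.020 at `D = 7`, −0.008 at `D = 15` and below 0.002 at
`D = 30`. The theory-validation sweep therefore draws manifolds with
participation ratios roughly 8–25 — the regime the theory describes, and
the upper range reported for neural data — and users applying the
prediction to very low-dimensional manifolds should expect deviations of a
few percent at low SNR.

## Estimation

A concept's exemplar matrix `X (P×V)` is centered and decomposed by
singular values; radii are the singular values divided by `√P` (the spec
of the 1/P-normalized covariance), so sample summaries converge to the
population quantities of the generating distribution as `P` grows. All
`min(P−1, V)` components are retained — no variance-threshold truncation.
Zero total variance (all exemplars identical) raises a degenerate-manifold
error rather than reporting `D = 0`; inside `geometry_grid` degenerate
concepts are excluded with a logged warning instead.

## Empirical few-shot protocol

`empirical_error_protocol` mirrors the nested resampling used to validate
the theory. Per outer fold (default 16) every concept is split
90%/10%; geometry is estimated on the 90% side so that estimated SNR and
empirical error are paired per fold. Per inner repetition (default 16) `m`
exemplars per concept are drawn without replacement from the 10% side,
averaged into prototypes, and the remaining held-out exemplars are
classified by projection onto the prototype difference with a midpoint
threshold (equivalently nearest prototype; exact ties go to the first
concept — a measure-zero convention for continuous data). Errors are
averaged over inner draws, then mean and across-fold standard deviation
are reported per ordered pair.

Choices fixed here because the protocol leaves them open: the holdout is
`max(floor(0.10·P), m+1)` rows; when a `trial_id` column is present,
repeats are averaged into one exemplar row *before* splitting so no trial
of one exemplar can appear on both sides; the inner loop re-draws only the
m-subsets (the test set is the complement within the holdout); a master
seed spawns independent per-fold streams, making results reproducible and
order-independent.

## Random embedding

Unit subsampling keeps `k` uniformly drawn columns (clamped with a warning
when `k` exceeds the ambient dimension); projection multiplies by a dense
`V×d` matrix of iid `N(0, 1/d)` entries — the standard
Johnson–Lindenstrauss construction, which preserves expected squared
norms. For manifolds whose Dimensionality is small relative to `d`,
geometric estimates are preserved: a single projection perturbs a squared
centre distance by a `χ²(d)/d` factor (relative std `√(2/d)` ≈ 8% at
`d = 300`), and residual SNR attenuation scales like `m·D·S/(2d)`, so the
projection target should comfortably exceed `m·D·S` — 300 dimensions
suits participation ratios up to ~10; higher-dimensional representations
warrant a larger target (e.g. 2,000). `convergence_sweep` tabulates
estimates over an embedding grid, with fraction-of-maximum columns and the
per-point seeds recorded so any grid point can be reproduced exactly.

## Synthetic generator and noise model

Concepts are Gaussian clouds `x = c + B diag(√λ) z` with orthonormal
`V×k` bases (explicit, or `"random"` resolved deterministically from the
seed via QR with sign fixing). `ground_truth_geometry` runs the same
pairwise formulas on the population spectrum, giving the oracle that
estimates converge to. Measurement noise replicates each exemplar over
trials with additive zero-mean Gaussian noise whose mean per-unit variance
equals (mean signal variance across exemplars) / SNRₘ; signal is fixed per
exemplar, noise fresh per trial. Uncorrelated noise is iid across units at
that variance; correlated noise draws a full random covariance as a
normalized Wishart sample (`AAᵀ/V`, `A` square standard normal) with its
mean diagonal matched to the same target — the correlated structure is not
otherwise constrained, so this is one convenient family, not a claim about
measurement physics. Trial averaging over `n` samples cuts the effective
noise variance by `n`.

The noise-distortion experiment corrupts one fixed draw of noiseless
exemplars per cell of a (SNRₘ × trial-average × correlated) grid and
re-estimates geometry. Defaults: 3 concepts, `V = 150`, `k = 12`
exponentially decaying spectra (`D ≈ 7`), 300 exemplars, SNRₘ grid
0.3–10. Expected structure, which the acceptance checks assert: noise
inflates Dimensionality above truth and deflates SNR and Signal; estimated
SNR rises with SNRₘ; 5-sample averaging lands closer to truth than
1-sample for every property (a 2% fold-noise allowance covers sampling
fluctuations in nearly-converged cells). Above SNRₘ ≈ 30 the remaining
noise distortion falls below the finite-sample bias of the estimates, so
grids beyond that probe the estimator, not the noise model.

What the generator does not emulate: non-Gaussian manifold shape,
heavy-tailed or stimulus-dependent noise, inter-subject variability, and
label noise (one exemplar belonging to several concepts). Passing tests
show that the estimators and the theory are mutually consistent under the
Gaussian model, not that any particular dataset satisfies it.

## Covariation analyses

The log-linear Overlap model `log N(m) = α log S + β log D + γ` is fitted
by OLS on natural logs (coefficients rescale trivially under a change of
base); rows with nonpositive `S`, `D` or `N` are excluded with a logged
count since their logarithm is undefined, and the single-predictor
(`log S` only) R² is reported for comparison. Substituting the fitted
`N(S, D)` into the SNR expression with Bias held at a constant (typically
the per-dataset mean — it varies little) yields the SNR surface over the
`(S, D)` plane; iso-SNR contour levels are taken at surface quantiles.
The iso-lines are slightly curved in log–log space whenever `β ≠ −2α`.

Permutation correlations use the add-one estimator
`p = (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1)` with `y` permuted under a
seeded generator — valid and never zero under exchangeability. The
property-correlation suite reports the full Pearson matrix over
{SNR, S, b, N(m), D} either per observation row ("per-pair") or after
averaging within levels (ROIs/layers; at least 3), with optional filtering
by a level-depth column; constant properties yield NaN entries rather than
failing the suite. Permutations pool all observations; a grouping hook
(the level column) is available if within-group permutation is needed.
Hierarchy distances are shortest-path hop counts on a user-supplied
undirected edge list; disconnected pairs are flagged as infinite.

## Numerical conventions

Orthonormality is validated to 1e−8; degenerate-manifold and
coincident-centroid checks use a 1e−12 relative threshold against the data
scale; the self-overlap identity holds to 1e−10; classification ties go to
the first concept; error-matrix standard deviations use `ddof = 1` across
outer folds; TSV floats are written at full precision and read with
round-trip parsing so every table survives write→read unchanged.

## Problem sizes in the shipped experiments

The validation experiments use 20 concept pairs × 580 exemplars (theory
sweep), 20 replicates × 250 exemplars in 10,000 ambient dimensions
(projection invariance), a 4×3×2 noise grid at 300 exemplars, 100
regression replicates of n = 500, and 1,000 null replicates × 500
permutations (calibration). These sizes give Monte-Carlo uncertainty
comfortably below each check's tolerance while keeping a full run on a
single CPU in the minutes range.

## Known limitations

- The SNR prediction degrades for `D ≲ 5` (see above) and for strongly
  non-Gaussian exemplar distributions.
- Only pairwise (two-concept) classifiers are implemented; no n-way
  readout.
- Overlap terms are *not* invariant under random projection in relative
  terms (two low-rank subspaces genuinely overlap more in 300 than in
  10,000 dimensions, by a factor ≈ V/d); invariance claims apply to
  Signal, Dimensionality and SNR, where the effect is second order.
- The correlated-noise family is a single Wishart construction; real
  measurement covariances (e.g. spatially structured fMRI noise) may
  distort geometry differently.
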