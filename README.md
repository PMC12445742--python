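# manifoldgeom

Geometry of concept manifolds and few-shot prototype classification.

A *concept manifold* is the cloud of activity patterns — fMRI voxel
responses, encoding-model outputs, or network-layer features — evoked by
exemplars of one concept, viewed as points in a high-dimensional activation
space. A small set of geometric properties of a pair of such manifolds
determines how well a linear *m-shot* classifier (nearest prototype, each
prototype the mean of *m* exemplars) can tell the concepts apart:

- **Signal** `S_ab = ‖Δx‖²` — squared centroid distance, normalized by the
  reference manifold's squared total radius `R_a²`;
- **Bias** `b_ab = R_b²/R_a² − 1` — relative squared-radius mismatch;
- **Dimensionality** `D_a = (Σᵢ rᵢ²)² / Σᵢ rᵢ⁴` — the participation ratio
  of the covariance spectrum, the effective number of variance-carrying
  directions;
- **Overlaps** `N^a_ab = ‖Δx·Uᵃ‖²`, `N^b_ab = ‖Δx·Uᵇ‖²`,
  `N^ab_ab = ‖(Uᵃ)ᵀUᵇ‖²_F` — alignment of radius-weighted principal
  directions with the signal direction and with each other.

These compose into a geometric signal-to-noise ratio

```
SNR_ab(m) = ½ (S_ab + b_ab/m) / sqrt( (1/D_a + N^b_ab + N^ab_ab)/m + N^a_ab )
```

and the *m*-shot error is the Gaussian tail `H(SNR)`, with
`H(z) = ½(1 − erf(z/√2))`. All pairwise quantities describe concept *a*
relative to concept *b*, so the pair is ordered and `SNR(a,b) ≠ SNR(b,a)`
in general.

The package is for researchers who want to apply this geometric analysis to
their own activity matrices: it estimates all of the quantities above from
labeled exemplar-by-unit data, measures empirical *m*-shot error with a
nested resampling protocol so theory and experiment are paired
observations, embeds very high-dimensional populations by random subspace
sampling and Gaussian random projection, fits the log-linear model
`log N(m) = α log S + β log D + γ` that renders SNR a function of Signal
and Dimensionality only (iso-SNR maps), runs permutation-tested
correlations among properties, and ships a synthetic manifold generator
with analytic ground truth plus a trial-to-trial measurement-noise model
for end-to-end validation.

## Worked example

```python
import numpy as np
from manifoldgeom import (ConceptSpec, ManifoldSpec, sample_manifolds,
                          geometry_grid, empirical_error_protocol,
                          ground_truth_geometry)
from manifoldgeom.synthetic import materialize

rng = np.random.default_rng(0)
V, k, P = 100, 8, 400
lam = np.exp(-np.arange(k) / 3.0); lam /= lam.sum()
concepts = {}
for name in ("faces", "houses", "tools"):
    c = rng.standard_normal(V); c *= 0.9 / np.linalg.norm(c)
    concepts[name] = ConceptSpec(center=c, spectrum=lam, basis="random",
                                 n_exemplars=P)
spec = materialize(ManifoldSpec(ambient_dim=V, concepts=concepts), seed=1)

dataset = sample_manifolds(spec, seed=1)
grid = geometry_grid(dataset, m=5)
print(grid.pairs[["concept_a", "concept_b", "signal", "bias",
                  "combined_overlap", "snr", "predicted_error"]].round(3))
```

```
concept_a concept_b  signal   bias  combined_overlap   snr  predicted_error
    faces    houses   1.556 -0.003             0.038 2.794            0.003
    faces     tools   1.677  0.039             0.039 3.003            0.001
   houses     faces   1.561  0.003             0.022 3.181            0.001
   houses     tools   1.560  0.042             0.024 3.132            0.001
    tools     faces   1.614 -0.037             0.020 3.343            0.000
    tools    houses   1.497 -0.040             0.026 2.943            0.002
```

The three clouds sit about one radius apart (`signal ≈ 1.5`), have nearly
matched sizes (`bias ≈ 0`) and occupy ~5 effective directions each
(participation ratio ≈ 5.1–5.3 in `grid.concepts`), so the theory predicts
5-shot errors of a few tenths of a percent. The empirical protocol agrees:

```python
result = empirical_error_protocol(dataset, m=5, n_outer=16, n_inner=16, seed=2)
print(result.error_mean.round(3))
```

```
        faces  houses  tools
faces     NaN   0.013  0.011
houses  0.003     NaN  0.004
tools   0.005   0.006    NaN
```

Entry `(a, b)` is the fraction of held-out `a` exemplars misclassified
against `b`, averaged over 16 inner prototype draws and 16 outer 90/10
splits. Because the generator's geometry is known analytically,
`ground_truth_geometry(spec, "faces", "houses", m=5)` gives the population
values the estimates converge to (`SNR(5) = 2.714`, predicted error 0.003
here).

The same operations are available from the shell via the `manifoldgeom`
CLI (`estimate`, `fewshot`, `project`, `simulate`, `covary`, and `run` for
a config-driven end-to-end pipeline with a reproducibility manifest).

Input format: delimited text (TSV by default) with a header; first column
is the concept label, an optional second column `trial_id` groups repeated
presentations of the same exemplar, and the remaining columns are units.

## Documentation

`docs/methods.md` documents the model and estimation conventions, the
resampling protocol, the synthetic generator and noise model, numerical
choices and known limitations.
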