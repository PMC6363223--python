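# Methods

## Model and assumptions

Expression of gene *i* in condition *j* is modelled as a linear
combination of latent transcription-factor activities,
X_ij = Σ_k W_ik Â_kj, with a fixed transcriptional delay τ for
time-series data (expression at t responds to activities at t − τ).
The model assumes: (i) regulation is linear on the chosen expression
scale; (ii) each gene has few regulators (sparsity); (iii) related
datasets share part of their network while keeping dataset-specific
edges; (iv) the prior topology is informative about which targets a TF
controls, though it may contain errors.

## Transcription-factor activities

Activities solve X = P·A in the least-squares sense via the Moore–Penrose
pseudo-inverse (SVD, relative singular-value cutoff 1e-10 to absorb rank
deficiency from TFs with duplicated target sets). The responding
expression is taken at t + τ/2 (linear interpolation along each
time-series chain) because the activity at t manifests between t and
t + τ. TFs with an all-zero prior column use their own mRNA as an
activity proxy. Prior magnitudes (e.g. motif counts) are used as-is; a
`clip_prior` switch reduces them to signs. Neither X nor P is centred or
rescaled before inversion.

## Time alignment

Time axes are reconstructed by summing `delta_t` along `previous_sample`
links. Interpolation is linear between the two bracketing samples and is
never extrapolated: targets before the first or after the last sample of
a series clamp to the boundary sample. Steady-state samples always map to
themselves. With τ = 0 both alignments are exact identities.

## The sparse + block-sparse decomposition

Per gene, coefficients over d datasets form the TFs × datasets matrix
W = S + B with the convex objective

    Σ_d 1/(2 n_d) ‖X^(d) − Â^(d)ᵀ(S+B)_d‖²
      + λ_s Σ_{k,d} Φ_kd |S_kd| + λ_b Σ_k ‖B_k‖∞.

The per-task 1/n_d loss normalisation keeps one λ pair meaningful across
tasks of different size and makes the d = 1 case coincide exactly with
the standard lasso parameterisation.

Minimisation is cyclical coordinate descent with covariance updates: only
A·Aᵀ (shared by all genes of a dataset) and A·Xᵀ enter the sweeps, so
they are computed once per bootstrap. S entries update by prior-weighted
soft-thresholding of the least-squares update; each B row updates by the
exact proximal operator of λ_b‖·‖∞ under the per-task quadratic,
computed through the dual as a weighted projection onto the ℓ1 ball
(sorted-breakpoint solution of the piecewise-linear KKT condition). With
equal per-task curvatures this is the classic Moreau decomposition; at
d = 1 it reduces to scalar soft-thresholding. Predictors with zero
variance in a task are pinned to zero rather than failing. A gene that is
itself a TF is excluded from its own candidate regulator set — with the
mRNA fallback a self-edge would trivially explain its own response.

Convergence: sweeps stop when the largest coefficient change falls below
1e-6 (1000 sweeps cap); the objective is non-increasing per sweep and
solutions match an independent subgradient minimiser to ≤1e-4 relative
objective gap (verified in the test suite).

## Prior weighting

Φ_kd = 1/ρ when TF k → gene i is in dataset d's prior, else 1, then each
column is rescaled to sum to the number of predictors. ρ ≥ 1 ("prior
weight") is the only knob: ρ = 1 disables differential shrinkage. Φ
multiplies the penalty on S only, never B, so priors valid in one dataset
encourage dataset-specific edges rather than forcing them everywhere.

## Model selection

λ_b = c·√(d·ln p / n̄) over 20 log-spaced c in [0.01, 10] (n̄ = mean task
sample count), each paired with λ_s at ratios {0.55, 0.65, 0.75, 0.85,
0.95}·λ_b — strictly inside the admissible open interval (½, 1). The grid
is traversed from most to least penalised with warm starts, selecting the
extended BIC minimum at γ = 1:

    EBIC = 1/d Σ_d [ n_d ln(RSS_d/n_d) + k_d ln n_d + 2γ ln C(p·d, k_d) ].

Ties keep the more-penalised (sparser) fit. Two safeguards make the
criterion well defined at the degenerate ends: RSS is floored at machine
epsilon (noise-free fits otherwise yield ln 0), and any fit whose support
size k_d reaches the number of *distinct* conditions of task d is
assigned +∞. The second guard is a degrees-of-freedom requirement:
BIC-type criteria presuppose k < n, and under bootstrap resampling the
effective sample count is the number of distinct resampled conditions —
a model with k ≥ #distinct interpolates exactly and its likelihood term
degenerates. Without this guard, near-saturated dense fits dominate the
selection whenever samples are scarce, and they hit the multitask model
hardest because a shared B row pays its ℓ∞ penalty once while reducing
the residual in every task.

The single-task mode runs the same machinery at d = 1 with the block
component disabled, using the λ_s members of the grid as its lasso path.

## Confidence scores, bootstraps, ranking

A selected predictor's score is c = 1 − σ²_full/σ²_reduced from OLS
refits on the selected support with and without that predictor; nesting
guarantees c ∈ [0, 1]. Refits use minimum-norm least squares, so an
exactly collinear duplicate scores 0 instead of aborting. The full
fit + scoring is repeated over bootstraps (default 20) that resample
condition columns with replacement, jointly in design and response;
bootstrap b uses generator seed `seed + b`. Edges are ranked within each
bootstrap (descending score, average ranks on ties), ranks averaged, and
the averaged ranks mapped affinely to confidences with the best achieved
rank → 1 and the worst → 0 (an all-tied degenerate matrix maps to 0.5).
Ensemble networks (across datasets) are combined the same way.

## Evaluation

Precision–recall is computed over ranked prefixes restricted to the gold
standard's TF × gene universe, with AUPR = Σ precision·Δrecall (step
rule, no interpolation). Gold-standard signs are ignored for PR; sign
agreement is available separately. `filter_at_precision` returns the
longest prefix holding a precision cutoff, and `overlap_counts` tallies
the Venn decomposition of edge sets across networks.

## Synthetic benchmark

The generator emulates the structure the method assumes: per-gene sparse
signed truths with a controlled fraction of edges shared across datasets
(identical signed weights), activities i.i.d. standard normal (optional
AR(1) chains for time-series tests), expression X = W·A + ε with
Gaussian noise (default σ = 0.5 against weights drawn uniform in
±[0.5, 2], i.e. roughly 6:1 signal-to-noise per edge), TF mRNA rows
(activity + noise) so the fallback path is exercised, priors with
controlled recall plus one false edge per five true ones (the default
corruption design), and random prior/evaluation splits of a gold
standard. All randomness flows from one integer seed through named
substreams. Default sizes in the test suite (200 genes × 20 TFs ×
3 datasets × 50 samples for recovery; smaller for unit tests) keep a
full run at a few minutes on one CPU.

What it does **not** emulate: platform/batch effects, heteroscedastic or
count-based noise, correlated TF activities, nonlinear or combinatorial
regulation, and network motifs such as feedback loops. Passing recovery
tests therefore demonstrates correctness of the estimator under its own
assumptions, not performance on real microarray/RNA-seq compendia.

## Numerical choices

- standardization: predictor rows and responses are z-scored per dataset
  (population SD) before fitting; ℓ1 penalties are scale-sensitive and
  EBIC values must be comparable across genes.
- pseudo-inverse cutoff 1e-10 (relative); solver tolerance 1e-6, max
  1000 sweeps; EBIC RSS floor = machine epsilon; saturation guard as
  above.
- tie-breaks: EBIC ties → sparser fit; ranking ties → average ranks;
  written edge lists sort by descending confidence then lexicographic
  (tf, gene). All outputs are byte-reproducible for a fixed seed and
  independent of the worker count (threaded per-gene parallelism over
  GIL-releasing kernels).
- degenerate inputs: constant genes get empty models and zero scores;
  constant predictors are pinned to zero; missing expression values are
  rejected at load rather than imputed (downstream covariance updates
  assume complete matrices).

## Known limitations

- The ℓ1/ℓ∞ block penalty encourages all-or-none sharing; partially
  shared edges must be absorbed by S and can be under-weighted when most
  datasets lack the edge.
- EBIC with γ = 1 is conservative in very small samples; together with
  the saturation guard it will return empty models when conditions are
  fewer than a handful.
- TFA estimation inherits the prior's errors; heavily false-positive
  priors distort activities for all downstream models (mitigated but not
  removed by the robustness of model selection to false prior edges).
- Identifier matching is exact and case-sensitive; no alias resolution.
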