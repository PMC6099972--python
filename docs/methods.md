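# Methods

## Problem and data

The package models the acute toxicity of substituted aromatic compounds to
the ciliate *Tetrahymena pyriformis*, expressed as −log IGC50 (log10 of the
reciprocal 50 % growth-inhibitory concentration; the underlying
concentration unit is not recorded in the source table, so the package
treats the endpoint purely as printed log-scale values and performs no unit
conversion). The packaged reference table contains 160 compounds in three
structurally defined groups — 46 nitro-substituted, 75 halogen-substituted
and 39 with both substituent classes — each split into training subsets
A–D (36/60/31 compounds) and an external test set T (10/15/8). The fixture
is a verbatim transcription, including three typographical compound names
as printed (e.g. "30-Nitroacetophenone") and both published predicted
columns with their residuals; Unicode minus signs are normalised to ASCII
on read.

## Statistics and their exact definitions

- **R²** is the squared Pearson correlation between observed and predicted
  values. For the fitted values of an intercept OLS model this equals
  1 − SSres/SStot; for externally supplied predictions the two forms
  diverge, and the squared correlation is the definition under which the
  packaged table reproduces all six published training R² footers to three
  decimals (the explained-variance form gives 0.715 instead of 0.829 for
  the nitro group, because that group's printed predictions carry a mean
  offset — see "Known data inconsistencies").
- **RMS** is sqrt(Σe²/n) with divisor n (the convention under which the
  published footers are self-consistent for two of three groups);
  `fit_mlr(..., rms_ddof=p+1)` provides the residual-degrees-of-freedom
  alternative.
- **F** is the overall regression F, (R²/p)/((1−R²)/(n−p−1)); it reproduces
  the published footers from their own (R², n, p) triples within rounding,
  which is how the definition was fixed.
- **LOO q²** is 1 − PRESS/SStot with PRESS from the closed-form deleted
  residual e_i/(1 − h_ii); a test verifies equality with n explicit refits
  to 1e−10.
- **External q²** uses the training-set mean in the denominator (the Q²F1
  form); the source is silent on the centring and this is the conservative,
  most common choice.
- **Through-origin block**: k = Σyŷ/Σŷ² (observed regressed on predicted
  through the origin) and R0² = 1 − Σ(y−kŷ)²/Σ(y−ȳ)²; the primed
  quantities swap the roles of y and ŷ. The four predictivity conditions
  are q²ext > 0.5, R² > 0.6, min(ratio, ratio′) < 0.1 and at least one
  slope in [0.85, 1.15].

## Descriptor formulas and pre-selection

The two printed formulas are implemented in bare units — atomic masses in
amu, distances in Å, nuclear charges as atomic numbers, no physical
constants — matching the dimensionless use of the descriptors in linear
models. The gravitation index sums m_i m_j/r_ij² over *bonded* pairs only;
the maximum nucleus–nucleus repulsion takes the max of Z_a Z_b/R_ab over
bonds of one element pair and raises a "not applicable" error when the
molecule has no such bond, leaving the fill policy to the caller.

Pre-selection removes zero-variance columns, optionally columns whose
|corr with y| falls below a configurable floor (default 0 = disabled, since
no threshold is published), and then resolves intercorrelated pairs
greedily in descending |corr with y|: a column is dropped if it correlates
at |r| ≥ r_max (default 0.8) with any already-accepted column. The output
is idempotent and its maximum pairwise |r| is strictly below the bound
(asserted by exhaustive scan in the tests). Ties fall back to column order,
so the screen is deterministic.

## Stepwise MLR

Forward selection scores candidate models by the overall F of the enlarged
OLS fit (equivalent to R² at fixed step, since every candidate model at a
step has the same p), seeds with the best single descriptor, and skips
candidates correlated at |r| ≥ 0.8 with anything already selected. The
source describes sorting "by F-test values" without specifying partial-F
thresholds, so no stopping rule other than the requested descriptor count
is applied; if the intercorrelation gate exhausts the candidates early the
function warns and returns the shorter list. Under the default study-like
conditions (n = 36, 3 signal among 50 columns, noise SD 0.19) the selector
recovers the planted triple in 20/20 seeds (asserted ≥ 18/20).

## RBF network

One Gaussian hidden layer with a single shared width (the published models
report one width per model: 0.8, 2.0, 1.7 for architectures 3-10-1, 3-9-1,
3-9-1), linear output layer with bias. Training recruits centres greedily
from the training points: at each step the candidate whose admission (with
the output weights re-solved exactly by least squares) most reduces the
training SSE is added, until the SSE goal or the hidden-unit cap is
reached. Ties break to the lowest row index; duplicate rows enter the
candidate pool once; a rank-deficient output solve falls back to the
least-norm solution with a warning. Training SSE is therefore
non-increasing in hidden units, and with all distinct points as centres the
network interpolates noise-free data.

Inputs are z-scored per column before any distance computation (parameters
stored in the model). This is the package's choice — raw heterogeneous
descriptors would make Euclidean distance scale-dominated — and it has a
visible consequence: a generating Gaussian bump in raw coordinates is not
exactly representable by one standardized-metric unit, so the noise-free
single-bump test asserts R² ≥ 0.9 for one unit and ≥ 0.99 for a small
network rather than exactness.

The width scan trains at each grid value (default 0.1–4.0 step 0.1, 40
widths) and selects the width with the best leave-one-out q² of the output
layer, computed in closed form with the chosen centres held fixed. A full
greedy retrain per left-out point would be the literal LOO; the
fixed-centre form is the standard fast surrogate for linear-in-parameters
networks and keeps the 40-point scan interactive. Training-SSE selection is
available but degenerates toward small widths (memorisation) and is not the
default.

## Applicability domain

Leverages use the intercept-augmented design, h_i = x_i(XᵀX)⁻¹x_iᵀ, so
m = p + 1 parameters and training leverages sum to m; the warning leverage
is h* = 3m/n (0.333 for a 36-compound, 3-descriptor fit). σ is the
training residual SD with divisor n − p − 1 and the Y-outlier bound is
|e_i/σ| > 3 (raw residuals are exported alongside for plotting either
axis). Test compounds get leverages against the training Gram matrix and
Y-flags against the training σ, so both sets share one Williams plot.
`remove_and_refit` drops flagged training compounds (refusing to go below
n = p + 2) and returns the reduced data, the refit and the removal audit
trail.

## Five-fold rotation

The rotation holds out each subset in the published order T, D, A, B, C,
refits via a caller-supplied factory and reports per-fold and averaged R²,
F and RMS for the training and held-out portions. The published per-fold
numbers are not refittable (the descriptor values behind the published
models were never printed), so the machinery is validated on synthetic
data; a degenerate constant-prediction factory surfaces as an
undefined-statistic error rather than a silent NaN.

## Synthetic generator

`SyntheticSpec` defaults emulate the nitro-group training conditions:
n = 36 compounds, 3 true descriptors among 50, Gaussian noise with SD 0.19
log units (the training-RMS scale of the published models), standard-normal
descriptor marginals. Collinearity in the nuisance block comes from one
common latent factor, giving every nuisance pair expected correlation equal
to the requested level — the simplest structure that exercises the
|r| ≥ 0.8 pruning rule. Gaussian bumps over the signal columns provide the
nonlinearity for RBF tests. One `numpy.random.Generator` seeded from
`spec.seed` drives all draws (subset labelling uses seed + 1 so labels are
independent of the matrix draw but still reproducible).

What the generator does **not** emulate: the heavy-tailed, mixed-scale and
block-correlated marginals of real computed descriptor catalogues, discrete
counts, or structure–activity mechanisms. Passing tests therefore
demonstrate the correctness of the algorithms under controlled conditions,
not predictive performance on new chemistry.

## Known data inconsistencies in the packaged table

Recomputing summary statistics from the printed per-compound predictions
exposes three irreproducible published values, all in the nitro group
(group 1) MLR column:

1. Its training residuals have mean +0.145 — impossible for genuine OLS
   fitted values — so the training RMS recomputes to 0.234, not the
   published 0.192 (the training R² still matches, 0.828 vs 0.829, because
   the squared correlation is offset-invariant).
2. Two external-test rows carry gross printed residuals (+0.80 and +1.08
   log units, self-consistent between the value and residual columns), so
   the test R² recomputes to 0.629 against the published 0.917 and the
   through-origin slopes to (0.681, 1.228) against the published
   (0.88, 1.11).
3. The published external-set table appears label-shifted: its "R²" row
   coincides with the training R² values and its "q²ext" row with the
   test-set R² values reported in the text.

The fixture transcribes the table faithfully and the statistics are
reported as computed; the corresponding reference-value tests fail by
design rather than being loosened. The halogen and mixed groups recompute
cleanly. A related oddity (the mixed group's rotation rows swapping the
full-fit and test statistics) affects no packaged constant.

## Numerical choices and limitations

- Rank deficiency raises explicit errors in OLS and leverage computations
  (tolerance-based rank check); the RBF output layer alone is allowed a
  least-norm fallback because near-duplicate centres at large widths are
  expected during scans.
- PRESS refuses leverages of 1 (self-determining points) instead of
  dividing by zero.
- All tie-breaks (stepwise candidates, centre admission, width selection)
  prefer the earlier index / smaller value, making every procedure
  deterministic given input order.
- Problem sizes throughout the tests mirror the study (n ≤ 75, p = 3,
  ≤ 10 hidden units, 40-width scans), where every routine runs in well
  under a second; the implementations are dense-matrix and not intended
  for thousands of descriptors.
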