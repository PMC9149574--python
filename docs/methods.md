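# Methods

## Model

The classifier is a residual feed-forward network `f(x) = θᵀx + g_W(x)`
on flattened per-subject features (ROI-major: all T time points of ROI 1,
then ROI 2, …).  `g_W` is a single hidden layer of width K with ReLU
activations and a scalar output; `θ` is the linear skip layer.  The output
is passed through a sigmoid and trained with mean binary cross-entropy —
the standard instantiation of an "empirical loss" for a binary diagnosis
target, and the one that yields calibrated probabilities for ROC analysis.

The objective is `L(θ,W) + λ_eff‖θ‖₁` subject to the per-feature hierarchy
constraint `‖W_j⁽¹⁾‖_∞ ≤ M|θ_j|`.  The constraint never enters the
objective value; it is enforced exactly by the hierarchical proximal
operator (below), so every post-prox iterate is feasible.

### Hierarchical proximal operator

For each feature j independently, the prox solves

    min_{θ,W}  ½(θ−θ̃)² + ½‖W−W̃‖² + t·|θ|   s.t.  ‖W‖_∞ ≤ M|θ|

in closed form: sort `|W̃|` descending, compute for n = 0..K

    w_n = M/(1+nM²) · SoftThreshold_t(|θ̃| + M·Σ_{i≤n}|W̃_(i)|)

and keep the first n whose `w_n` lies between the (n+1)-th and n-th sorted
magnitudes (sentinels +∞ and 0).  Then `θ = sign(θ̃)·w*/M` and W is clipped
entrywise to magnitude `w*`.  Implementation notes:

* `sign(0)` is taken as +1, which guarantees `θ_j = 0 ⇒ W_j = 0` exactly
  (a zero skip weight removes the feature entirely); for `θ̃ = 0` the two
  signed minimisers are tied, so this costs no optimality.
* Sorting is stable on descending absolute value; original column order
  breaks ties.
* The prox produces exact zeros, so "active feature" means `θ_j ≠ 0`
  literally, with no tolerance.
* The test suite checks the operator against a dense-grid minimiser of the
  constrained convex subproblem (exact in W given θ, 1e-6 grid in θ) on
  200 random instances.

### Structural (DTI) penalty

Per subject, FA connectivity `ρ` maps to `D_ji = exp(−ρ_ji²/σ)`: strong
white-matter connections are penalised weakly ("inverse proportional"
coupling).  The bandwidth σ is the mean over **training** subjects of the
sample SD (denominator n−1) of the upper-triangle off-diagonal FA entries;
restricting to the training split keeps model selection leakage-free, and
the same σ is reused for validation/test subjects.  Inputs must have a
zero FA diagonal (self-connectivity is undefined), so D's diagonal is 1
and shifts all eigenvalues equally.  σ = 0 (all networks constant) is a
degenerate input and raises.

Each D is summarised by its maximal eigenvalue; since the skip weights are
shared across subjects, the per-subject eigenvalues cannot each scale the
shared penalty, and they are reduced to one scalar `c` by the arithmetic
mean over training subjects — preserving the cohort-level magnitude.  The
multi-modal objective then uses `λ_eff = c·λ`; `c = 1` recovers the plain
LassoNet exactly (regression-tested against an independent implementation
to 1e-8 per path step).

Two application modes exist. Default: `λ_eff = c·λ` with the path update
`λ ← (1+ε)λ` — a constant multiplier, absorbed into the λ scale.
`dti_compound=True` applies the literal compounding update
`λ ← (1+ε)·λ·c` each step; it is kept for fidelity but degenerates the
path granularity when c is far from 1, so it is off by default.

## Training

Full-batch gradient descent with momentum 0.9, followed each epoch by the
prox at threshold `α·λ_eff` (step-size-scaled, the standard
proximal-gradient semantics; an unscaled mode is available via
`prox_stepsize_scaled=False`).  Full-batch updates make runs bit-reproducible
given the seed and keep the active count k essentially monotone along the
path.  A dense warm start (λ = 0, unconstrained) precedes either

* the **grid protocol** (default): one model per λ ∈ {0.1, …, 1.0}, each
  warm-started from the same dense solution, selected by validation
  accuracy with ties toward smaller λ (the denser model); or
* the **multiplicative path**: λ grows by (1+ε) per step from an automatic
  starting point until k = 0.  λ_start is found by log-scale bisection on
  a short (≤10-epoch) training probe for the largest λ keeping ≥98% of
  features active — a single prox application is far weaker than the
  iterated prox, whose repeated clipping cascades, so probing with actual
  training steps is what makes the starting point meaningful.

Features are z-scored per column on the training split (L1 penalties are
scale-sensitive); validation and test reuse the training statistics.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| hidden width K | 32 | small enough for desk-scale cohorts, expressive enough for the nonlinear part |
| M (hierarchy) | 1.0 | balances skip and first-layer magnitudes; with M ≫ 1 the first-layer mass `M·Σ|W|` shields features from the soft threshold and the 0.1–1.0 grid never sparsifies |
| α (learning rate) | 1e-2 | with B = 100 full-batch epochs per λ this converges the prox-gradient iteration; at 1e-3 the grid stays fully dense within the same budget |
| B (epochs per λ) | 100 | enough for the clipping cascade to settle at each penalty level |
| ε (path multiplier) | 0.02 | fine-grained λ resolution on the multiplicative path |
| λ grid | 0.1 … 1.0, step 0.1 | the interval on which the penalty level is selected by validation accuracy |

M and α interact: the per-epoch threshold is `α·c·λ`, so what matters is
its scale relative to the equilibrium skip-weight magnitudes.  The
defaults make the grid sweep from ~dense (λ = 0.1) to strongly sparse
(λ = 1.0) on standardized features.

## Baselines

Lasso `(1/n)‖y−XW‖² + λ‖W‖₁` and elastic net `‖y−XW‖² + λ₂‖W‖₂² + λ₁‖W‖₁`
delegate to scikit-learn coordinate descent with exact objective-scale
mappings (checked against the orthonormal-design soft threshold and the
ridge closed form).  Group lasso `‖y−XW‖² + λΣ√p_l‖W_l‖₂` and sparse group
lasso `‖y−XW‖² + λ₁Σ‖W_l‖₂ + λ₂‖W‖₁` have no in-environment solver and use
FISTA with exact block/compound proximal maps (gradient in O(nd) form for
the d ≫ n regime).  Groups are one per ROI (T features each) — the natural
partition of the flattened features.  Labels are coded ±1 for these
squared-error selectors.  Selected features feed a linear SVM (C = 1);
hyperparameters come from a {0.01, 0.05, 0.1, 0.2, 0.5, 1.0} grid chosen
by validation accuracy, ties toward the sparsest model.

The comparison harness uses one fixed stratified 6:2:2 subject split
(floors with remainder to train: 85 → 51/17/17) reused across methods and
repeats; per repeat only training randomness (network initialisation)
varies, so deterministic pipelines have zero SD by construction.
Stratification is a deliberate choice: at these sample sizes an
unstratified split can lose a class from a 17-subject test set.

## Metrics

ACC, SEN, SPE, GMean, F1 from the confusion table; GMean is the geometric
mean `sqrt(SEN·SPE)` (robust to class imbalance).  Zero-denominator
sensitivity/specificity raise a named error; an all-negative F1 is defined
as 0 with a warning.  ROC points group tied scores and always include
(0,0) and (1,1); the trapezoidal AUC equals the pairwise Mann–Whitney
statistic (tested to 1e-12).

## Synthetic cohort generator

Per subject: a lag-1 autoregressive Gaussian time series with innovations
scaled so the stationary variance is ~1, cross-ROI covariance with
correlation `fc_block_corr` inside six contiguous ROI blocks (a crude
community structure), and — for group 1 — a fixed sinusoid of period T/8
scaled by `effect_size` (in noise-SD units) added to the informative ROIs,
making specific (time point, ROI) features discriminative.  FA =
`clip(coupling·|functional correlation| + (1−coupling)·0.3 + N(0, fa_noise_sd))`,
symmetrised, zero diagonal; the 0.3 baseline is a mid-range white-matter
FA that keeps clipping rare.

Defaults (30 subjects/group, T = 60, R = 30, 5 informative ROIs, effect
size 2.0, AR 0.3, block correlation 0.3, coupling 0.6, FA noise 0.05) keep
the d ≫ n regime (1800 features vs 60 subjects) while running in seconds —
the problem sizes used throughout the tests and the acceptance script.

What the generator does **not** emulate: hemodynamic response dynamics and
scanner noise spectra, spatially varying tract anatomy, realistic FA
distributions, site/motion confounds, or label noise.  Passing tests
therefore demonstrate the algorithmic contracts (prox optimality,
constraint enforcement, path behaviour, leakage-free selection, support
recovery under a known planted signal) — not clinical performance on real
scans, whose published accuracies come from restricted-access data and are
not reproduction targets here.

## Numerical choices and degenerate inputs

* Symmetry tolerance 1e-8 for eigenvalue inputs, 1e-9 for FA files
  (symmetrised after validation); eigenvalues via LAPACK `eigh` on the
  symmetrised matrix.
* Zero-variance features get SD 1 in the z-score (they carry no signal and
  end up centred at 0).
* λ-selection ties → smaller λ; hyperparameter ties → sparsest model;
  ranking ties → lower region id; prox sorting ties → original column order.
* Empty selected-feature sets fall back to majority-class prediction with
  a warning rather than failing the harness.
* The path warns and returns the partial path if `max_path_steps` is hit.

## Limitations

Binary classification only (group pairs are extracted from multi-group
manifests); one hidden layer (the class allows arbitrary feed-forward
nets); CPU full-batch training, sized for cohorts of tens-to-hundreds of
subjects; the AAL-90 centroid coordinates bundled for node export are
approximate and user-replaceable; region-importance aggregation (L1 mass
of skip weights per ROI) is one reasonable choice among several — selection
frequency across repeats is exposed as an alternative workflow, not a
default.
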