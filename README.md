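# mmlassonet

Sparse neural feature selection for multimodal neuroimaging classification.

Distinguishing Alzheimer's disease (AD), early mild cognitive impairment
(EMCI) and healthy controls (HC) from resting-state fMRI is a severely
underdetermined problem: flattening each subject's ROI time series (e.g.
187 time points x 90 AAL regions = 16,830 features) leaves far more
features than subjects.  `mmlassonet` implements a **multi-modal LassoNet**:
a residual feed-forward classifier whose L1-penalised skip layer performs
feature selection, with the penalty scaled by a multiplier derived from
each subject's DTI structural connectivity — encoding the assumption that
structure and function are coupled in the brain.

## The model

The hypothesis class is the set of residual networks

```
f(x) = θᵀx + g_W(x)
```

with `θ ∈ R^d` the skip (feature-selection) weights and `g_W` a
one-hidden-layer ReLU network.  Training minimises

```
min_{θ,W}  L(θ, W) + λ_eff ‖θ‖₁   subject to  ‖W_j⁽¹⁾‖_∞ ≤ M |θ_j|,  j = 1..d
```

where `L` is the mean binary cross-entropy.  The hierarchy constraint ties
each feature's first-layer weights to its skip weight: when the proximal
step drives `θ_j` to exactly zero the feature leaves the network entirely.
The constraint is enforced in closed form by the **hierarchical proximal
operator** applied after every full-batch gradient step.

The multimodal part: each subject's FA network `ρ` gives a penalty matrix
`D_ji = exp(−ρ_ji²/σ)` (strong structural connections ⇒ weak penalties),
with `σ` the mean per-subject SD of FA entries on the training split.  The
per-subject maximal eigenvalues of `D` are averaged over training subjects
into a scalar `c`, and `λ_eff = c·λ`.  With `c = 1` the model reduces
exactly to the standard LassoNet.

Selection of `λ` is by validation accuracy, either on an explicit grid
`{0.1, …, 1.0}` (default) or along a multiplicative dense-to-sparse path
`λ ← (1+ε)λ`.  Baselines (lasso, group lasso, sparse group lasso, elastic
net, each + linear SVM), confusion-matrix metrics (ACC/SEN/SPE/GMean/F1),
ROC/AUC, a synthetic multimodal cohort generator with ground-truth
informative ROIs, and AAL-90 region ranking/export are included.

## Worked example

```python
from mmlassonet import (CohortConfig, SplitSpec, fit_multimodal,
                        generate_cohort, split_dataset)

cohort = generate_cohort(CohortConfig(seed=0))   # 60 subjects, 60x30 series
train, valid, test = split_dataset(cohort, SplitSpec(seed=0))  # 6:2:2
model = fit_multimodal(train, valid)
labels, probs = model.predict(test)
```

Running `python examples/02_fit_multimodal.py` prints:

```
penalty bandwidth sigma : 0.0839
structural multiplier c : 18.751 (scales the L1 penalty on the skip weights)
selected lambda         : 0.1 with 132 of 1800 features active
test metrics (%): {'ACC': 100.0, 'SEN': 100.0, 'SPE': 100.0, 'GMean': 100.0,
                   'F1': 100.0, 'AUC': 1.0}
```

`sigma` is the penalty bandwidth estimated from the training FA networks;
`c` multiplies every penalty level; the selected model keeps 132 of 1800
flattened features, and the held-out test split is classified perfectly —
the synthetic cohort plants a strong group signal in 5 known ROIs, and
`examples/04_rank_regions.py` shows those planted regions ranked first.
The other examples cover cohort simulation, the method comparison table,
and the structural-penalty pipeline step by step.

A thin CLI wraps the same functions:

```bash
mmlassonet simulate --config cohort.yaml --out data/
mmlassonet fit --data data/ --out run --seed 0
mmlassonet compare --data data/ --methods lasso,mmlassonet --out cmp
mmlassonet rank-regions --model run.model.json --out regions
```

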