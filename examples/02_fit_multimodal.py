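"""Fit the multi-modal LassoNet on a synthetic cohort and evaluate it.

The structural networks of the training subjects set the penalty
multiplier c (mean of the maximal eigenvalues of the per-subject penalty
matrices exp(-rho^2/sigma)); the penalty level lambda is chosen on the
validation split; the held-out test split is scored once at the end.
"""

import numpy as np

from mmlassonet import (
    CohortConfig, SplitSpec, compute_metrics, confusion, fit_multimodal,
    generate_cohort, roc_auc, split_dataset,
)

cohort = generate_cohort(CohortConfig(seed=0))
train, valid, test = split_dataset(cohort, SplitSpec(seed=0))

model = fit_multimodal(train, valid)

print(f"penalty bandwidth sigma : {model.sigma:.4f}")
print(f"structural multiplier c : {model.dti_scalar:.3f} "
      "(scales the L1 penalty on the skip weights)")
print(f"selected lambda         : {model.lambda_val:g} "
      f"with {model.params.k_active()} of {model.params.d} features active")

labels, probs = model.predict(test)
m = compute_metrics(confusion(test.labels, labels),
                    auc=roc_auc(test.labels, probs)[1])
print("test metrics (%):",
      {k: round(v, 2) for k, v in m.as_percent_dict().items()})
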