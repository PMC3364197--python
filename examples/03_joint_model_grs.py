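"""Fit the 13-SNP joint logistic model and compute the genetic risk score.

The GRS of a subject is the fitted linear predictor a + sum b_i x_i
(log-odds of disease).  Prints the per-SNP conditional odds ratios, the
mean GRS by arm, model fit (McFadden R²), in-sample AUC, and the OR per
GRS unit — which equals e exactly for an in-sample refit.
"""

import numpy as np

from amdgrs import (default_config, fit_joint_model, grs_for_study,
                    mcfadden_r2, or_per_grs_unit, roc_auc, simulate_cohort)

cfg = default_config(seed=1)
study = simulate_cohort(cfg)
model = fit_joint_model(study, cfg.panel)
scores = grs_for_study(model, study)

print(f"intercept a = {model.intercept:.2f}")
ci = model.or_ci95()
for snp, or_, (lo, hi) in zip(model.snp_ids, model.odds_ratios(), ci):
    print(f"  {snp:<12} OR {or_:5.2f}  (95% CI {lo:.2f}-{hi:.2f})")

case = study.case_mask
print(f"\nmean GRS cases    {scores.values[case].mean():6.2f}")
print(f"mean GRS controls {scores.values[~case].mean():6.2f}")
print(f"McFadden R2       {mcfadden_r2(model, study):.4f}")
print(f"in-sample AUC     {roc_auc(scores, study.status):.3f}")
or_unit, (lo, hi) = or_per_grs_unit(study, scores)
print(f"OR per GRS unit   {or_unit:.2f} (95% CI {lo:.2f}-{hi:.2f})  "
      f"[= e, the in-sample self-calibration identity]")
print("\nCases carry a visibly higher mean score than controls; an AUC "
      "near 0.8 means a random case outscores a random control ~80% of "
      "the time.")
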