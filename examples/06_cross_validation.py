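"""Internal validation: cross-validated AUC and a parsimonious model.

Repeated random subsampling (2/3 train / 1/3 test) checks how much of
the in-sample AUC is optimism from estimating the GRS weights on the
same data; backward elimination of whole loci asks how few SNPs keep
the full model's discrimination.
"""

from amdgrs import (cross_validate, default_config, fit_joint_model,
                    grs_for_study, roc_auc, simulate_cohort)
from amdgrs.validation import parsimonious_search

cfg = default_config(seed=1)
study = simulate_cohort(cfg)
model = fit_joint_model(study, cfg.panel)
in_auc = roc_auc(grs_for_study(model, study), study.status)

cv = cross_validate(study, cfg.panel, n_repeats=200, seed=1)
lo, hi = cv.ci95
print(f"in-sample AUC        {in_auc:.3f}")
print(f"cross-validated AUC  {cv.mean_auc:.3f} "
      f"(95% CI {lo:.3f}-{hi:.3f}, {cv.n_repeats} repeats)")

steps, best = parsimonious_search(study, cfg.panel)
print("\nbackward elimination of loci (weakest single-locus AUC first):")
for s in steps:
    label = "full model" if s.dropped_locus is None else f"- {s.dropped_locus}"
    print(f"  {label:<14} {len(s.retained_snps):>2} SNPs  "
          f"AUC {s.auc:.3f}  R2 {s.mcfadden_r2:.4f}")
print(f"\nsmallest model within 0.001 AUC of full: "
      f"{len(best.retained_snps)} SNPs")
print("The held-out AUC sits just below the in-sample value (small "
      "optimism), and several weak loci can be dropped with essentially "
      "no loss of discrimination.")
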