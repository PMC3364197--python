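"""Per-SNP case-control association on a simulated cohort.

For each panel SNP: additive per-allele odds ratio with Wald 95% CI and
p-value, single-SNP AUC, and the exact Hardy-Weinberg test in controls.
"""

from amdgrs import default_config, simulate_cohort
from amdgrs.association import association_frame, association_table

cfg = default_config(seed=1)
study = simulate_cohort(cfg)
df = association_frame(association_table(study, cfg.panel))
print(df.drop(columns="error").to_string(
    index=False, float_format=lambda v: f"{v:.3g}"))
print("\nORs above 1 mean the risk allele raises disease odds; the strong "
      "CFH/ARMS2 variants carry ORs near 3 and single-SNP AUCs near 0.68, "
      "the weak lipid-pathway variants sit close to 1 and AUC 0.5.")
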