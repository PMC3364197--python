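"""Per-SNP case-control association statistics.

For each panel SNP: risk-allele frequencies by group, the additive
per-allele odds ratio from a single-SNP logistic regression (Wald 95% CI
and p-value), the exact Hardy-Weinberg test in controls, and the
single-SNP AUC.  An additive logistic model codes genotype as risk-allele
dosage 0/1/2, so one coefficient measures the multiplicative change in
disease odds per risk allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from ._glm import logit_fit as _logit_fit
from .errors import FitError
from .panel import CaseControlStudy, SnpPanel
from .validation import roc_auc

__all__ = [
    "AssociationResult",
    "fit_single_snp",
    "hwe_exact_test",
    "snp_auc_from_genotype_distributions",
    "association_table",
]


@dataclass(frozen=True)
class AssociationResult:
    """Single-SNP association summary (one row of the association table)."""

    snp_id: str
    or_per_allele: float
    ci95: tuple[float, float]
    p_value: float
    freq_cases: float
    freq_controls: float
    auc: float
    hwe_p_controls: float
    error: str | None = None


def fit_single_snp(study: CaseControlStudy, snp_id: str,
                   adjust_age_sex: bool = False,
                   lrt: bool = False) -> AssociationResult:
    """Additive logistic regression of status on one SNP's dosage.

    OR per risk allele is ``exp(beta)`` with Wald 95% CI
    ``exp(beta ± 1.96 SE)``; the p-value is two-sided Wald by default
    (``lrt=True`` swaps in the likelihood-ratio p).  ``adjust_age_sex``
    adds age and sex covariates for sensitivity analysis.
    """
    if study.n_cases == 0 or study.n_controls == 0:
        raise FitError("need both cases and controls")
    g = study.dosage[snp_id].to_numpy(dtype=float)
    if np.unique(g).size < 2:
        raise FitError(f"{snp_id}: dosage has no variation")
    cols = [np.ones_like(g), g]
    if adjust_age_sex:
        if study.age_years is None or study.sex is None:
            raise FitError("age/sex adjustment requested without covariates")
        cols.append(np.asarray(study.age_years, dtype=float))
        cols.append(np.array([1.0 if s == "M" else 0.0 for s in study.sex]))
    X = np.column_stack(cols)
    y = study.status.astype(float)
    try:
        res = _logit_fit(X, y)
    except FitError as exc:
        raise FitError(f"{snp_id}: {exc}") from exc
    beta, se = res.params[1], res.bse[1]
    if lrt:
        X0 = np.delete(X, 1, axis=1)
        res0 = _logit_fit(X0, y)
        lr = 2.0 * (res.llf - res0.llf)
        from scipy.stats import chi2
        p = float(chi2.sf(max(lr, 0.0), df=1))
    else:
        p = float(2.0 * norm.sf(abs(beta / se)))

    case = study.case_mask
    freq_cases = float(g[case].mean() / 2.0)
    freq_controls = float(g[~case].mean() / 2.0)
    auc = roc_auc(g, study.status)
    ctrl = study.dosage[snp_id].to_numpy()[~case]
    hwe_p = hwe_exact_test(int((ctrl == 0).sum()), int((ctrl == 1).sum()),
                           int((ctrl == 2).sum()))
    return AssociationResult(
        snp_id=snp_id,
        or_per_allele=float(np.exp(beta)),
        ci95=(float(np.exp(beta - 1.959963984540054 * se)),
              float(np.exp(beta + 1.959963984540054 * se))),
        p_value=p,
        freq_cases=freq_cases,
        freq_controls=freq_controls,
        auc=auc,
        hwe_p_controls=hwe_p,
    )


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Conditional on the observed allele counts, the heterozygote count
    follows a known distribution under HWE; the p-value sums the
    probabilities of all heterozygote counts no more probable than the
    observed one (the standard exact HWE test).  Returns p in (0, 1].
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_alt = 2 * n_hom_alt + n_het  # alt allele count; test is symmetric
    h_min = n_alt % 2
    h_max = min(n_alt, 2 * n - n_alt)
    hs = np.arange(h_min, h_max + 1, 2)
    # log P(h | allele counts) up to a shared constant
    logp = (hs * math.log(2.0)
            - gammaln(hs + 1)
            - gammaln((n_alt - hs) / 2 + 1)
            - gammaln((2 * n - n_alt - hs) / 2 + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[(hs == n_het).argmax()]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def snp_auc_from_genotype_distributions(case_dist, control_dist) -> float:
    """Exact single-SNP AUC from genotype distributions.

    AUC is the probability that a random case carries more risk alleles
    than a random control, with half credit for ties:
    ``sum_ij case(i) control(j) [i>j] + 0.5 [i=j]``.
    """
    c = np.asarray(case_dist, dtype=float)
    u = np.asarray(control_dist, dtype=float)
    for d in (c, u):
        if d.ndim != 1 or (d < 0).any() or abs(d.sum() - 1.0) > 1e-9:
            raise ValueError("each distribution must be a probability vector")
    if c.shape != u.shape:
        raise ValueError("distributions must have equal support")
    gt = np.tril(np.ones((len(c), len(c))), -1)  # [i > j]
    return float(c @ gt @ u + 0.5 * float(c @ u))


def association_table(study: CaseControlStudy, panel: SnpPanel,
                      subset=None, **fit_kwargs) -> list[AssociationResult]:
    """One :class:`AssociationResult` per panel SNP, optionally on a subset.

    ``subset`` is a boolean mask over subjects or a callable
    ``study -> mask`` (e.g. GA cases plus all controls).  Per-SNP fit
    failures are collected into the result's ``error`` field rather than
    aborting the table.
    """
    if subset is not None:
        mask = subset(study) if callable(subset) else np.asarray(subset, bool)
        study = study.subset(mask)
    if study.n_cases == 0 or study.n_controls == 0:
        raise FitError("subset must retain both cases and controls")
    out = []
    for snp in panel.ids:
        try:
            out.append(fit_single_snp(study, snp, **fit_kwargs))
        except FitError as exc:
            out.append(AssociationResult(
                snp_id=snp, or_per_allele=math.nan, ci95=(math.nan, math.nan),
                p_value=math.nan, freq_cases=math.nan, freq_controls=math.nan,
                auc=math.nan, hwe_p_controls=math.nan, error=str(exc)))
    return out


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of an association table."""
    return pd.DataFrame({
        "snp_id": [r.snp_id for r in results],
        "or_per_allele": [r.or_per_allele for r in results],
        "ci95_low": [r.ci95[0] for r in results],
        "ci95_high": [r.ci95[1] for r in results],
        "p_value": [r.p_value for r in results],
        "freq_cases": [r.freq_cases for r in results],
        "freq_controls": [r.freq_controls for r in results],
        "auc": [r.auc for r in results],
        "hwe_p_controls": [r.hwe_p_controls for r in results],
        "error": [r.error or "" for r in results],
    })
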