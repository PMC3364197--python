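"""Discrimination and internal validation of the risk model.

Covers the ROC/AUC computation (Mann-Whitney form with midrank tie
handling), repeated random-subsampling cross-validation of the GRS
(refit on 2/3 of the cohort, test AUC on the held-out 1/3, many
repeats), and a greedy backward search for a parsimonious model that
drops whole locus groups ranked by single-locus discriminative value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import FitError, ValidationError
from .panel import CaseControlStudy, SnpPanel

__all__ = [
    "roc_auc",
    "CrossValidationResult",
    "cross_validate",
    "ParsimoniousStep",
    "parsimonious_search",
    "drop_one_locus_comparison",
]


def roc_auc(scores, status) -> float:
    """AUC of the ROC: P(random case outscores a random control), ties 0.5.

    Equivalent to the trapezoidal area under the empirical ROC traced by
    sweeping the score cut-off.
    """
    s = np.asarray(getattr(scores, "values", scores), dtype=float)
    y = np.asarray(status).astype(int)
    if y.min() == y.max():
        raise ValueError("need both cases and controls to compute an AUC")
    return float(roc_auc_score(y, s))


@dataclass(frozen=True)
class CrossValidationResult:
    """Summary of repeated random-subsampling cross-validation."""

    n_repeats: int
    train_fraction: float
    aucs: np.ndarray            # per-repeat held-out AUC
    n_skipped: int
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def ci95(self) -> tuple[float, float]:
        """Normal-approximation CI of the mean over repeats."""
        half = 1.959963984540054 * self.aucs.std(ddof=1) / \
            np.sqrt(len(self.aucs))
        return (self.mean_auc - half, self.mean_auc + half)

    def percentile_ci95(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.aucs, [2.5, 97.5])
        return (float(lo), float(hi))


def cross_validate(study: CaseControlStudy, panel: SnpPanel,
                   n_repeats: int = 2000, train_fraction: float = 2 / 3,
                   seed: int = 0, stratified: bool = False
                   ) -> CrossValidationResult:
    """Repeated random 2/3-train / 1/3-test subsampling of the cohort.

    Per repeat the joint model is refit on the training split and the
    held-out subjects are scored with the training weights; the held-out
    AUC is recorded.  Splits are simple random subsamples by default
    (``stratified=True`` preserves the case/control ratio).  Repeats
    whose training split cannot be fitted are skipped; more than 5%
    skips aborts.  Deterministic given ``seed``.
    """
    from .model import fit_joint_model, grs_for_study

    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must lie in (0,1)")
    rng = np.random.default_rng(seed)
    n = study.n
    n_train = int(round(train_fraction * n))
    if n_train < 2 or n - n_train < 2:
        raise ValidationError("cohort too small for the requested split")
    aucs = []
    skipped = 0
    for _ in range(n_repeats):
        if stratified:
            case_idx = np.flatnonzero(study.case_mask)
            ctrl_idx = np.flatnonzero(~study.case_mask)
            rng.shuffle(case_idx)
            rng.shuffle(ctrl_idx)
            nc = int(round(train_fraction * len(case_idx)))
            nu = int(round(train_fraction * len(ctrl_idx)))
            train_idx = np.concatenate([case_idx[:nc], ctrl_idx[:nu]])
        else:
            train_idx = rng.permutation(n)[:n_train]
        mask = np.zeros(n, dtype=bool)
        mask[train_idx] = True
        train, test = study.subset(mask), study.subset(~mask)
        try:
            if train.n_cases == 0 or train.n_controls == 0:
                raise FitError("single-class training split")
            model = fit_joint_model(train, panel)
            scores = grs_for_study(model, test)
            aucs.append(roc_auc(scores, test.status))
        except (FitError, ValueError):
            skipped += 1
    if skipped > 0.05 * n_repeats:
        raise ValidationError(
            f"{skipped}/{n_repeats} cross-validation splits unfittable")
    return CrossValidationResult(
        n_repeats=n_repeats, train_fraction=train_fraction,
        aucs=np.asarray(aucs), n_skipped=skipped, seed=seed)


@dataclass(frozen=True)
class ParsimoniousStep:
    """One row of the backward-elimination trajectory."""

    dropped_locus: str | None     # None for the full model
    retained_snps: tuple[str, ...]
    auc: float
    mcfadden_r2: float


def _locus_auc(study: CaseControlStudy, panel: SnpPanel, locus: str) -> float:
    """Discriminative value of one locus alone: AUC of a GRS fitted on
    that locus's SNPs only."""
    from .model import fit_joint_model, grs_for_study

    sub = panel.subset([s.id for s in panel.snps_in_locus(locus)])
    model = fit_joint_model(study, sub)
    return roc_auc(grs_for_study(model, study), study.status)


def parsimonious_search(study: CaseControlStudy, panel: SnpPanel,
                        auc_tolerance: float = 0.001
                        ) -> tuple[list[ParsimoniousStep], ParsimoniousStep]:
    """Greedy backward elimination of whole locus groups.

    Loci are ranked by their single-locus AUC; the weakest remaining
    locus is dropped at each step and the joint model refit on the
    surviving SNPs, recording AUC and McFadden R².  Returns the full
    trajectory (first row = full model) and the smallest model whose AUC
    stays within ``auc_tolerance`` of the full model's.  A fit failure
    truncates the trajectory with the rows obtained so far.
    """
    from .model import fit_joint_model, grs_for_study, mcfadden_r2

    loci = panel.locus_groups
    if len(loci) < 2:
        raise ValidationError("need at least two locus groups")
    order = sorted(loci, key=lambda L: _locus_auc(study, panel, L))

    def _evaluate(snp_ids, dropped):
        sub = panel.subset(snp_ids)
        model = fit_joint_model(study, sub)
        auc = roc_auc(grs_for_study(model, study), study.status)
        return ParsimoniousStep(dropped_locus=dropped,
                                retained_snps=tuple(snp_ids),
                                auc=auc,
                                mcfadden_r2=mcfadden_r2(model, study))

    steps = []
    remaining = list(panel.ids)
    try:
        steps.append(_evaluate(remaining, None))
        for locus in order[:-1]:  # keep at least one locus
            drop_ids = {s.id for s in panel.snps_in_locus(locus)}
            remaining = [s for s in remaining if s not in drop_ids]
            steps.append(_evaluate(remaining, locus))
    except FitError:
        pass  # partial trajectory is still informative
    full_auc = steps[0].auc
    best = min((s for s in steps if s.auc >= full_auc - auc_tolerance),
               key=lambda s: len(s.retained_snps))
    return steps, best


def drop_one_locus_comparison(study: CaseControlStudy, panel: SnpPanel
                              ) -> pd.DataFrame:
    """AUC and R² after dropping each single locus from the full model.

    Complements the strict greedy trajectory: an exhaustive
    leave-one-locus-out sweep, so non-greedy parsimonious choices (drop a
    locus the greedy order would have kept) are visible too.
    """
    from .model import fit_joint_model, grs_for_study, mcfadden_r2

    rows = []
    for locus in panel.locus_groups:
        drop_ids = {s.id for s in panel.snps_in_locus(locus)}
        keep = [s for s in panel.ids if s not in drop_ids]
        sub = panel.subset(keep)
        model = fit_joint_model(study, sub)
        rows.append({
            "dropped_locus": locus,
            "n_snps": len(keep),
            "auc": roc_auc(grs_for_study(model, study), study.status),
            "mcfadden_r2": mcfadden_r2(model, study),
        })
    return pd.DataFrame(rows)
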