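"""Joint multi-SNP logistic model and the genetic risk score (GRS).

The GRS of a subject with dosages ``x_1..x_k`` is the fitted linear
predictor of the joint logistic regression of case status on all panel
SNPs at once::

    GRS = a + sum_i b_i x_i

where ``a`` is the model intercept and ``b_i`` the per-SNP log-odds
coefficients; ``exp(b_i)`` is the odds ratio of the i-th variant
*conditional on* the other panel SNPs.  Because the GRS is the model's
own log-odds of disease, an in-sample univariate refit of status on the
GRS has slope exactly 1 — the odds ratio per GRS unit is e ≈ 2.72, a
useful self-calibration identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._glm import logit_fit
from .errors import FitError
from .panel import CaseControlStudy, SnpPanel

__all__ = [
    "FittedRiskModel",
    "RiskScoreSet",
    "fit_joint_model",
    "compute_grs",
    "grs_for_study",
    "GroupComparison",
    "mcfadden_r2",
    "or_per_grs_unit",
    "compare_grs_groups",
    "model_from_panel_weights",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class FittedRiskModel:
    """Intercept, per-SNP log-odds weights and fit diagnostics."""

    intercept: float
    betas: np.ndarray              # log-OR per SNP, panel order
    snp_ids: tuple[str, ...]
    se: np.ndarray | None = None   # Wald standard errors (None if imported)
    llf: float | None = None
    llnull: float | None = None
    iterations: int | None = None
    gradient_norm: float | None = None

    @property
    def k(self) -> int:
        return len(self.betas)

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.betas)

    def or_ci95(self) -> np.ndarray:
        """Per-SNP Wald 95% CIs on the odds-ratio scale, shape (k, 2)."""
        if self.se is None:
            raise ValueError("model carries no standard errors")
        lo = np.exp(self.betas - _Z95 * self.se)
        hi = np.exp(self.betas + _Z95 * self.se)
        return np.column_stack([lo, hi])


@dataclass(frozen=True)
class RiskScoreSet:
    """Per-subject GRS values (log-odds scale), aligned to a study."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ValueError("GRS values must be finite")

    def __len__(self) -> int:
        return len(self.values)


def fit_joint_model(study: CaseControlStudy, panel: SnpPanel,
                    tol: float = 1e-8, maxiter: int = 100) -> FittedRiskModel:
    """ML logistic fit of case status on all panel SNPs jointly.

    The design matrix is [1, dosages]; rank deficiency (e.g. duplicated
    or collinear SNP columns) and separation raise :class:`FitError`
    naming the offending columns.
    """
    if study.n_cases == 0 or study.n_controls == 0:
        raise FitError("need both cases and controls")
    G = study.dosage[list(panel.ids)].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(G)), G])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        offending = _dependent_columns(X, panel.ids)
        raise FitError(f"design matrix rank deficient; involved SNPs: "
                       f"{offending}")
    y = study.status.astype(float)
    res = logit_fit(X, y, tol=tol, maxiter=maxiter)
    grad = res.model.score(res.params)
    return FittedRiskModel(
        intercept=float(res.params[0]),
        betas=np.asarray(res.params[1:], dtype=float),
        snp_ids=tuple(panel.ids),
        se=np.asarray(res.bse[1:], dtype=float),
        llf=float(res.llf),
        llnull=float(res.llnull),
        iterations=int(res.mle_retvals.get("iterations", -1)),
        gradient_norm=float(np.linalg.norm(grad)),
    )


def _dependent_columns(X: np.ndarray, ids) -> list[str]:
    """Greedy scan for dosage columns linearly dependent on earlier ones."""
    out = []
    for j in range(1, X.shape[1]):
        sub = X[:, : j + 1]
        if np.linalg.matrix_rank(sub) < sub.shape[1]:
            out.append(ids[j - 1])
    return out


def compute_grs(model: FittedRiskModel, dosages) -> RiskScoreSet:
    """Affine score ``a + sum b_i x_i`` per subject.

    ``dosages`` is an (n, k) array/DataFrame or a single length-k vector,
    columns in the model's SNP order.
    """
    D = np.atleast_2d(np.asarray(dosages, dtype=float))
    if D.shape[1] != model.k:
        raise ValueError(f"dosage vectors of length {D.shape[1]} do not "
                         f"match model k={model.k}")
    return RiskScoreSet(model.intercept + D @ model.betas)


def grs_for_study(model: FittedRiskModel, study: CaseControlStudy
                  ) -> RiskScoreSet:
    """GRS per study subject (columns aligned by SNP id)."""
    return compute_grs(model, study.dosage[list(model.snp_ids)].to_numpy())


def mcfadden_r2(model: FittedRiskModel, study: CaseControlStudy) -> float:
    """McFadden pseudo-R²: ``1 − lnL(model) / lnL(intercept-only)``.

    If the model object carries fitted log-likelihoods they are used;
    otherwise both are recomputed directly on the study.
    """
    if model.llf is not None and model.llnull is not None:
        llf, llnull = model.llf, model.llnull
    else:
        llf = _log_likelihood(model, study)
        llnull = _null_log_likelihood(study)
    if llnull == 0.0:
        raise ValueError("null log-likelihood is zero (single-class data?)")
    return float(1.0 - llf / llnull)


def _log_likelihood(model: FittedRiskModel, study: CaseControlStudy) -> float:
    from scipy.special import expit
    eta = model.intercept + \
        study.dosage[list(model.snp_ids)].to_numpy(dtype=float) @ model.betas
    p = expit(eta)
    y = study.status
    return float(np.sum(np.log(np.where(y == 1, p, 1 - p))))


def _null_log_likelihood(study: CaseControlStudy) -> float:
    n1, n0 = study.n_cases, study.n_controls
    n = n1 + n0
    if n1 == 0 or n0 == 0:
        return 0.0
    return float(n1 * np.log(n1 / n) + n0 * np.log(n0 / n))


def or_per_grs_unit(study: CaseControlStudy, scores: RiskScoreSet
                    ) -> tuple[float, tuple[float, float]]:
    """Odds ratio per one-unit GRS increase, with Wald 95% CI.

    Univariate logistic refit of status on the score.  When the scores
    are the in-sample linear predictor of a converged joint fit on the
    same study, the slope is exactly 1 (the joint fit's score equations
    already hold), so the OR equals e ≈ 2.718.
    """
    s = scores.values
    if np.ptp(s) == 0:
        raise FitError("scores are constant")
    X = np.column_stack([np.ones_like(s), s])
    res = logit_fit(X, study.status.astype(float))
    slope, se = res.params[1], res.bse[1]
    return (float(np.exp(slope)),
            (float(np.exp(slope - _Z95 * se)),
             float(np.exp(slope + _Z95 * se))))


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    mean_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    t: float
    df: float
    p_value: float
    significant: bool


def compare_grs_groups(scores_a, scores_b, alpha: float = 0.05 / 3,
                       welch: bool = True) -> GroupComparison:
    """Two-sample t-test on mean GRS between subject groups.

    Welch (unequal variances) by default; the significance flag uses a
    Bonferroni-adjusted threshold of 0.05/3 — the convention for the
    three planned subgroup contrasts (age, sex, subtype).
    """
    a = np.asarray(getattr(scores_a, "values", scores_a), dtype=float)
    b = np.asarray(getattr(scores_b, "values", scores_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two subjects")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    def ci(x):
        half = _Z95 * np.std(x, ddof=1) / np.sqrt(len(x))
        return (float(x.mean() - half), float(x.mean() + half))
    return GroupComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        ci_a=ci(a), ci_b=ci(b),
        t=float(res.statistic), df=float(res.df),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
    )


def model_from_panel_weights(panel: SnpPanel, intercept: float
                             ) -> FittedRiskModel:
    """Build a scoring model from a panel's ``fixed_weight`` entries.

    Lets an external cohort be scored on a previously fitted scale
    without refitting.  Every panel SNP must carry a weight.
    """
    missing = [s.id for s in panel if s.fixed_weight is None]
    if missing:
        raise ValueError(f"panel SNPs lack fixed weights: {missing}")
    return FittedRiskModel(
        intercept=float(intercept),
        betas=np.array([s.fixed_weight for s in panel], dtype=float),
        snp_ids=tuple(panel.ids),
    )
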