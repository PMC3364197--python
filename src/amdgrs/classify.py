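"""Five-category GRS risk classification and exact category odds ratios.

The classification scheme splits the observed GRS range into ``k``
equal-width intervals (five by default).  Intervals are right-closed —
``(-inf, c1], (c1, c2], ..., (c4, inf)`` — so a score landing exactly on
a cut point belongs to the lower category.  Category-versus-reference
odds ratios use conditional maximum likelihood with exact conditional
confidence intervals (Fisher-style, based on the noncentral
hypergeometric distribution), which remains well-behaved in the sparse
top category where a Wald interval would not be.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .errors import ClassificationError
from .model import RiskScoreSet
from .panel import CaseControlStudy

__all__ = [
    "RiskClassification",
    "CategoryTable",
    "CategoryOddsRatio",
    "make_categories",
    "assign_categories",
    "category_table",
    "category_odds_ratios",
    "screening_metrics",
]


@dataclass(frozen=True)
class RiskClassification:
    """Equal-width category boundaries with per-subject labels (1..k)."""

    boundaries: np.ndarray          # k-1 ascending interior cut points
    labels: np.ndarray              # category per subject, 1..k
    observed_range: tuple[float, float]

    @property
    def k(self) -> int:
        return len(self.boundaries) + 1


@dataclass(frozen=True)
class CategoryTable:
    """Per-category case/control counts with arm-wise percentages.

    Counts may be fractional (e.g. reconstructed from published
    percentages); percentages are of each study arm's total.  Explicit
    arm margins can be supplied when the category counts are a rounded
    reconstruction whose sum drifts off the true study margins by a
    count or two; they default to the column sums.
    """

    cases: np.ndarray
    controls: np.ndarray
    strata: dict[str, np.ndarray] | None = None  # extra count rows
    total_cases: float | None = None
    total_controls: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "cases",
                           np.asarray(self.cases, dtype=float))
        object.__setattr__(self, "controls",
                           np.asarray(self.controls, dtype=float))
        if self.cases.shape != self.controls.shape:
            raise ValueError("cases/controls rows differ in length")

    @property
    def k(self) -> int:
        return len(self.cases)

    @property
    def n_cases(self) -> float:
        return float(self.total_cases if self.total_cases is not None
                     else self.cases.sum())

    @property
    def n_controls(self) -> float:
        return float(self.total_controls if self.total_controls is not None
                     else self.controls.sum())

    @property
    def pct_cases(self) -> np.ndarray:
        return 100.0 * self.cases / self.n_cases

    @property
    def pct_controls(self) -> np.ndarray:
        return 100.0 * self.controls / self.n_controls

    def pooled(self, categories) -> tuple[float, float]:
        """(cases, controls) summed over a set of category indices (1-based)."""
        idx = [c - 1 for c in categories]
        return float(self.cases[idx].sum()), float(self.controls[idx].sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "category": np.arange(1, self.k + 1),
            "n_cases": self.cases,
            "n_controls": self.controls,
            "pct_of_cases": self.pct_cases,
            "pct_of_controls": self.pct_controls,
        })
        for name, row in (self.strata or {}).items():
            df[name] = row
        return df


def make_categories(scores: RiskScoreSet, k: int = 5) -> RiskClassification:
    """Split the pooled observed score range into ``k`` equal-width bins.

    Cut points are ``min + w*{1..k-1}`` with ``w = (max-min)/k``; the
    extremes are swallowed by the outer open-ended intervals, so every
    subject is labelled.  Constant scores cannot be classified.
    """
    s = np.asarray(getattr(scores, "values", scores), dtype=float)
    if k < 2:
        raise ClassificationError("need k >= 2 categories")
    lo, hi = float(s.min()), float(s.max())
    if hi == lo:
        raise ClassificationError("scores are constant; no range to split")
    w = (hi - lo) / k
    boundaries = lo + w * np.arange(1, k)
    labels = assign_categories(s, boundaries)
    return RiskClassification(boundaries=boundaries, labels=labels,
                              observed_range=(lo, hi))


def assign_categories(scores, boundaries) -> np.ndarray:
    """Right-closed assignment: category = 1 + #{cut points strictly below}."""
    s = np.asarray(getattr(scores, "values", scores), dtype=float)
    b = np.asarray(boundaries, dtype=float)
    if not (np.diff(b) > 0).all():
        raise ClassificationError("boundaries must be strictly increasing")
    return (1 + (s[:, None] > b[None, :]).sum(axis=1)).astype(np.int64)


def category_table(study: CaseControlStudy,
                   classification: RiskClassification,
                   age_strata: bool = False) -> CategoryTable:
    """Per-category case/control counts for a classified study.

    With ``age_strata=True`` (requires age) extra percentage rows split
    cases into the under-75 and 75-plus age groups.
    """
    labels = classification.labels
    if len(labels) != study.n:
        raise ClassificationError("labels not aligned to study subjects")
    k = classification.k
    case = study.case_mask
    cases = np.array([np.sum(case & (labels == g)) for g in range(1, k + 1)],
                     dtype=float)
    controls = np.array([np.sum(~case & (labels == g))
                         for g in range(1, k + 1)], dtype=float)
    strata = None
    if age_strata:
        if study.age_years is None:
            raise ClassificationError("age strata requested without ages")
        age = np.asarray(study.age_years, dtype=float)
        young = case & (age < 75)
        old = case & (age >= 75)
        strata = {}
        for name, mask in (("pct_cases_under75", young),
                           ("pct_cases_75plus", old)):
            tot = mask.sum()
            counts = np.array([np.sum(mask & (labels == g))
                               for g in range(1, k + 1)], dtype=float)
            strata[name] = 100.0 * counts / tot if tot else counts * np.nan
    return CategoryTable(cases=cases, controls=controls, strata=strata)


@dataclass(frozen=True)
class CategoryOddsRatio:
    category: int
    odds_ratio: float | None      # None for the reference row
    ci95: tuple[float, float] | None
    is_reference: bool = False
    missing: bool = False


def category_odds_ratios(table: CategoryTable, reference: int = 3
                         ) -> list[CategoryOddsRatio]:
    """Odds ratio of each category versus the reference category.

    Each comparison is a 2x2 table (category vs reference; cases vs
    controls) summarised by the conditional maximum-likelihood odds ratio
    with an exact conditional 95% CI.  Sparse cells (even a single
    control) need no continuity correction under exact inference.  A
    category empty of both cases and controls is reported as missing.
    """
    if not (1 <= reference <= table.k):
        raise ValueError(f"reference {reference} outside 1..{table.k}")
    ref_c, ref_u = table.cases[reference - 1], table.controls[reference - 1]
    if ref_c < 1 or ref_u < 1:
        raise ValueError("reference category needs >=1 case and >=1 control")
    out = []
    for g in range(1, table.k + 1):
        if g == reference:
            out.append(CategoryOddsRatio(g, None, None, is_reference=True))
            continue
        a, b = table.cases[g - 1], table.controls[g - 1]
        if a == 0 and b == 0:
            out.append(CategoryOddsRatio(g, None, None, missing=True))
            continue
        tab = np.round([[a, b], [ref_c, ref_u]]).astype(int)
        res = _scipy_odds_ratio(tab, kind="conditional")
        ci = res.confidence_interval(0.95)
        out.append(CategoryOddsRatio(
            g, float(res.statistic), (float(ci.low), float(ci.high))))
    return out


def _clopper_pearson(x: float, n: float, level: float = 0.95
                     ) -> tuple[float, float]:
    """Exact binomial CI (integer-rounded counts)."""
    x, n = int(round(x)), int(round(n))
    a = (1 - level) / 2
    lo = 0.0 if x == 0 else float(beta_dist.ppf(a, x, n - x + 1))
    hi = 1.0 if x == n else float(beta_dist.ppf(1 - a, x + 1, n - x))
    return lo, hi


@dataclass(frozen=True)
class ScreeningMetrics:
    sensitivity: float
    specificity: float
    sensitivity_ci95: tuple[float, float]
    specificity_ci95: tuple[float, float]


def screening_metrics(table: CategoryTable, positive_categories
                      ) -> ScreeningMetrics:
    """Sensitivity/specificity of 'high-risk category' as a screening rule.

    Sensitivity is the fraction of all cases falling in the positive
    categories; specificity the fraction of controls outside them.
    Clopper-Pearson exact 95% intervals.
    """
    pos = set(positive_categories)
    if not pos or not pos <= set(range(1, table.k + 1)):
        raise ValueError(f"positive set must be a non-empty subset of "
                         f"1..{table.k}")
    pos_cases, pos_controls = table.pooled(pos)
    sens = pos_cases / table.n_cases
    spec = (table.n_controls - pos_controls) / table.n_controls
    return ScreeningMetrics(
        sensitivity=float(sens),
        specificity=float(spec),
        sensitivity_ci95=_clopper_pearson(pos_cases, table.n_cases),
        specificity_ci95=_clopper_pearson(table.n_controls - pos_controls,
                                          table.n_controls),
    )
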