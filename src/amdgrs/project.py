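"""Prevalence-weighted projection of a case-control study onto a population.

A case-control sample over-represents cases by design.  To mimic a
general population in which the disease has prevalence ``pi``, case
counts are scaled by the weight

    w = (pi / (1 - pi)) * (N_controls / N_cases)

which is the unique factor making the weighted case fraction equal the
prevalence: ``w N_cases / (w N_cases + N_controls) = pi``.  Applied
within GRS categories this yields the absolute disease risk per category
(the fraction of the modeled population in that category who are cases)
and the category sizes of the modeled population.  Predictive values of
a category-based screening rule follow from the same weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CategoryTable
from .errors import ProjectionError
from .reference import PREVALENCE_BY_AGE_BAND

__all__ = [
    "PopulationProjection",
    "case_weight",
    "absolute_risk_by_category",
    "modeled_population_fractions",
    "predictive_values",
    "project",
    "projection_grid",
    "reweighted_histogram",
]


def case_weight(prevalence: float, n_cases: float, n_controls: float) -> float:
    """Case-count weight making the weighted case fraction equal prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise ProjectionError(f"prevalence {prevalence} outside (0,1)")
    if n_cases <= 0 or n_controls <= 0:
        raise ProjectionError("need positive case and control counts")
    return (prevalence / (1.0 - prevalence)) * (n_controls / n_cases)


def absolute_risk_by_category(table: CategoryTable, prevalence: float
                              ) -> np.ndarray:
    """Absolute disease risk per GRS category at an assumed prevalence.

    ``risk_g = w c_g / (w c_g + u_g)`` with cases ``c_g``, controls
    ``u_g`` and the prevalence weight ``w``.  Categories with no subjects
    at all come back as NaN.
    """
    w = case_weight(prevalence, table.n_cases, table.n_controls)
    wc = w * table.cases
    tot = wc + table.controls
    with np.errstate(invalid="ignore", divide="ignore"):
        risk = np.where(tot > 0, wc / tot, np.nan)
    return risk


def modeled_population_fractions(table: CategoryTable, prevalence: float
                                 ) -> np.ndarray:
    """Fraction of the modeled general population in each GRS category.

    Normalised over the categories, so the fractions sum to one even
    when reconstructed counts drift a subject off the stated margins.
    """
    w = case_weight(prevalence, table.n_cases, table.n_controls)
    num = w * table.cases + table.controls
    return num / num.sum()


def predictive_values(table: CategoryTable, prevalence: float,
                      positive_categories) -> tuple[float, float]:
    """(PPV, NPV) of a positive-category screening rule in the modeled
    population.

    PPV is the weighted case fraction inside the positive categories;
    NPV the weighted control fraction outside them.  With all categories
    positive the PPV equals the prevalence by construction.
    """
    pos = set(positive_categories)
    if not pos or not pos <= set(range(1, table.k + 1)):
        raise ProjectionError("positive set must be a non-empty subset of "
                              f"1..{table.k}")
    w = case_weight(prevalence, table.n_cases, table.n_controls)
    pos_c, pos_u = table.pooled(pos)
    neg_c, neg_u = table.n_cases - pos_c, table.n_controls - pos_u
    ppv = w * pos_c / (w * pos_c + pos_u) if (pos_c + pos_u) > 0 else np.nan
    npv = neg_u / (w * neg_c + neg_u) if (neg_c + neg_u) > 0 else np.nan
    return float(ppv), float(npv)


@dataclass(frozen=True)
class PopulationProjection:
    """Projection of a category table onto one assumed prevalence."""

    prevalence: float
    weight: float
    absolute_risk: np.ndarray
    population_fraction: np.ndarray
    n_cases: float
    n_controls: float


def project(table: CategoryTable, prevalence: float) -> PopulationProjection:
    return PopulationProjection(
        prevalence=prevalence,
        weight=case_weight(prevalence, table.n_cases, table.n_controls),
        absolute_risk=absolute_risk_by_category(table, prevalence),
        population_fraction=modeled_population_fractions(table, prevalence),
        n_cases=table.n_cases,
        n_controls=table.n_controls,
    )


def projection_grid(table: CategoryTable,
                    prevalences: dict[str, float] | None = None
                    ) -> pd.DataFrame:
    """Absolute-risk and population-fraction blocks over a prevalence grid.

    Default grid is the age-band schedule (1% at ages 65-69 up to 15%
    above 85).  Values are percentages.
    """
    if prevalences is None:
        prevalences = PREVALENCE_BY_AGE_BAND
    rows = []
    for label, prev in prevalences.items():
        p = project(table, prev)
        for block, vec in (("absolute_risk_pct", p.absolute_risk),
                           ("population_pct", p.population_fraction)):
            rows.append({"age_band": label, "prevalence": prev,
                         "block": block,
                         **{f"cat{g + 1}": 100.0 * vec[g]
                            for g in range(table.k)}})
    return pd.DataFrame(rows)


def reweighted_histogram(scores, status, prevalence: float,
                         bins: int = 30) -> pd.DataFrame:
    """Case/control GRS histogram with case bins scaled to a prevalence.

    Emits plottable bin data (left edge, right edge, weighted case count,
    control count); rendering is left to the caller.
    """
    s = np.asarray(getattr(scores, "values", scores), dtype=float)
    y = np.asarray(status).astype(bool)
    w = case_weight(prevalence, y.sum(), (~y).sum())
    edges = np.histogram_bin_edges(s, bins=bins)
    case_counts, _ = np.histogram(s[y], bins=edges)
    ctrl_counts, _ = np.histogram(s[~y], bins=edges)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "weighted_cases": w * case_counts,
        "controls": ctrl_counts.astype(float),
    })
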