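"""Published summary statistics of the 13-SNP late-stage AMD panel.

These constants transcribe the printed summary results of a German
(Lower Frankonian) case-control study of late-stage age-related macular
degeneration — 986 cases, 796 controls — on which the genetic risk score
was originally built: per-SNP risk-allele frequencies and single-SNP odds
ratios, within-locus r² between SNPs sharing a locus, the five-category
risk-group composition, and the age-band prevalence schedule used for
absolute-risk projection.  Individual-level genotypes were never
deposited, so these summaries are the only published anchor; the
:mod:`amdgrs.simulate` module generates cohorts matching them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import SnpDefinition, SnpPanel

__all__ = [
    "N_CASES",
    "N_CONTROLS",
    "amd13_panel",
    "CONTROL_FREQS",
    "CASE_FREQS",
    "SINGLE_SNP_OR",
    "WITHIN_LOCUS_R2",
    "PREVALENCE_BY_AGE_BAND",
    "GRS_CUTPOINTS",
    "CATEGORY_PCT_CASES",
    "CATEGORY_PCT_CONTROLS",
    "CATEGORY_PCT_CASES_UNDER75",
    "CATEGORY_PCT_CASES_OVER75",
    "ReferenceCategoryCounts",
    "reconstruct_category_counts",
    "reference_category_table",
]

#: Case-control margins of the source study.
N_CASES = 986
N_CONTROLS = 796

# (rsID, gene label, locus group, risk allele, other allele,
#  control freq, case freq, single-SNP OR, r² with first SNP of locus)
_PANEL_ROWS = [
    ("rs1061170", "CFH", "CFH", "C", "T", 0.365, 0.600, 2.74, None),
    ("rs800292", "CFH", "CFH", "G", "A", 0.761, 0.888, 2.43, 0.150),
    ("rs6677604", "CFH", "CFH", "G", "A", 0.777, 0.884, 2.19, 0.203),
    ("rs10490924", "ARMS2", "ARMS2", "T", "G", 0.189, 0.441, 3.13, None),
    ("rs4151667", "CFB", "CFB", "T", "A", 0.951, 0.982, 2.82, None),
    ("rs438999", "CFB", "CFB", "T", "C", 0.915, 0.962, 2.31, 0.01),
    ("rs2230199", "C3", "C3", "C", "G", 0.175, 0.245, 1.52, None),
    ("rs7412", "APOE", "APOE", "T", "C", 0.079, 0.107, 1.41, None),
    ("rs429358", "APOE", "APOE", "T", "C", 0.881, 0.908, 1.35, 0.783),
    ("rs2285714", "PLA2G12A", "PLA2G12A", "T", "C", 0.409, 0.443, 1.14, None),
    ("rs493258", "LIPC", "LIPC", "C", "T", 0.538, 0.580, 1.18, None),
    ("rs10468017", "LIPC", "LIPC", "C", "T", 0.707, 0.751, 1.26, 0.367),
    ("rs9621532", "SYN3/TIMP3", "TIMP3", "A", "C", 0.960, 0.974, 1.58, None),
]


def amd13_panel() -> SnpPanel:
    """The 13-SNP AMD panel spanning 8 gene loci."""
    return SnpPanel(tuple(
        SnpDefinition(id=r[0], gene_label=r[1], locus_group=r[2],
                      risk_allele=r[3], other_allele=r[4])
        for r in _PANEL_ROWS
    ))


#: Risk-allele frequency in controls, panel order.
CONTROL_FREQS: dict[str, float] = {r[0]: r[5] for r in _PANEL_ROWS}
#: Risk-allele frequency in cases, panel order.
CASE_FREQS: dict[str, float] = {r[0]: r[6] for r in _PANEL_ROWS}
#: Published per-allele odds ratio from single-SNP logistic regression.
SINGLE_SNP_OR: dict[str, float] = {r[0]: r[7] for r in _PANEL_ROWS}
#: r² with the first SNP of the same locus group (None for lead SNPs).
WITHIN_LOCUS_R2: dict[str, float | None] = {r[0]: r[8] for r in _PANEL_ROWS}

#: Late-stage AMD prevalence assumed per age band for absolute-risk
#: projection: 1% at 65-69 up to 15% above 85 years.
PREVALENCE_BY_AGE_BAND: dict[str, float] = {
    "65-69": 0.01,
    "70-74": 0.025,
    "75-79": 0.05,
    "80-84": 0.10,
    ">85": 0.15,
}

#: Published GRS cut points of the five equal-width risk categories.
GRS_CUTPOINTS = (-1.79, -0.05, 1.70, 3.44)

#: Published five-category composition, percent of each study arm.
CATEGORY_PCT_CASES = (0.81, 9.00, 42.5, 39.7, 7.92)
CATEGORY_PCT_CONTROLS = (6.99, 41.7, 43.6, 7.50, 0.13)
CATEGORY_PCT_CASES_UNDER75 = (1.70, 6.20, 34.0, 42.3, 15.8)
CATEGORY_PCT_CASES_OVER75 = (0.54, 9.96, 45.2, 38.9, 5.38)


@dataclass(frozen=True)
class ReferenceCategoryCounts:
    """Per-category case/control counts reconstructed from printed percentages."""

    cases: np.ndarray
    controls: np.ndarray

    @property
    def n_cases(self) -> float:
        return float(self.cases.sum())

    @property
    def n_controls(self) -> float:
        return float(self.controls.sum())


def reconstruct_category_counts(integer: bool = True) -> ReferenceCategoryCounts:
    """Back out per-category counts from the published percentage rows.

    ``counts = pct/100 x margin`` with margins 986 cases / 796 controls,
    rounded to integers by default.  The published per-category sample
    sizes do not reconcile exactly with the percentage rows, so the
    percentages (which carry more digits) are treated as authoritative.
    With ``integer=False`` the fractional products are returned unrounded;
    a few published downstream values are only reproducible under one or
    the other convention, so both are exposed.
    """
    cases = np.array(CATEGORY_PCT_CASES) / 100.0 * N_CASES
    controls = np.array(CATEGORY_PCT_CONTROLS) / 100.0 * N_CONTROLS
    if integer:
        cases = np.round(cases)
        controls = np.round(controls)
    return ReferenceCategoryCounts(cases=cases, controls=controls)


def reference_category_table(integer: bool = True):
    """The published five-category composition as a
    :class:`~amdgrs.classify.CategoryTable`, carrying the true study
    margins (986 / 796) alongside the reconstructed counts."""
    from .classify import CategoryTable

    c = reconstruct_category_counts(integer=integer)
    return CategoryTable(cases=c.cases, controls=c.controls,
                         total_cases=N_CASES, total_controls=N_CONTROLS)
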