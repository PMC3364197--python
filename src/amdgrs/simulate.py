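"""Synthetic case-control cohorts under a logistic disease model.

The generator emulates the structure of the published AMD case-control
study: 13 biallelic SNPs with stated control risk-allele frequencies and
per-allele odds ratios, Hardy-Weinberg genotypes (optionally with
within-locus linkage disequilibrium), disease assigned by a logistic
model whose intercept is calibrated so the *population* prevalence hits a
target, and retrospective sampling of fixed case/control counts by
rejection from that population.

Per-SNP effects multiply on the odds scale: a subject with dosages
``g_1..g_k`` is diseased with probability ``sigmoid(alpha + sum b_i g_i)``
where ``b_i = log OR_i``.  Because sampling is retrospective, logistic
regression on the sampled cohort recovers the ``b_i`` (only the intercept
is shifted) — the classical case-control identifiability result the whole
analysis relies on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import CalibrationError, SimulationError
from .panel import CaseControlStudy, SnpPanel
from .reference import (
    CONTROL_FREQS,
    N_CASES,
    N_CONTROLS,
    SINGLE_SNP_OR,
    WITHIN_LOCUS_R2,
    amd13_panel,
)

__all__ = [
    "SimulationConfig",
    "default_config",
    "calibrate_intercept",
    "expected_case_allele_freq",
    "simulate_cohort",
    "simulate_from_group_freqs",
    "max_feasible_r2",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the population disease model and the sampling design.

    ``freqs`` are population risk-allele frequencies (the published
    control frequencies serve as the default proxy), ``per_allele_or``
    the multiplicative odds ratio per risk allele, both aligned to panel
    order.  ``ld_r2`` optionally maps a non-lead SNP id to a target r²
    with the first SNP of its locus group; loci are independent of each
    other.  A single integer ``seed`` drives all randomness.
    """

    panel: SnpPanel
    freqs: tuple[float, ...]
    per_allele_or: tuple[float, ...]
    target_prevalence: float
    n_cases: int
    n_controls: int
    ld_r2: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.panel)
        if len(self.freqs) != k or len(self.per_allele_or) != k:
            raise ValueError("freqs/per_allele_or must match panel size")
        for f, o in zip(self.freqs, self.per_allele_or):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} outside [0,1]")
            if o != 1.0 and not 0.0 < f < 1.0:
                raise ValueError("SNP with nonzero effect needs freq in (0,1)")
            if not o > 0:
                raise ValueError(f"odds ratio {o} must be positive")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0,1)")
        if self.n_cases < 0 or self.n_controls < 0 or \
                self.n_cases + self.n_controls == 0:
            raise ValueError("need non-negative n_cases/n_controls, not both 0")

    @property
    def betas(self) -> np.ndarray:
        return np.log(np.asarray(self.per_allele_or, dtype=float))


def default_config(seed: int = 0, ld: bool = False,
                   n_cases: int = N_CASES, n_controls: int = N_CONTROLS,
                   target_prevalence: float = 0.15) -> SimulationConfig:
    """Study-matched default: 13-SNP panel at published control frequencies
    and single-SNP odds ratios, 986 cases / 796 controls, prevalence 15%.

    ``ld=True`` additionally couples SNPs within a locus at the published
    r² (clipped to the feasible range for the given allele frequencies;
    positive risk-allele coupling assumed).
    """
    panel = amd13_panel()
    return SimulationConfig(
        panel=panel,
        freqs=tuple(CONTROL_FREQS[s] for s in panel.ids),
        per_allele_or=tuple(SINGLE_SNP_OR[s] for s in panel.ids),
        target_prevalence=target_prevalence,
        n_cases=n_cases,
        n_controls=n_controls,
        ld_r2={s: r for s, r in WITHIN_LOCUS_R2.items() if r is not None}
        if ld else None,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Genotype distribution machinery (exact, block-wise)
# ---------------------------------------------------------------------------

def _hwe_probs(p: float) -> np.ndarray:
    q = 1.0 - p
    return np.array([q * q, 2 * p * q, p * p])


def max_feasible_r2(p_lead: float, p_other: float) -> float:
    """Largest r² a two-locus haplotype model can realise with positive
    coupling of the two risk alleles at the given allele frequencies."""
    d_max = min(p_lead, p_other) - p_lead * p_other
    denom = math.sqrt(p_lead * (1 - p_lead) * p_other * (1 - p_other))
    return (d_max / denom) ** 2 if denom > 0 else 0.0


def _haplotype_blocks(config: SimulationConfig):
    """Partition the panel into independent blocks.

    Each block is ``(snp_indices, hap_alleles, hap_probs)`` where
    ``hap_alleles`` enumerates haplotypes (rows) over the block's SNPs as
    0/1 risk-allele indicators and ``hap_probs`` their frequencies.
    Within a block, non-lead SNPs are coupled to the lead through
    two-locus haplotype frequencies hitting the target r² (conditionally
    independent of each other given the lead allele); unlinked SNPs form
    singleton blocks.
    """
    panel = config.panel
    idx_of = {s: i for i, s in enumerate(panel.ids)}
    ld = config.ld_r2 or {}
    blocks = []
    for locus in panel.locus_groups:
        members = panel.snps_in_locus(locus)
        linked = [s for s in members[1:] if s.id in ld]
        if not linked:
            for s in members:
                i = idx_of[s.id]
                p = config.freqs[i]
                blocks.append(([i], np.array([[0], [1]]),
                               np.array([1 - p, p])))
            continue
        lead = members[0]
        block_snps = [lead] + linked
        loose = [s for s in members[1:] if s.id not in ld]
        for s in loose:
            i = idx_of[s.id]
            p = config.freqs[i]
            blocks.append(([i], np.array([[0], [1]]), np.array([1 - p, p])))
        p_lead = config.freqs[idx_of[lead.id]]
        # conditional P(risk at follower | lead allele) per follower
        cond = []
        for s in linked:
            p_j = config.freqs[idx_of[s.id]]
            r2 = ld[s.id]
            r2_max = max_feasible_r2(p_lead, p_j)
            if r2 > r2_max + 1e-12:
                warnings.warn(
                    f"target r2={r2:.3f} between {lead.id} and {s.id} is "
                    f"infeasible at freqs ({p_lead:.3f}, {p_j:.3f}); "
                    f"clipped to {r2_max:.3f}", stacklevel=3)
                r2 = r2_max
            d = math.sqrt(r2) * math.sqrt(
                p_lead * (1 - p_lead) * p_j * (1 - p_j))
            p11 = p_lead * p_j + d       # risk-risk haplotype
            cond.append((p11 / p_lead if p_lead > 0 else 0.0,
                         (p_j - p11) / (1 - p_lead) if p_lead < 1 else 0.0))
        m = len(block_snps)
        haps = np.array([[(h >> b) & 1 for b in range(m)]
                         for h in range(2 ** m)])
        probs = np.empty(len(haps))
        for hi, h in enumerate(haps):
            pr = p_lead if h[0] else 1 - p_lead
            for j, (p_r, p_nr) in enumerate(cond, start=1):
                given = p_r if h[0] else p_nr
                pr *= given if h[j] else 1 - given
            probs[hi] = pr
        blocks.append(([idx_of[s.id] for s in block_snps], haps, probs))
    return blocks


def _block_genotype_dists(config: SimulationConfig):
    """Exact per-block joint genotype distributions.

    Returns ``(snp_indices, genotypes, probs)`` per block, genotypes being
    all attainable dosage vectors of the block with their probabilities
    (two independent haplotypes per subject).
    """
    out = []
    for idx, haps, hprobs in _haplotype_blocks(config):
        n_h = len(haps)
        geno = {}
        for a in range(n_h):
            for b in range(n_h):
                g = tuple(haps[a] + haps[b])
                geno[g] = geno.get(g, 0.0) + hprobs[a] * hprobs[b]
        keys = sorted(geno)
        out.append((idx, np.array(keys), np.array([geno[k] for k in keys])))
    return out


def _score_distribution(config: SimulationConfig):
    """Exact distribution of the genetic burden ``sum b_i g_i``.

    Built by convolving per-block burden distributions; exact for any
    panel small enough to enumerate (3^k dosage combinations at worst —
    fine for the 13-SNP panel).
    """
    betas = config.betas
    vals = np.zeros(1)
    probs = np.ones(1)
    for idx, geno, gp in _block_genotype_dists(config):
        bvals = geno @ betas[idx]
        vals = (vals[:, None] + bvals[None, :]).ravel()
        probs = (probs[:, None] * gp[None, :]).ravel()
        if vals.size > 4_000_000:  # compact duplicate atoms if huge
            order = np.argsort(vals)
            vals, probs = vals[order], probs[order]
            uniq, inv = np.unique(np.round(vals, 12), return_inverse=True)
            probs = np.bincount(inv, weights=probs)
            vals = uniq
    return vals, probs


def calibrate_intercept(freqs, betas, target_prevalence: float,
                        panel: SnpPanel | None = None,
                        ld_r2: dict[str, float] | None = None) -> float:
    """Solve for the intercept that makes population disease frequency
    equal ``target_prevalence``.

    The mean of ``sigmoid(alpha + sum b_i g_i)`` over the exact genotype
    distribution (HWE per SNP; haplotype blocks if ``ld_r2`` given) is a
    strictly increasing function of ``alpha``; the root is found by Brent
    bracketing to well below 1e-8.
    """
    freqs = tuple(float(f) for f in np.atleast_1d(freqs))
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    if not 0.0 < target_prevalence < 1.0:
        raise CalibrationError("target prevalence must lie in (0,1)")
    if panel is None:
        panel = _anonymous_panel(len(freqs))
    cfg = SimulationConfig(panel=panel, freqs=freqs,
                           per_allele_or=tuple(np.exp(betas)),
                           target_prevalence=target_prevalence,
                           n_cases=1, n_controls=1, ld_r2=ld_r2)
    vals, probs = _score_distribution(cfg)

    def mean_prev(alpha: float) -> float:
        return float(probs @ expit(alpha + vals))

    lo, hi = -745.0, 745.0
    if not mean_prev(lo) < target_prevalence < mean_prev(hi):
        raise CalibrationError("prevalence not bracketable for these inputs")
    return float(brentq(lambda a: mean_prev(a) - target_prevalence,
                        lo, hi, xtol=1e-12, rtol=8.9e-16))


def _anonymous_panel(k: int) -> SnpPanel:
    from .panel import SnpDefinition
    return SnpPanel(tuple(
        SnpDefinition(id=f"snp{i + 1}", gene_label=f"L{i + 1}",
                      locus_group=f"L{i + 1}", risk_allele="A",
                      other_allele="G")
        for i in range(k)
    ))


def expected_case_allele_freq(pop_freq: float, or_: float,
                              intercept: float) -> float:
    """Expected risk-allele frequency among cases for one SNP.

    Three-term enumeration of ``P(g | case) ∝ HWE(g) * sigmoid(a + b g)``;
    in the rare-disease limit this reduces to ``HWE(g) * OR^g``.  Serves
    as the analytic oracle for simulated case frequencies.
    """
    if not 0.0 <= pop_freq <= 1.0 or not or_ > 0:
        raise ValueError("need pop_freq in [0,1] and positive odds ratio")
    g = np.arange(3)
    w = _hwe_probs(pop_freq) * expit(intercept + math.log(or_) * g)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("degenerate posterior: intercept too extreme")
    return float((g * w).sum() / (2 * tot))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _draw_genotypes(config: SimulationConfig, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    k = len(config.panel)
    G = np.empty((n, k), dtype=np.int8)
    for idx, haps, hprobs in _haplotype_blocks(config):
        choice = rng.choice(len(haps), size=(n, 2), p=hprobs / hprobs.sum())
        G[:, idx] = haps[choice[:, 0]] + haps[choice[:, 1]]
    return G


_CALIBRATION_CACHE: dict[tuple, float] = {}


def _cached_intercept(config: SimulationConfig) -> float:
    """Intercept for a config, cached on the disease-model parameters.

    Replicate simulations differing only in seed or sample sizes share
    one calibration (the intercept depends on neither).
    """
    key = (config.freqs, config.per_allele_or, config.target_prevalence,
           None if config.ld_r2 is None
           else tuple(sorted(config.ld_r2.items())),
           tuple(config.panel.ids),
           tuple(s.locus_group for s in config.panel))
    if key not in _CALIBRATION_CACHE:
        _CALIBRATION_CACHE[key] = calibrate_intercept(
            config.freqs, config.betas, config.target_prevalence,
            panel=config.panel, ld_r2=config.ld_r2)
    return _CALIBRATION_CACHE[key]


def simulate_cohort(config: SimulationConfig) -> CaseControlStudy:
    """Draw a retrospective case-control cohort from the population model.

    Subjects are sampled from the calibrated population in batches and
    kept until exactly ``n_cases`` cases and ``n_controls`` controls are
    collected (rejection sampling — exact under any LD structure).
    Deterministic given ``config.seed``.
    """
    alpha = _cached_intercept(config)
    rng = np.random.default_rng(config.seed)
    prev = config.target_prevalence
    expected_draws = max(config.n_cases / prev,
                         config.n_controls / (1.0 - prev))
    if expected_draws > 5e7:
        raise SimulationError(
            f"target composition needs ~{expected_draws:.0f} population "
            "draws; refusing (prevalence too extreme for requested counts)")
    max_draws = int(20 * expected_draws + 10_000)
    betas = config.betas

    rows, statuses = [], []
    need_cases, need_controls = config.n_cases, config.n_controls
    drawn = 0
    batch = int(min(max(2048, expected_draws * 1.1), 500_000))
    while need_cases > 0 or need_controls > 0:
        if drawn >= max_draws:
            raise SimulationError(
                f"could not reach {config.n_cases}/{config.n_controls} "
                f"cases/controls within {max_draws} draws")
        G = _draw_genotypes(config, batch, rng)
        y = rng.random(batch) < expit(alpha + G @ betas)
        drawn += batch
        for i in range(batch):
            if y[i] and need_cases > 0:
                rows.append(G[i])
                statuses.append(1)
                need_cases -= 1
            elif not y[i] and need_controls > 0:
                rows.append(G[i])
                statuses.append(0)
                need_controls -= 1
            if need_cases == 0 and need_controls == 0:
                break

    dosage = pd.DataFrame(np.array(rows, dtype=np.int8),
                          columns=config.panel.ids)
    n = len(rows)
    return CaseControlStudy(
        subjects=[f"S{i + 1:06d}" for i in range(n)],
        status=np.array(statuses, dtype=np.int8),
        dosage=dosage,
    )


def simulate_from_group_freqs(case_freqs, control_freqs,
                              n_cases: int, n_controls: int, seed: int,
                              snp_ids: list[str] | None = None
                              ) -> CaseControlStudy:
    """Draw cases and controls directly from group-specific HWE frequencies.

    Each group's genotypes are independent binomial(2, freq) draws per
    SNP — the distribution implied by per-group risk-allele frequencies
    under HWE.  Mirrors published two-column frequency summaries without a
    disease model; useful for AUC enumeration checks.
    """
    case_freqs = np.atleast_1d(np.asarray(case_freqs, dtype=float))
    control_freqs = np.atleast_1d(np.asarray(control_freqs, dtype=float))
    if case_freqs.shape != control_freqs.shape:
        raise ValueError("case/control frequency vectors differ in length")
    if ((case_freqs < 0) | (case_freqs > 1) |
            (control_freqs < 0) | (control_freqs > 1)).any():
        raise ValueError("frequencies must lie in [0,1]")
    if n_cases <= 0 or n_controls <= 0:
        raise SimulationError("need at least one case and one control")
    k = len(case_freqs)
    ids = snp_ids if snp_ids is not None else [f"snp{i + 1}" for i in range(k)]
    rng = np.random.default_rng(seed)
    g_case = rng.binomial(2, case_freqs, size=(n_cases, k))
    g_ctrl = rng.binomial(2, control_freqs, size=(n_controls, k))
    dosage = pd.DataFrame(np.vstack([g_case, g_ctrl]).astype(np.int8),
                          columns=ids)
    status = np.concatenate([np.ones(n_cases, dtype=np.int8),
                             np.zeros(n_controls, dtype=np.int8)])
    return CaseControlStudy(
        subjects=[f"S{i + 1:06d}" for i in range(n_cases + n_controls)],
        status=status,
        dosage=dosage,
    )
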