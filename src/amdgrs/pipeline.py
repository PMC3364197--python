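"""One-call pipeline: cohort in, full report bundle out.

Runs the whole analysis chain — per-SNP association, joint model and
GRS, five-category risk classification with exact odds ratios,
prevalence-weighted population projection, cross-validation and the
parsimonious backward search — and writes every stage as a
tab-separated report plus a JSON run manifest.  The bundle is
byte-reproducible given the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import association_frame, association_table
from .classify import (CategoryTable, category_odds_ratios, category_table,
                       make_categories, screening_metrics)
from .model import fit_joint_model, grs_for_study, mcfadden_r2, or_per_grs_unit
from .panel import CaseControlStudy, SnpPanel, load_panel, read_genotype_table
from .project import projection_grid
from .reference import PREVALENCE_BY_AGE_BAND, amd13_panel
from .simulate import SimulationConfig, default_config, simulate_cohort
from .validation import cross_validate, parsimonious_search, roc_auc

logger = logging.getLogger("amdgrs")

__all__ = ["PipelineConfig", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class PipelineConfig:
    """Input source, analysis settings and output location for one run.

    Exactly one of ``genotype_table`` (with ``panel_path``) or
    ``simulate`` may be set.
    """

    output_dir: str
    genotype_table: str | None = None
    panel_path: str | None = None
    simulate: SimulationConfig | None = None
    prevalences: dict[str, float] = field(
        default_factory=lambda: dict(PREVALENCE_BY_AGE_BAND))
    n_categories: int = 5
    cv_repeats: int = 2000
    cv_train_fraction: float = 2 / 3
    seed: int = 0

    def __post_init__(self):
        if (self.genotype_table is None) == (self.simulate is None):
            raise ValueError("set exactly one input source: genotype_table "
                             "or simulate")
        for v in self.prevalences.values():
            if not 0.0 < v < 1.0:
                raise ValueError(f"prevalence {v} outside (0,1)")

    def to_dict(self) -> dict:
        # output_dir is deliberately omitted: the manifest describes the
        # analysis, and a rerun into another directory must be identical
        d = {
            "genotype_table": self.genotype_table,
            "panel_path": self.panel_path,
            "prevalences": self.prevalences,
            "n_categories": self.n_categories,
            "cv_repeats": self.cv_repeats,
            "cv_train_fraction": self.cv_train_fraction,
            "seed": self.seed,
        }
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            sim["panel"] = [dataclasses.asdict(s) for s in self.simulate.panel]
            d["simulate"] = sim
        return d


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
              lineterminator="\n")


def _load_input(config: PipelineConfig) -> tuple[CaseControlStudy, SnpPanel]:
    if config.simulate is not None:
        logger.info("simulating cohort (seed=%d)", config.simulate.seed)
        return simulate_cohort(config.simulate), config.simulate.panel
    panel = load_panel(config.panel_path) if config.panel_path else \
        amd13_panel()
    logger.info("reading genotype table %s", config.genotype_table)
    return read_genotype_table(config.genotype_table, panel), panel


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every analysis stage and write the report bundle.

    Returns a mapping of report name to written path.  Any stage error
    propagates after a failure marker is written, leaving completed
    reports in place.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    t0 = time.time()
    try:
        study, panel = _load_input(config)
        logger.info("cohort: %d cases / %d controls, %d SNPs",
                    study.n_cases, study.n_controls, len(panel))

        # --- per-SNP association -------------------------------------
        assoc = association_table(study, panel)
        for r in assoc:
            if r.hwe_p_controls == r.hwe_p_controls and \
                    r.hwe_p_controls < 0.05:
                logger.warning("HWE violation in controls at %s (p=%.3g)",
                               r.snp_id, r.hwe_p_controls)
        path = out / "association.tsv"
        _write_tsv(association_frame(assoc), path)
        written["association"] = path

        # --- joint model + GRS ---------------------------------------
        model = fit_joint_model(study, panel)
        scores = grs_for_study(model, study)
        ors = model.odds_ratios()
        ci = model.or_ci95()
        mdf = pd.DataFrame({
            "term": ["intercept", *model.snp_ids],
            "log_odds": [model.intercept, *model.betas],
            "odds_ratio": [np.nan, *ors],
            "ci95_low": [np.nan, *ci[:, 0]],
            "ci95_high": [np.nan, *ci[:, 1]],
        })
        path = out / "model.tsv"
        _write_tsv(mdf, path)
        written["model"] = path
        grs_or, grs_ci = or_per_grs_unit(study, scores)
        r2 = mcfadden_r2(model, study)
        auc = roc_auc(scores, study.status)
        logger.info("in-sample AUC %.3f, McFadden R2 %.4f, OR/GRS-unit %.3f",
                    auc, r2, grs_or)

        # --- classification ------------------------------------------
        classification = make_categories(scores, config.n_categories)
        table = category_table(study, classification,
                               age_strata=study.age_years is not None)
        odds = category_odds_ratios(
            table, reference=(config.n_categories + 1) // 2)
        sparse = [o.category for o in odds
                  if not o.is_reference and not o.missing
                  and min(table.cases[o.category - 1],
                          table.controls[o.category - 1]) < 5]
        if sparse:
            logger.warning("sparse cells in categories %s; exact intervals "
                           "reported", sparse)
        cdf = table.to_frame()
        cdf["boundary_low"] = [-np.inf, *classification.boundaries]
        cdf["boundary_high"] = [*classification.boundaries, np.inf]
        cdf["odds_ratio"] = [o.odds_ratio if o.odds_ratio is not None
                             else np.nan for o in odds]
        cdf["or_ci95_low"] = [o.ci95[0] if o.ci95 else np.nan for o in odds]
        cdf["or_ci95_high"] = [o.ci95[1] if o.ci95 else np.nan for o in odds]
        cdf["reference"] = [o.is_reference for o in odds]
        path = out / "classification.tsv"
        _write_tsv(cdf, path)
        written["classification"] = path
        top = screening_metrics(table, {config.n_categories})
        logger.info("top-category screening: sensitivity %.1f%%, "
                    "specificity %.1f%%", 100 * top.sensitivity,
                    100 * top.specificity)

        # --- population projection -----------------------------------
        path = out / "projection.tsv"
        _write_tsv(projection_grid(table, config.prevalences), path)
        written["projection"] = path

        # --- cross-validation ----------------------------------------
        cv = cross_validate(study, panel, n_repeats=config.cv_repeats,
                            train_fraction=config.cv_train_fraction,
                            seed=config.seed)
        cvdf = pd.DataFrame([{
            "n_repeats": cv.n_repeats,
            "train_fraction": cv.train_fraction,
            "mean_auc": cv.mean_auc,
            "ci95_low": cv.ci95[0],
            "ci95_high": cv.ci95[1],
            "n_skipped": cv.n_skipped,
            "in_sample_auc": auc,
        }])
        path = out / "cross_validation.tsv"
        _write_tsv(cvdf, path)
        written["cross_validation"] = path

        # --- parsimonious search -------------------------------------
        steps, best = parsimonious_search(study, panel)
        sdf = pd.DataFrame([{
            "dropped_locus": s.dropped_locus or "",
            "n_snps": len(s.retained_snps),
            "retained_snps": ",".join(s.retained_snps),
            "auc": s.auc,
            "mcfadden_r2": s.mcfadden_r2,
            "is_smallest_equivalent": s is best,
        } for s in steps])
        path = out / "parsimonious.tsv"
        _write_tsv(sdf, path)
        written["parsimonious"] = path

        # --- manifest ------------------------------------------------
        cfg_json = json.dumps(config.to_dict(), sort_keys=True)
        manifest = {
            "package": "amdgrs",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "n_cases": study.n_cases,
            "n_controls": study.n_controls,
            "n_snps": len(panel),
            "reports": sorted(written),
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written["manifest"] = path
        logger.info("pipeline finished in %.1fs; %d reports in %s",
                    time.time() - t0, len(written), out)
        return written
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    A ``simulate`` block may either give full simulation parameters or
    ``defaults: true`` with optional overrides of the study-matched
    default config.
    """
    raw = yaml.safe_load(Path(path).read_text())
    sim = None
    if "simulate" in raw:
        blk = dict(raw.pop("simulate"))
        seed = int(blk.pop("seed", raw.get("seed", 0)))
        if blk.pop("defaults", True):
            sim = default_config(
                seed=seed,
                ld=bool(blk.pop("ld", False)),
                n_cases=int(blk.pop("n_cases", 986)),
                n_controls=int(blk.pop("n_controls", 796)),
                target_prevalence=float(blk.pop("target_prevalence", 0.15)),
            )
        else:
            panel = load_panel(blk.pop("panel"))
            sim = SimulationConfig(panel=panel, seed=seed, **blk)
    return PipelineConfig(simulate=sim, **raw)
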