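"""SNP panel definitions and genotype-dosage study I/O.

A *panel* fixes the set of variants a risk model is built on: for each SNP
its rsID, the gene it annotates, a locus group (SNPs in linkage
disequilibrium at one locus share a group), and the orientation of the
risk allele.  Dosages everywhere in this package count the **risk** allele
(0, 1 or 2 copies), not the minor allele; the panel file is the single
source of orientation truth.

A *case-control study* is a subjects x SNPs dosage matrix with disease
status and optional age / sex / late-stage subtype annotations.  Studies
are read and written as plain tab-separated text so that cohorts are
diff-able and round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, PanelFormatError, SchemaError

__all__ = [
    "SnpDefinition",
    "SnpPanel",
    "CaseControlStudy",
    "load_panel",
    "save_panel",
    "read_genotype_table",
    "write_genotype_table",
    "dosages_from_vcf",
]

#: Valid late-stage AMD subtype labels for cases: geographic atrophy,
#: neovascular disease, or both forms ("mixed").
SUBTYPES = ("GA", "NV", "mixed")

_SEXES = ("M", "F")


@dataclass(frozen=True)
class SnpDefinition:
    """One panel variant: identity, locus membership and allele orientation."""

    id: str
    gene_label: str
    locus_group: str
    risk_allele: str
    other_allele: str
    fixed_weight: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise PanelFormatError("SNP id must be non-empty")
        if self.risk_allele == self.other_allele:
            raise PanelFormatError(
                f"SNP {self.id!r}: risk_allele equals other_allele "
                f"({self.risk_allele!r})"
            )


@dataclass(frozen=True)
class SnpPanel:
    """Ordered collection of :class:`SnpDefinition` with unique ids."""

    snps: tuple[SnpDefinition, ...]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.snps]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PanelFormatError(f"duplicate SNP ids in panel: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.snps]

    @property
    def locus_groups(self) -> list[str]:
        """Locus group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.snps:
            seen.setdefault(s.locus_group, None)
        return list(seen)

    def snps_in_locus(self, locus_group: str) -> list[SnpDefinition]:
        return [s for s in self.snps if s.locus_group == locus_group]

    def subset(self, ids: Iterable[str]) -> "SnpPanel":
        """Panel restricted to ``ids`` (panel order preserved)."""
        keep = set(ids)
        missing = keep - set(self.ids)
        if missing:
            raise KeyError(f"ids not in panel: {sorted(missing)}")
        return SnpPanel(tuple(s for s in self.snps if s.id in keep))

    def with_weights(self, weights: dict[str, float]) -> "SnpPanel":
        """Return a copy carrying ``fixed_weight`` (log-odds) per SNP."""
        return SnpPanel(
            tuple(replace(s, fixed_weight=weights.get(s.id, s.fixed_weight))
                  for s in self.snps)
        )


@dataclass
class CaseControlStudy:
    """Subjects x SNPs risk-allele dosage matrix with case/control status.

    ``dosage`` is a DataFrame indexed by subject id with one column per
    panel SNP; every cell is 0, 1 or 2.  ``status`` is an int8 array
    aligned to subjects, 1 for cases and 0 for controls.  Covariates are
    optional; ``subtype`` may only be set for cases.
    """

    subjects: list[str]
    status: np.ndarray
    dosage: pd.DataFrame
    age_years: np.ndarray | None = None
    sex: np.ndarray | None = None
    subtype: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        n = len(self.subjects)
        if self.status.shape != (n,):
            raise DataError(f"status length {self.status.shape} != {n} subjects")
        if self.dosage.shape[0] != n:
            raise DataError("dosage row count does not match subjects")
        vals = self.dosage.to_numpy()
        if vals.size and not np.isin(vals, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(vals, (0, 1, 2)))[0]
            raise DataError(
                f"dosage value {vals[tuple(bad)]!r} outside {{0,1,2}} at "
                f"subject {self.subjects[bad[0]]!r}, "
                f"SNP {self.dosage.columns[bad[1]]!r}"
            )
        self.dosage = self.dosage.astype(np.int8)
        self.dosage.index = pd.Index(self.subjects, name="subject_id")
        for name in ("age_years", "sex", "subtype"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise DataError(f"{name} length does not match subjects")
        if self.subtype is not None:
            for st, flag in zip(self.subtype, self.status):
                if st is not None and not flag:
                    raise DataError("subtype set for a control subject")
                if st is not None and st not in SUBTYPES:
                    raise DataError(f"unknown subtype {st!r}")

    # -- convenience -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.status).sum())

    @property
    def case_mask(self) -> np.ndarray:
        return self.status == 1

    def subset(self, mask: np.ndarray) -> "CaseControlStudy":
        """Study restricted to subjects where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        pick = lambda a: None if a is None else np.asarray(a, dtype=object)[idx]
        return CaseControlStudy(
            subjects=[self.subjects[i] for i in idx],
            status=self.status[idx],
            dosage=self.dosage.iloc[idx].copy(),
            age_years=None if self.age_years is None
            else np.asarray(self.age_years, dtype=float)[idx],
            sex=pick(self.sex),
            subtype=pick(self.subtype),
        )


# ---------------------------------------------------------------------------
# Panel config I/O (YAML or JSON)
# ---------------------------------------------------------------------------

_REQUIRED_SNP_KEYS = ("id", "gene", "locus", "risk_allele", "other_allele")


def load_panel(path: str | Path) -> SnpPanel:
    """Read a SNP panel config (YAML or JSON).

    The file holds a top-level ``snps`` list; each record needs ``id``,
    ``gene``, ``locus``, ``risk_allele`` and ``other_allele``, and may carry
    an optional ``weight`` (a fixed log-odds coefficient for scoring new
    cohorts without refitting).  File order is preserved.
    """
    path = Path(path)
    try:
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (OSError, ValueError, yaml.YAMLError) as exc:
        raise PanelFormatError(f"cannot parse panel file {path}: {exc}") from exc
    if not isinstance(raw, dict) or "snps" not in raw:
        raise PanelFormatError(f"{path}: expected a mapping with a 'snps' list")
    snps = []
    for i, rec in enumerate(raw["snps"]):
        missing = [k for k in _REQUIRED_SNP_KEYS if k not in rec]
        if missing:
            raise PanelFormatError(
                f"{path}: snp record {i} ({rec.get('id', '<no id>')!r}) "
                f"missing fields {missing}"
            )
        snps.append(
            SnpDefinition(
                id=str(rec["id"]),
                gene_label=str(rec["gene"]),
                locus_group=str(rec["locus"]),
                risk_allele=str(rec["risk_allele"]),
                other_allele=str(rec["other_allele"]),
                fixed_weight=None if rec.get("weight") is None
                else float(rec["weight"]),
            )
        )
    return SnpPanel(tuple(snps))


def save_panel(panel: SnpPanel, path: str | Path) -> None:
    """Write a panel back to YAML in the dialect accepted by load_panel."""
    recs = []
    for s in panel:
        rec: dict = {
            "id": s.id,
            "gene": s.gene_label,
            "locus": s.locus_group,
            "risk_allele": s.risk_allele,
            "other_allele": s.other_allele,
        }
        if s.fixed_weight is not None:
            rec["weight"] = float(s.fixed_weight)
        recs.append(rec)
    Path(path).write_text(yaml.safe_dump({"snps": recs}, sort_keys=False))


# ---------------------------------------------------------------------------
# Genotype-dosage table I/O (TSV)
# ---------------------------------------------------------------------------

_MANDATORY_COLS = ("subject_id", "status")
_OPTIONAL_COLS = ("age", "sex", "subtype")


def read_genotype_table(path: str | Path, panel: SnpPanel) -> CaseControlStudy:
    """Load a tab-separated dosage table against a panel.

    Required columns: ``subject_id``, ``status`` (case/control) and one
    column per panel SNP holding the risk-allele dosage (0/1/2, no
    missing values).  Optional columns ``age``, ``sex`` (M/F) and
    ``subtype`` (cases only) are captured when present.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_COLS if c not in df.columns]
    missing += [s for s in panel.ids if s not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    subjects = df["subject_id"].tolist()
    status = np.empty(len(df), dtype=np.int8)
    for i, s in enumerate(df["status"]):
        if s == "case":
            status[i] = 1
        elif s == "control":
            status[i] = 0
        else:
            raise DataError(f"{path}: row {i}: status {s!r} not case/control")

    dosage = np.empty((len(df), len(panel)), dtype=np.int8)
    for j, snp in enumerate(panel.ids):
        col = df[snp]
        for i, cell in enumerate(col):
            if cell not in ("0", "1", "2"):
                raise DataError(
                    f"{path}: row {i}, SNP {snp}: dosage {cell!r} "
                    "outside {0,1,2}"
                )
            dosage[i, j] = int(cell)

    def _opt(name: str):
        if name not in df.columns:
            return None
        return df[name].tolist()

    age = _opt("age")
    if age is not None:
        age = np.array([float(a) if a != "" else np.nan for a in age])
    sex = _opt("sex")
    if sex is not None:
        for i, s in enumerate(sex):
            if s not in _SEXES and s != "":
                raise DataError(f"{path}: row {i}: sex {s!r} not M/F")
        sex = np.array([s if s else None for s in sex], dtype=object)
    subtype = _opt("subtype")
    if subtype is not None:
        subtype = np.array([s if s else None for s in subtype], dtype=object)

    return CaseControlStudy(
        subjects=subjects,
        status=status,
        dosage=pd.DataFrame(dosage, columns=panel.ids),
        age_years=age,
        sex=sex,
        subtype=subtype,
    )


def write_genotype_table(study: CaseControlStudy, path: str | Path) -> None:
    """Write the TSV dialect accepted by :func:`read_genotype_table`.

    Optional covariate columns are emitted only when present on the study,
    so read∘write is the identity on all fields and a second write of a
    re-read file is byte-identical.
    """
    cols: dict[str, list] = {
        "subject_id": list(study.subjects),
        "status": ["case" if s else "control" for s in study.status],
    }
    if study.age_years is not None:
        cols["age"] = [
            "" if np.isnan(a) else (str(int(a)) if float(a).is_integer()
                                    else repr(float(a)))
            for a in study.age_years
        ]
    if study.sex is not None:
        cols["sex"] = ["" if s is None else s for s in study.sex]
    if study.subtype is not None:
        cols["subtype"] = ["" if s is None else s for s in study.subtype]
    for snp in study.dosage.columns:
        cols[snp] = [str(int(v)) for v in study.dosage[snp]]
    header = "\t".join(cols)
    lines = [header]
    for row in zip(*cols.values()):
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Optional VCF import
# ---------------------------------------------------------------------------

def dosages_from_vcf(path: str | Path, panel: SnpPanel) -> pd.DataFrame:
    """Extract risk-allele dosages for panel SNPs from a VCF.

    Records are matched by ID.  Multi-allelic records and missing
    genotypes are rejected; the panel's risk/other alleles must match the
    record's REF/ALT pair (in either orientation).  Coordinates are not
    used.  Requires :mod:`cyvcf2`.
    """
    from cyvcf2 import VCF  # local import: optional dependency

    wanted = {s.id: s for s in panel}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    found: dict[str, np.ndarray] = {}
    for rec in vcf:
        snp = wanted.get(rec.ID)
        if snp is None:
            continue
        if len(rec.ALT) != 1:
            raise DataError(f"{rec.ID}: multi-allelic record not supported")
        alleles = {rec.REF, rec.ALT[0]}
        if alleles != {snp.risk_allele, snp.other_allele}:
            raise DataError(
                f"{rec.ID}: VCF alleles {sorted(alleles)} do not match panel "
                f"({snp.risk_allele}/{snp.other_allele})"
            )
        risk_is_alt = snp.risk_allele == rec.ALT[0]
        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        dos = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                raise DataError(f"{rec.ID}: missing genotype for {samples[i]}")
            alt_count = int(a == 1) + int(b == 1)
            dos[i] = alt_count if risk_is_alt else 2 - alt_count
        found[rec.ID] = dos
    missing = [s for s in panel.ids if s not in found]
    if missing:
        raise SchemaError(f"VCF lacks panel SNPs {missing}")
    return pd.DataFrame({s: found[s] for s in panel.ids},
                        index=pd.Index(samples, name="subject_id"))
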