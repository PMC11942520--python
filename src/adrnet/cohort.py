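"""Cohort ingestion: patient VCFs -> binary carrier matrix; clinical table I/O.

Genotypes are collapsed to carrier status by default (1 if the patient has
at least one alternate allele at the panel site, dominant coding); an
additive 0/1/2 coding is available via ``genotype_coding="additive"``.
Missing calls (``./.``) count as non-carrier but are tracked in a parallel
missing mask, and patients with a high missing fraction can be flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import format_percentage
from .panel import PanelManifest

__all__ = [
    "GenotypeMatrix",
    "ClinicalTable",
    "QCReport",
    "TREATMENTS",
    "ADR_CATEGORIES",
    "read_cohort_vcf",
    "qc_summary",
    "summarize_clinical",
    "flag_high_missingness",
]

log = logging.getLogger(__name__)

TREATMENTS = ("cisplatin", "carboplatin", "pemetrexed", "radiotherapy", "other")
ADR_CATEGORIES = ("hematologic", "gastrointestinal", "asthenia", "skin", "pain", "dyspnea")

CLINICAL_COLUMNS = ["patient_id", "age", "sex", "stage", "treatments", "adr_any", "adr_categories"]


@dataclass
class GenotypeMatrix:
    """Patients x panel-variants matrix.

    ``carrier`` holds 0/1 (or 0/1/2 under additive coding); ``missing_mask``
    is 1 where the site had no call.  Missing sites always have carrier 0.
    Column order equals panel order.
    """

    patient_ids: list
    variant_ids: list
    carrier: np.ndarray
    missing_mask: np.ndarray
    coding: str = "carrier"

    def __post_init__(self):
        self.carrier = np.asarray(self.carrier, dtype=np.int8)
        self.missing_mask = np.asarray(self.missing_mask, dtype=np.int8)
        if self.carrier.shape != (len(self.patient_ids), len(self.variant_ids)):
            raise ValueError("carrier shape does not match ids")
        if self.missing_mask.shape != self.carrier.shape:
            raise ValueError("missing_mask shape does not match carrier")
        if np.any(self.carrier[self.missing_mask == 1] != 0):
            raise ValueError("missing sites must have carrier 0")

    @property
    def shape(self):
        return self.carrier.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.carrier, index=self.patient_ids, columns=self.variant_ids)

    def to_tsv(self, path) -> None:
        """Write a wide TSV; missing cells are encoded as ``.``."""
        values = self.carrier.astype(object)
        values[self.missing_mask == 1] = "."
        df = pd.DataFrame(values, index=self.patient_ids, columns=self.variant_ids)
        df.index.name = "patient_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, coding: str = "carrier") -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        raw = df.to_numpy()
        missing = (raw == ".").astype(np.int8)
        carrier = np.where(raw == ".", "0", raw).astype(np.int8)
        return cls(
            patient_ids=list(df.index),
            variant_ids=list(df.columns),
            carrier=carrier,
            missing_mask=missing,
            coding=coding,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.patient_ids == other.patient_ids
            and self.variant_ids == other.variant_ids
            and np.array_equal(self.carrier, other.carrier)
            and np.array_equal(self.missing_mask, other.missing_mask)
        )


@dataclass
class ClinicalTable:
    """Per-patient clinical record: demographics, treatments, ADR outcomes.

    ``treatments`` and ``adr_categories`` are stored as tuples per patient.
    ``adr_any`` must be true whenever ``adr_categories`` is non-empty (a
    patient can also be flagged with an ADR without a recorded category).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.df
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing column(s): {', '.join(missing)}")
        if df["patient_id"].duplicated().any():
            dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
            raise ValueError(f"duplicate patient id(s): {dups}")
        bad = df[(df["adr_categories"].map(len) > 0) & (~df["adr_any"])]
        if len(bad):
            raise ValueError(
                "adr_any is false but adr_categories non-empty for: "
                + ", ".join(bad["patient_id"])
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def patient_ids(self) -> list:
        return list(self.df["patient_id"])

    def treated_ids(self, treatments) -> set:
        """Patients who received any of the given treatment(s)."""
        if isinstance(treatments, str):
            treatments = (treatments,)
        wanted = set(treatments)
        mask = self.df["treatments"].map(lambda ts: bool(wanted & set(ts)))
        return set(self.df.loc[mask, "patient_id"])

    def adr_ids(self) -> set:
        return set(self.df.loc[self.df["adr_any"], "patient_id"])

    def observed_treatments(self) -> list:
        seen = []
        for ts in self.df["treatments"]:
            for t in ts:
                if t not in seen:
                    seen.append(t)
        return seen

    @classmethod
    def from_records(cls, records) -> "ClinicalTable":
        df = pd.DataFrame(records, columns=CLINICAL_COLUMNS)
        df["treatments"] = df["treatments"].map(tuple)
        df["adr_categories"] = df["adr_categories"].map(tuple)
        df["adr_any"] = df["adr_any"].astype(bool)
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "ClinicalTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
        df["age"] = df["age"].astype(float)
        df["treatments"] = df["treatments"].map(
            lambda s: tuple(t for t in s.split(";") if t)
        )
        df["adr_categories"] = df["adr_categories"].map(
            lambda s: tuple(t for t in s.split(";") if t)
        )
        df["adr_any"] = df["adr_any"].map(lambda s: s.strip().lower() in {"1", "true", "yes"})
        return cls(df[CLINICAL_COLUMNS])

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out["treatments"] = out["treatments"].map(";".join)
        out["adr_categories"] = out["adr_categories"].map(";".join)
        out["adr_any"] = out["adr_any"].astype(int)
        out.to_csv(path, index=False)


@dataclass
class QCReport:
    n_snv: int
    n_indel: int
    per_chromosome: dict
    n_x_chrom: int

    def to_dict(self) -> dict:
        return {
            "n_snv": self.n_snv,
            "n_indel": self.n_indel,
            "per_chromosome": dict(self.per_chromosome),
            "n_x_chrom": self.n_x_chrom,
        }


def _norm_chrom(c: str) -> str:
    return str(c).removeprefix("chr")


def read_cohort_vcf(paths, panel: PanelManifest, genotype_coding: str = "carrier") -> GenotypeMatrix:
    """Build the carrier matrix from one or more VCF files.

    One matrix row per sample, one column per panel variant in panel order.
    Sites are matched by (chrom, pos, ref, alt) and, failing that, by rsid.
    Multi-allelic records are decomposed: only the panel's alt allele is
    matched.  Panel sites with no record (or ``./.``) in a sample's VCF are
    non-carrier with the missing mask set.  Variants in a VCF that are not
    in the panel are ignored.
    """
    from cyvcf2 import VCF

    if genotype_coding not in {"carrier", "additive"}:
        raise ValueError(f"unknown genotype coding {genotype_coding!r}")

    by_locus = {}
    by_rsid = {}
    for col, v in enumerate(panel):
        by_locus[(v.chrom, v.pos, v.ref, v.alt)] = col
        by_rsid[v.rsid] = col
    n_var = len(panel)

    patient_ids: list[str] = []
    rows: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for path in paths:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        for s in samples:
            if s in patient_ids:
                raise ValueError(f"duplicate sample name {s!r} across VCF inputs")
        patient_ids.extend(samples)
        block = np.zeros((len(samples), n_var), dtype=np.int8)
        mask = np.ones((len(samples), n_var), dtype=np.int8)  # absent -> missing
        for rec in vcf:
            chrom = _norm_chrom(rec.CHROM)
            col = None
            alt_index = None
            for ai, alt in enumerate(rec.ALT or []):
                col = by_locus.get((chrom, rec.POS, rec.REF, alt))
                if col is not None:
                    alt_index = ai + 1
                    break
            if col is None and rec.ID:
                col = by_rsid.get(rec.ID)
                alt_index = 1 if rec.ALT else None
            if col is None:
                log.debug("ignoring %s:%s %s (not in panel)", rec.CHROM, rec.POS, rec.ID)
                continue
            for si, g in enumerate(rec.genotypes):
                alleles = [a for a in g[:-1]]
                if all(a < 0 for a in alleles):
                    continue  # no-call: stays missing
                n_alt = sum(1 for a in alleles if a == alt_index)
                value = min(n_alt, 1) if genotype_coding == "carrier" else n_alt
                block[si, col] = value
                mask[si, col] = 0
        rows.append(block)
        masks.append(mask)
    if not rows:
        raise ValueError("no VCF inputs given")
    return GenotypeMatrix(
        patient_ids=patient_ids,
        variant_ids=panel.rsids,
        carrier=np.vstack(rows),
        missing_mask=np.vstack(masks),
        coding=genotype_coding,
    )


def flag_high_missingness(matrix: GenotypeMatrix, threshold: float = 0.2) -> list:
    """Patients whose fraction of missing panel sites exceeds `threshold`."""
    frac = matrix.missing_mask.mean(axis=1)
    return [p for p, f in zip(matrix.patient_ids, frac) if f > threshold]


def qc_summary(matrix: GenotypeMatrix, panel: PanelManifest) -> QCReport:
    """SNV/indel and per-chromosome counts among variants observed in the cohort.

    A variant is observed when at least one patient carries it.
    """
    observed = matrix.carrier.sum(axis=0) > 0
    by_rsid = {v.rsid: v for v in panel}
    n_snv = n_indel = n_x = 0
    per_chrom: dict[str, int] = {}
    for rsid, seen in zip(matrix.variant_ids, observed):
        if not seen:
            continue
        v = by_rsid[rsid]
        if v.is_snv:
            n_snv += 1
        else:
            n_indel += 1
        per_chrom[v.chrom] = per_chrom.get(v.chrom, 0) + 1
        if v.chrom == "X":
            n_x += 1
    return QCReport(n_snv=n_snv, n_indel=n_indel, per_chromosome=per_chrom, n_x_chrom=n_x)


def summarize_clinical(clinical: ClinicalTable, decimals: int = 1) -> pd.DataFrame:
    """Cohort characteristics table: label, count, truncated percentage.

    Mirrors a clinical "Table 1": sex, stage, ADR prevalence and category
    breakdown, and treatment exposure, each as ``count (pct%)`` of the
    cohort with percentages truncated to `decimals`.
    """
    n = len(clinical)
    if n == 0:
        raise ValueError("clinical table is empty")
    df = clinical.df
    rows = []

    def add(section, label, count):
        rows.append(
            {
                "section": section,
                "label": label,
                "count": int(count),
                "percentage": format_percentage(int(count), n, decimals),
            }
        )

    for sex in sorted(df["sex"].unique()):
        add("sex", sex, (df["sex"] == sex).sum())
    for stage in sorted(df["stage"].unique()):
        add("stage", stage, (df["stage"] == stage).sum())
    add("adr", "patients_with_adrs", df["adr_any"].sum())
    for cat in ADR_CATEGORIES:
        add("adr_category", cat, df["adr_categories"].map(lambda cs: cat in cs).sum())
    for t in clinical.observed_treatments():
        add("treatment", t, df["treatments"].map(lambda ts: t in ts).sum())
    platinum = df["treatments"].map(lambda ts: bool({"cisplatin", "carboplatin"} & set(ts)))
    add("treatment", "platinum_doublet", platinum.sum())
    return pd.DataFrame(rows, columns=["section", "label", "count", "percentage"])
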