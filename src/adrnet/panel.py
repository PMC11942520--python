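"""SNP-panel manifest: loading, validation, and design filtering.

The panel is a curated set of germline pharmacogenomic variants, each
annotated with the gene it falls in, a functional gene category, and the
drugs whose toxicity or efficacy the variant is associated with.  A subset
of rows is flagged as excluded by the assay design or as duplicates of
another row; :func:`filter_panel` removes those and reports the counts.

The on-disk format is a UTF-8 TSV with a mandatory header.  Coordinates are
1-based hg19.  Drug annotations are serialized as semicolon-separated
``drug|phenotype_category[|note]`` triples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd

from ._utils import truncate_percentage

__all__ = [
    "CATEGORIES",
    "DrugAnnotation",
    "PanelVariant",
    "PanelManifest",
    "FilterReport",
    "PanelError",
    "PanelFormatError",
    "PanelRowError",
    "load_panel",
    "write_panel",
    "filter_panel",
    "gene_category_summary",
]

#: Closed five-way functional classification of panel genes.
CATEGORIES = (
    "transporter",
    "phase_I_metabolism",
    "phase_II_metabolism",
    "dna_repair",
    "other_target_signaling",
)

COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "category",
    "drug_annotations",
    "radiotoxicity",
    "design_excluded",
    "duplicate_of",
]

VALID_CHROMS = {str(c) for c in range(1, 23)} | {"X"}


class PanelError(Exception):
    """Base class for panel manifest problems."""


class PanelFormatError(PanelError):
    """The file structure (header/columns) is unusable."""


class PanelRowError(PanelError):
    """One or more rows violate the manifest invariants.

    All violations are collected and reported together.
    """

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class DrugAnnotation(NamedTuple):
    drug: str
    phenotype_category: str
    note: str = ""


@dataclass
class PanelVariant:
    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""  # empty -> intergenic
    category: str = "other_target_signaling"
    drug_annotations: tuple = ()
    radiotoxicity: bool = False
    design_excluded: bool = False
    duplicate_of: str | None = None

    @property
    def is_intergenic(self) -> bool:
        return self.gene == ""

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class PanelManifest:
    variants: list = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def rsids(self) -> list:
        return [v.rsid for v in self.variants]

    def get(self, rsid: str) -> PanelVariant:
        for v in self.variants:
            if v.rsid == rsid:
                return v
        raise KeyError(rsid)


@dataclass
class FilterReport:
    n_input: int
    n_design_excluded: int
    n_duplicates: int
    n_retained: int
    retained_fraction: float

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_design_excluded": self.n_design_excluded,
            "n_duplicates": self.n_duplicates,
            "n_retained": self.n_retained,
            "retained_fraction": self.retained_fraction,
        }


def _parse_bool(raw: str) -> bool:
    return str(raw).strip().lower() in {"1", "true", "yes"}


def _parse_annotations(raw: str) -> tuple:
    out = []
    for chunk in str(raw).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split("|")
        if len(parts) == 1:
            out.append(DrugAnnotation(parts[0], ""))
        else:
            out.append(DrugAnnotation(parts[0], parts[1], parts[2] if len(parts) > 2 else ""))
    return tuple(out)


def load_panel(path) -> PanelManifest:
    """Read a panel manifest TSV, validating every row.

    Raises :class:`PanelFormatError` if a mandatory column is missing and
    :class:`PanelRowError` carrying *all* row-level violations (malformed
    position, unknown category/chromosome, dangling ``duplicate_of``, ...)
    with 1-based line numbers.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise PanelFormatError(f"{path}: no header row") from None
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    errors: list[str] = []
    variants: list[PanelVariant] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        rsid = str(row.rsid).strip()
        if not rsid:
            errors.append(f"line {line}: empty rsid")
            continue
        try:
            pos = int(row.pos)
        except (TypeError, ValueError):
            errors.append(f"line {line}: {rsid}: malformed position {row.pos!r}")
            continue
        if pos < 1:
            errors.append(f"line {line}: {rsid}: position must be >= 1, got {pos}")
            continue
        chrom = str(row.chrom).strip().removeprefix("chr")
        if chrom not in VALID_CHROMS:
            errors.append(f"line {line}: {rsid}: unknown chromosome {row.chrom!r}")
            continue
        category = str(row.category).strip()
        if category and category not in CATEGORIES:
            errors.append(f"line {line}: {rsid}: unknown category {category!r}")
            continue
        gene = str(row.gene).strip()
        if not gene and not category:
            category = "other_target_signaling"
        if not category:
            errors.append(f"line {line}: {rsid}: coding variant without category")
            continue
        dup = str(row.duplicate_of).strip() or None
        variants.append(
            PanelVariant(
                rsid=rsid,
                chrom=chrom,
                pos=pos,
                ref=str(row.ref).strip(),
                alt=str(row.alt).strip(),
                gene=gene,
                category=category,
                drug_annotations=_parse_annotations(row.drug_annotations),
                radiotoxicity=_parse_bool(row.radiotoxicity),
                design_excluded=_parse_bool(row.design_excluded),
                duplicate_of=dup,
            )
        )
        seen.add(rsid)

    # duplicate_of must reference a distinct rsid present in the manifest
    for v in variants:
        if v.duplicate_of is not None:
            if v.duplicate_of == v.rsid:
                errors.append(f"{v.rsid}: duplicate_of refers to itself")
            elif v.duplicate_of not in seen:
                errors.append(f"{v.rsid}: duplicate_of names unknown rsid {v.duplicate_of!r}")
    if errors:
        raise PanelRowError(errors)
    return PanelManifest(variants=variants, provenance=str(path))


def write_panel(manifest: PanelManifest, path) -> None:
    rows = []
    for v in manifest:
        rows.append(
            {
                "rsid": v.rsid,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "category": v.category,
                "drug_annotations": ";".join(
                    "|".join(p for p in ann if p) for ann in v.drug_annotations
                ),
                "radiotoxicity": int(v.radiotoxicity),
                "design_excluded": int(v.design_excluded),
                "duplicate_of": v.duplicate_of or "",
            }
        )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, sep="\t", index=False)


def filter_panel(manifest: PanelManifest) -> tuple[PanelManifest, FilterReport]:
    """Drop design-excluded and duplicate variants; report the counts.

    A variant flagged both design-excluded and duplicate counts once, under
    design exclusion, with a warning.  Rows whose rsid repeats an earlier
    row are treated as duplicates; the first occurrence in file order wins.
    The retained fraction is a percentage truncated to one decimal.
    """
    kept: list[PanelVariant] = []
    n_excl = n_dup = 0
    seen: set[str] = set()
    for v in manifest:
        if v.design_excluded:
            if v.duplicate_of is not None:
                warnings.warn(
                    f"{v.rsid} flagged both design_excluded and duplicate; "
                    "counted under design_excluded",
                    stacklevel=2,
                )
            n_excl += 1
        elif v.duplicate_of is not None or v.rsid in seen:
            n_dup += 1
        else:
            kept.append(v)
            seen.add(v.rsid)
    n_input = len(manifest)
    n_retained = len(kept)
    report = FilterReport(
        n_input=n_input,
        n_design_excluded=n_excl,
        n_duplicates=n_dup,
        n_retained=n_retained,
        retained_fraction=truncate_percentage(n_retained, n_input, 1) if n_input else 0.0,
    )
    return PanelManifest(variants=kept, provenance=manifest.provenance), report


def gene_category_summary(manifest: PanelManifest) -> dict:
    """Count distinct genes per functional category.

    Each gene is counted once in its category; intergenic variants (no gene
    symbol) are reported separately under ``intergenic_variants``.
    """
    genes_by_cat: dict[str, set] = {c: set() for c in CATEGORIES}
    n_intergenic = 0
    for v in manifest:
        if v.is_intergenic:
            n_intergenic += 1
        else:
            genes_by_cat[v.category].add(v.gene)
    out = {c: len(g) for c, g in genes_by_cat.items()}
    out["intergenic_variants"] = n_intergenic
    return out
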