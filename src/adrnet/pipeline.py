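"""End-to-end orchestration: panel -> ingest -> cluster -> annotate ->
enrich -> associate -> per-patient reports.

A run is driven by a YAML config, executes the stages in order with
structured logging, and writes every stage artifact plus a ``manifest.json``
recording the configuration, seeds, and SHA-256 digests of all outputs, so
a rerun with identical config and inputs is byte-identical and verifiable.

Per-patient reports are research output, not clinical advice; every report
carries an explicit banner saying so.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_clusters, drug_cluster_proportions, gene_exclusivity
from .association import Z_DEFAULT, associate_all
from .clustering import DEFAULT_EDGE_THRESHOLD, Clustering, build_patient_graph, detect_communities
from .cohort import ClinicalTable, flag_high_missingness, qc_summary, read_cohort_vcf, summarize_clinical
from .enrichment import TermGeneMap, enrich_clusters
from .panel import filter_panel, load_panel, write_panel

__all__ = ["RunConfig", "PatientReport", "run_pipeline", "render_report", "PipelineStageError"]

log = logging.getLogger(__name__)

DISCLAIMER = "Research use only - not a clinical device."

#: Clusters at or below this size get a small-cluster caveat in reports.
SMALL_CLUSTER = 5


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    panel: str
    vcf_dir: str
    clinical: str
    gmt: str
    out_dir: str
    namespaces: str | None = None
    metric: str = "jaccard"
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD
    resolution: float = 1.0
    seed: int = 17
    genotype_coding: str = "carrier"
    assignment_mode: str = "private"
    convention: str = "A"
    z: float = Z_DEFAULT
    alpha: float = 0.05
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        missing = [k for k in ("panel", "vcf_dir", "clinical", "gmt", "out_dir") if k not in kwargs]
        if missing:
            raise ValueError(f"{path}: missing required config key(s): {', '.join(missing)}")
        return cls(extra=extra, **kwargs)

    def validate(self) -> None:
        for key in ("panel", "clinical", "gmt"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise FileNotFoundError(f"config {key}: {p} does not exist")
        vdir = Path(self.vcf_dir)
        if not vdir.is_dir() or not sorted(vdir.glob("*.vcf*")):
            raise FileNotFoundError(f"config vcf_dir: no VCF files under {vdir}")
        if self.namespaces is not None and not Path(self.namespaces).exists():
            raise FileNotFoundError(f"config namespaces: {self.namespaces} does not exist")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        if self.convention not in {"A", "B"}:
            raise ValueError(f"unknown convention {self.convention!r}")


@dataclass
class PatientReport:
    patient_id: str
    cluster: int
    cluster_size: int
    drug_profile: dict
    associations: list
    flagged_treatments: list
    caveats: list

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        lines = [
            DISCLAIMER,
            f"Patient {self.patient_id} - cluster {self.cluster} "
            f"({self.cluster_size} member{'s' if self.cluster_size != 1 else ''})",
        ]
        for c in self.caveats:
            lines.append(f"CAVEAT: {c}")
        if self.flagged_treatments:
            lines.append("Treatments with elevated ADR susceptibility in this cluster (OR > 1):")
            for t in self.flagged_treatments:
                row = next(r for r in self.associations if r["treatment"] == t)
                lines.append(
                    f"  - {t}: OR {row['or_value']:.2f} "
                    f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f})"
                )
        else:
            lines.append("No treatment shows elevated ADR odds in this cluster.")
        if self.drug_profile:
            lines.append("Cluster drug-annotation profile (share of each drug's occurrences):")
            for drug, p in sorted(self.drug_profile.items(), key=lambda kv: -kv[1])[:10]:
                lines.append(f"  - {drug}: {p:.2f}")
        return "\n".join(lines) + "\n"


def render_report(
    associations: pd.DataFrame,
    clustering: Clustering,
    patient_id: str,
    proportions: pd.DataFrame | None = None,
) -> PatientReport:
    """Per-patient summary of cluster assignment and treatment ORs.

    Flags every treatment whose OR point estimate in the patient's cluster
    exceeds 1 (elevated susceptibility direction).  A caveat is added for
    small clusters, where estimates rest on very few patients.
    """
    if patient_id not in clustering.labels:
        raise KeyError(f"unknown patient id {patient_id!r}")
    cluster = clustering.labels[patient_id]
    size = len(clustering.members(cluster))
    sub = associations[associations["cluster"] == cluster]
    rows = sub.to_dict("records")
    flagged = [r["treatment"] for r in rows if r["or_value"] > 1]
    caveats = []
    if size <= SMALL_CLUSTER:
        caveats.append(
            f"small cluster (n={size}): association estimates are unstable "
            "and confidence intervals are wide"
        )
    profile = {}
    if proportions is not None and cluster in proportions.columns:
        col = proportions[cluster]
        profile = {drug: float(p) for drug, p in col.items() if p > 0}
    return PatientReport(
        patient_id=patient_id,
        cluster=cluster,
        cluster_size=size,
        drug_profile=profile,
        associations=rows,
        flagged_treatments=flagged,
        caveats=caveats,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Any stage failure is re-raised as :class:`PipelineStageError` naming
    the stage.  Reruns with identical config and inputs produce identical
    output digests.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(exist_ok=True)
    stage = "panel"
    try:
        t0 = time.time()
        manifest = load_panel(config.panel)
        filtered, report = filter_panel(manifest)
        write_panel(filtered, out / "panel_filtered.tsv")
        _dump_json(report.to_dict(), out / "filter_report.json")
        log.info("stage=panel rows_in=%d rows_out=%d elapsed=%.2fs",
                 report.n_input, report.n_retained, time.time() - t0)

        stage = "ingest"
        t0 = time.time()
        vcfs = sorted(Path(config.vcf_dir).glob("*.vcf*"))
        matrix = read_cohort_vcf(vcfs, filtered, genotype_coding=config.genotype_coding)
        matrix.to_tsv(out / "genotype_matrix.tsv")
        qc = qc_summary(matrix, filtered)
        flagged = flag_high_missingness(matrix)
        _dump_json({**qc.to_dict(), "high_missingness_patients": flagged}, out / "qc.json")
        clinical = ClinicalTable.from_csv(config.clinical)
        summarize_clinical(clinical).to_csv(out / "clinical_summary.tsv", sep="\t", index=False)
        log.info("stage=ingest patients=%d variants=%d elapsed=%.2fs",
                 *matrix.shape, time.time() - t0)

        stage = "cluster"
        t0 = time.time()
        graph = build_patient_graph(matrix, metric=config.metric, edge_threshold=config.edge_threshold)
        graph.edge_frame().to_csv(out / "graph_edges.tsv", sep="\t", index=False)
        clustering = detect_communities(graph, seed=config.seed, resolution=config.resolution)
        clustering.to_frame().to_csv(out / "partition.tsv", sep="\t", index=False)
        _dump_json(
            {
                "q": clustering.q,
                "n_clusters": clustering.n_clusters,
                "seed": clustering.seed,
                "resolution": clustering.resolution,
                "sizes": clustering.sizes(),
            },
            out / "clustering.json",
        )
        log.info("stage=cluster k=%d Q=%.4f elapsed=%.2fs",
                 clustering.n_clusters, clustering.q, time.time() - t0)

        stage = "annotate"
        t0 = time.time()
        annotation = annotate_clusters(clustering, matrix, filtered, mode=config.assignment_mode)
        _dump_json(annotation.to_dict(), out / "cluster_annotation.json")
        exclusive, histogram = gene_exclusivity(annotation)
        _dump_json(
            {"exclusive_genes": {str(k): v for k, v in exclusive.items()},
             "shared_gene_histogram": {str(k): v for k, v in histogram.items()}},
            out / "gene_venn.json",
        )
        proportions = drug_cluster_proportions(annotation, filtered)
        proportions.to_csv(out / "drug_proportions.tsv", sep="\t")
        log.info("stage=annotate clusters=%d drugs=%d elapsed=%.2fs",
                 len(annotation.clusters), len(proportions), time.time() - t0)

        stage = "enrich"
        t0 = time.time()
        term_map = TermGeneMap.from_gmt(config.gmt, namespaces=config.namespaces)
        enrichment = enrich_clusters(annotation.gene_sets, term_map, alpha=config.alpha)
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        log.info("stage=enrich tests=%d elapsed=%.2fs", len(enrichment), time.time() - t0)

        stage = "associate"
        t0 = time.time()
        associations = associate_all(
            clinical, clustering, convention=config.convention, z=config.z
        )
        associations.to_csv(out / "association.tsv", sep="\t", index=False)
        _dump_json(associations.to_dict("records"), out / "association.json")
        log.info("stage=associate rows=%d elapsed=%.2fs", len(associations), time.time() - t0)

        stage = "report"
        t0 = time.time()
        for pid in clustering.labels:
            rep = render_report(associations, clustering, pid, proportions)
            _dump_json(rep.to_dict(), out / "reports" / f"{pid}.json")
            (out / "reports" / f"{pid}.txt").write_text(rep.to_text())
        log.info("stage=report patients=%d elapsed=%.2fs",
                 len(clustering.labels), time.time() - t0)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    digests = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    _dump_json(
        {
            "version": __version__,
            "config": {k: v for k, v in asdict(config).items()},
            "outputs": digests,
        },
        out / "manifest.json",
    )
    return out
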