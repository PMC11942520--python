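"""Cluster -> variant -> gene -> drug annotation statistics.

Variants are attributed to clusters either privately (carried only by that
cluster's members; the default, which makes cluster variant sets disjoint
and Venn counts exact) or by union (carried by at least one member).  Gene
sets follow from the panel's gene symbols, drug sets from the panel's drug
annotations.  The drug-proportion matrix normalizes, for each drug, its
(variant, drug) annotation occurrences across clusters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .clustering import Clustering
from .cohort import GenotypeMatrix
from .panel import PanelManifest

__all__ = [
    "ClusterAnnotation",
    "assign_cluster_variants",
    "annotate_clusters",
    "gene_exclusivity",
    "drug_cluster_proportions",
    "drug_exclusivity",
    "normalize_drug",
]

_COMBO_SPLIT = re.compile(r"\s*[/+]\s*")


def normalize_drug(name: str) -> list:
    """Lower-case generic name(s); combination regimens split into constituents."""
    return [p.strip().lower() for p in _COMBO_SPLIT.split(str(name)) if p.strip()]


@dataclass
class ClusterAnnotation:
    """Per-cluster variant/gene/drug sets plus membership counts."""

    variant_sets: dict
    gene_sets: dict
    drug_sets: dict
    n_patients: dict
    mode: str = "private"

    @property
    def clusters(self) -> list:
        return sorted(self.variant_sets)

    def counts(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": c,
                "n_patients": self.n_patients[c],
                "n_genes": len(self.gene_sets[c]),
                "n_variants": len(self.variant_sets[c]),
            }
            for c in self.clusters
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            str(c): {
                "n_patients": self.n_patients[c],
                "variants": sorted(self.variant_sets[c]),
                "genes": sorted(self.gene_sets[c]),
                "drugs": sorted(self.drug_sets[c]),
            }
            for c in self.clusters
        }


def assign_cluster_variants(
    clustering: Clustering, matrix: GenotypeMatrix, mode: str = "private"
) -> dict:
    """Attribute carried variants to clusters.

    ``union``: every variant carried by >= 1 member.  ``private``: variants
    carried by members of that cluster and by nobody outside it (variants
    spanning clusters are attributed to none).
    """
    if mode not in {"union", "private"}:
        raise ValueError(f"unknown mode {mode!r}")
    missing = [p for p in matrix.patient_ids if p not in clustering.labels]
    if missing:
        raise ValueError(f"clustering does not cover patient(s): {missing}")
    carriers_by_cluster: dict[int, set] = {c: set() for c in range(clustering.n_clusters)}
    for i, pid in enumerate(matrix.patient_ids):
        c = clustering.labels[pid]
        carried = [matrix.variant_ids[j] for j in range(len(matrix.variant_ids)) if matrix.carrier[i, j] > 0]
        carriers_by_cluster.setdefault(c, set()).update(carried)
    if mode == "union":
        return carriers_by_cluster
    out = {}
    for c, vs in carriers_by_cluster.items():
        others = set()
        for c2, vs2 in carriers_by_cluster.items():
            if c2 != c:
                others |= vs2
        out[c] = vs - others
    return out


def annotate_clusters(
    clustering: Clustering,
    matrix: GenotypeMatrix,
    panel: PanelManifest,
    mode: str = "private",
) -> ClusterAnnotation:
    variant_sets = assign_cluster_variants(clustering, matrix, mode=mode)
    by_rsid = {v.rsid: v for v in panel}
    gene_sets = {}
    drug_sets = {}
    n_patients = {}
    for c, vs in variant_sets.items():
        genes = set()
        drugs = set()
        for rsid in vs:
            v = by_rsid.get(rsid)
            if v is None:
                continue
            if v.gene:
                genes.add(v.gene)
            for ann in v.drug_annotations:
                drugs.update(normalize_drug(ann.drug))
        gene_sets[c] = genes
        drug_sets[c] = drugs
        n_patients[c] = sum(1 for p in matrix.patient_ids if clustering.labels[p] == c)
    return ClusterAnnotation(
        variant_sets={c: set(v) for c, v in variant_sets.items()},
        gene_sets=gene_sets,
        drug_sets=drug_sets,
        n_patients=n_patients,
        mode=mode,
    )


def gene_exclusivity(annotation: ClusterAnnotation) -> tuple[dict, dict]:
    """Per-cluster exclusive gene counts and a shared-gene histogram.

    A gene is exclusive when present in exactly one cluster's gene set; the
    histogram keys are the number of clusters sharing each gene.
    """
    clusters = annotation.clusters
    if not clusters:
        raise ValueError("no clusters")
    membership: dict[str, list] = {}
    for c in clusters:
        for g in annotation.gene_sets[c]:
            membership.setdefault(g, []).append(c)
    exclusive = {c: 0 for c in clusters}
    histogram: dict[int, int] = {}
    for g, cs in membership.items():
        k = len(cs)
        histogram[k] = histogram.get(k, 0) + 1
        if k == 1:
            exclusive[cs[0]] += 1
    return exclusive, histogram


def drug_cluster_proportions(
    annotation: ClusterAnnotation, panel: PanelManifest
) -> pd.DataFrame:
    """Drugs x clusters proportion matrix.

    One occurrence is one distinct (variant, drug) annotation pair, counted
    in the cluster holding that variant; each drug's row is normalized by
    its total occurrences, so rows sum to one.  Drugs with no occurrence in
    any cluster are omitted.
    """
    clusters = annotation.clusters
    pairs_by_drug: dict[str, dict[int, set]] = {}
    by_rsid = {v.rsid: v for v in panel}
    for c in clusters:
        for rsid in annotation.variant_sets[c]:
            v = by_rsid.get(rsid)
            if v is None:
                continue
            for ann in v.drug_annotations:
                for drug in normalize_drug(ann.drug):
                    pairs_by_drug.setdefault(drug, {}).setdefault(c, set()).add(rsid)
    if not pairs_by_drug:
        return pd.DataFrame(columns=clusters, dtype=float)
    rows = {}
    for drug in sorted(pairs_by_drug):
        counts = [len(pairs_by_drug[drug].get(c, ())) for c in clusters]
        total = sum(counts)
        if total == 0:
            continue
        rows[drug] = [n / total for n in counts]
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=clusters)
    mat.index.name = "drug"
    return mat


def drug_exclusivity(matrix: pd.DataFrame) -> tuple[dict, int, int]:
    """Exclusive-per-cluster counts, shared count, and common-to-all count.

    Exclusive: nonzero in exactly one cluster.  Shared: nonzero in >= 2.
    Common-to-all: nonzero in every cluster (also counted among shared).
    """
    if matrix.empty:
        raise ValueError("empty drug-proportion matrix")
    nz = matrix.to_numpy() > 0
    n_clusters = matrix.shape[1]
    per_drug = nz.sum(axis=1)
    exclusive = {c: 0 for c in matrix.columns}
    for drug_i, k in enumerate(per_drug):
        if k == 1:
            c = matrix.columns[int(nz[drug_i].argmax())]
            exclusive[c] += 1
    n_shared = int((per_drug >= 2).sum())
    n_common_all = int((per_drug == n_clusters).sum())
    return exclusive, n_shared, n_common_all
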