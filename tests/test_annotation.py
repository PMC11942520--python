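import numpy as np
import pandas as pd
import pytest

from adrnet.annotation import (
    ClusterAnnotation,
    annotate_clusters,
    assign_cluster_variants,
    drug_cluster_proportions,
    drug_exclusivity,
    gene_exclusivity,
    normalize_drug,
)
from adrnet.clustering import Clustering
from adrnet.panel import DrugAnnotation, PanelManifest, PanelVariant
from conftest import make_matrix


def clustering_for(labels):
    n = max(labels.values()) + 1
    return Clustering(labels=labels, q=0.0, n_clusters=n, seed=0)


class TestVariantAssignment:
    def test_private_mode_collects_cluster_only_variants(self):
        # P1,P2 in cluster 0 carry v0,v1; P3 (cluster 1) carries v2
        m = make_matrix([{0}, {1}, {2}])
        cl = clustering_for({"P001": 0, "P002": 0, "P003": 1})
        sets = assign_cluster_variants(cl, m, mode="private")
        assert sets[0] == {"v0", "v1"}
        assert sets[1] == {"v2"}

    def test_variant_spanning_clusters_is_private_to_none_union_to_both(self):
        m = make_matrix([{0}, {0}])
        cl = clustering_for({"P001": 0, "P002": 1})
        private = assign_cluster_variants(cl, m, mode="private")
        union = assign_cluster_variants(cl, m, mode="union")
        assert private[0] == private[1] == set()
        assert union[0] == union[1] == {"v0"}

    def test_private_sets_are_pairwise_disjoint(self, default_cohort, default_clustering):
        sets = assign_cluster_variants(default_clustering, default_cohort.genotypes, mode="private")
        clusters = sorted(sets)
        for i in clusters:
            for j in clusters:
                if i < j:
                    assert not (sets[i] & sets[j])

    def test_empty_cluster_yields_empty_set(self):
        m = make_matrix([{0}, {1}])
        cl = Clustering(labels={"P001": 0, "P002": 0}, q=0.0, n_clusters=2, seed=0)
        sets = assign_cluster_variants(cl, m, mode="union")
        assert sets[1] == set()

    def test_labels_must_cover_patients(self):
        m = make_matrix([{0}, {1}])
        cl = clustering_for({"P001": 0})
        with pytest.raises(ValueError, match="cover"):
            assign_cluster_variants(cl, m)


def annotation_from_gene_sets(gene_sets):
    clusters = sorted(gene_sets)
    return ClusterAnnotation(
        variant_sets={c: set() for c in clusters},
        gene_sets={c: set(gene_sets[c]) for c in clusters},
        drug_sets={c: set() for c in clusters},
        n_patients={c: 1 for c in clusters},
    )


class TestGeneExclusivity:
    def test_reported_exclusive_distribution(self):
        """Five clusters with exclusive gene counts 47/37/45/12/5 -> 146 total,
        plus 30 genes shared by no more than three clusters."""
        counts = [47, 37, 45, 12, 5]
        gene_sets = {c: {f"EX{c}_{i}" for i in range(n)} for c, n in enumerate(counts)}
        shared_two = {f"SH2_{i}" for i in range(20)}
        shared_three = {f"SH3_{i}" for i in range(10)}
        gene_sets[0] |= shared_two | shared_three
        gene_sets[1] |= shared_two | shared_three
        gene_sets[2] |= shared_three
        exclusive, histogram = gene_exclusivity(annotation_from_gene_sets(gene_sets))
        assert exclusive == {0: 47, 1: 37, 2: 45, 3: 12, 4: 5}
        assert sum(exclusive.values()) == 146
        assert histogram == {1: 146, 2: 20, 3: 10}
        assert max(histogram) <= 3 or histogram.get(4, 0) == histogram.get(5, 0) == 0

    def test_single_cluster_all_genes_exclusive(self):
        exclusive, histogram = gene_exclusivity(annotation_from_gene_sets({0: {"A", "B"}}))
        assert exclusive == {0: 2}
        assert histogram == {1: 2}

    def test_gene_in_every_cluster_counts_in_top_bucket_only(self):
        gene_sets = {c: {"UBIQ"} for c in range(5)}
        gene_sets[0].add("ONLY0")
        exclusive, histogram = gene_exclusivity(annotation_from_gene_sets(gene_sets))
        assert exclusive == {0: 1, 1: 0, 2: 0, 3: 0, 4: 0}
        assert histogram == {1: 1, 5: 1}

    def test_exclusive_counts_sum_matches_exclusive_set(self, default_cohort, default_clustering):
        ann = annotate_clusters(default_clustering, default_cohort.genotypes, default_cohort.panel)
        exclusive, histogram = gene_exclusivity(ann)
        assert sum(exclusive.values()) == histogram.get(1, 0)


def panel_with_annotations(spec):
    """spec: iterable of (rsid, [drug, ...])."""
    variants = []
    for i, (rsid, drugs) in enumerate(spec):
        anns = tuple(DrugAnnotation(d, "Toxicity") for d in drugs)
        variants.append(
            PanelVariant(rsid, "1", 100 + i, "A", "G", gene=f"G{i}",
                         category="transporter", drug_annotations=anns)
        )
    return PanelManifest(variants=variants)


def annotation_with_variants(variant_sets):
    clusters = sorted(variant_sets)
    return ClusterAnnotation(
        variant_sets={c: set(variant_sets[c]) for c in clusters},
        gene_sets={c: set() for c in clusters},
        drug_sets={c: set() for c in clusters},
        n_patients={c: 1 for c in clusters},
    )


class TestDrugProportions:
    def test_occurrences_normalized_per_drug(self):
        panel = panel_with_annotations([("v1", ["D"]), ("v2", ["D"]), ("v3", ["D"])])
        ann = annotation_with_variants({0: {"v1", "v2"}, 1: {"v3"}})
        mat = drug_cluster_proportions(ann, panel)
        assert mat.loc["d", 0] == pytest.approx(2 / 3)
        assert mat.loc["d", 1] == pytest.approx(1 / 3)

    def test_single_variant_drug_fully_in_its_cluster(self):
        panel = panel_with_annotations([("v1", ["Solo"]), ("v2", [])])
        ann = annotation_with_variants({0: {"v1"}, 1: {"v2"}})
        mat = drug_cluster_proportions(ann, panel)
        assert mat.loc["solo", 0] == 1.0
        assert mat.loc["solo", 1] == 0.0

    def test_radiotherapy_fixture_three_quarters_in_cluster_zero(self):
        # 9 of 12 radiotherapy-annotated variants sit in cluster 0
        spec = [(f"v{i}", ["radiotherapy"]) for i in range(12)]
        panel = panel_with_annotations(spec)
        ann = annotation_with_variants(
            {0: {f"v{i}" for i in range(9)}, 1: {"v9", "v10", "v11"}}
        )
        mat = drug_cluster_proportions(ann, panel)
        assert mat.loc["radiotherapy", 0] == pytest.approx(0.75)

    def test_duplicate_annotation_lines_collapse_to_one_occurrence(self):
        panel = panel_with_annotations([("v1", ["D", "D"]), ("v2", ["D"])])
        ann = annotation_with_variants({0: {"v1"}, 1: {"v2"}})
        mat = drug_cluster_proportions(ann, panel)
        assert mat.loc["d", 0] == pytest.approx(0.5)

    def test_combination_regimens_expand_to_constituents(self):
        assert normalize_drug("Carboplatin/Pemetrexed") == ["carboplatin", "pemetrexed"]
        panel = panel_with_annotations([("v1", ["Carboplatin/Pemetrexed"]), ("v2", ["pemetrexed"])])
        ann = annotation_with_variants({0: {"v1"}, 1: {"v2"}})
        mat = drug_cluster_proportions(ann, panel)
        assert mat.loc["carboplatin", 0] == 1.0
        assert mat.loc["pemetrexed", 0] == pytest.approx(0.5)

    def test_rows_sum_to_one(self, default_cohort, default_clustering):
        ann = annotate_clusters(default_clustering, default_cohort.genotypes, default_cohort.panel)
        mat = drug_cluster_proportions(ann, default_cohort.panel)
        assert len(mat) > 0
        np.testing.assert_allclose(mat.sum(axis=1).to_numpy(), 1.0, atol=1e-12)


class TestDrugExclusivity:
    @staticmethod
    def engineered_matrix():
        """Exclusives 3/14/7/2/0 plus 41 shared drugs, 12 common to all five."""
        rows = {}
        for c, n in enumerate([3, 14, 7, 2, 0]):
            for i in range(n):
                row = [0.0] * 5
                row[c] = 1.0
                rows[f"excl{c}_{i}"] = row
        for i in range(12):
            rows[f"common_{i}"] = [0.2] * 5
        for i in range(29):  # shared but not universal
            row = [0.0] * 5
            row[i % 4] = 0.5
            row[(i + 1) % 4] = 0.5
            rows[f"shared_{i}"] = row
        return pd.DataFrame.from_dict(rows, orient="index", columns=range(5))

    def test_reported_exclusivity_counts(self):
        exclusive, n_shared, n_common = drug_exclusivity(self.engineered_matrix())
        assert exclusive == {0: 3, 1: 14, 2: 7, 3: 2, 4: 0}
        assert n_shared == 41
        assert n_common == 12

    def test_drug_in_all_clusters_counted_shared_and_common(self):
        mat = pd.DataFrame({0: [0.5], 1: [0.5]}, index=["d"])
        exclusive, n_shared, n_common = drug_exclusivity(mat)
        assert exclusive == {0: 0, 1: 0}
        assert n_shared == n_common == 1

    def test_single_cluster_drug_is_exclusive(self):
        mat = pd.DataFrame({0: [1.0, 0.0], 1: [0.0, 1.0]}, index=["a", "b"])
        exclusive, n_shared, n_common = drug_exclusivity(mat)
        assert exclusive == {0: 1, 1: 1}
        assert n_shared == 0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            drug_exclusivity(pd.DataFrame())


def test_annotation_counts_frame(default_cohort, default_clustering):
    ann = annotate_clusters(default_clustering, default_cohort.genotypes, default_cohort.panel)
    counts = ann.counts()
    assert counts["n_patients"].sum() == 70
    assert set(counts["cluster"]) == set(range(5))
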