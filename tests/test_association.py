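import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from adrnet.association import (
    AGGREGATES,
    ContingencyTable,
    associate_all,
    build_contingency,
    odds_ratio,
    recover_table,
)
from adrnet.clustering import Clustering
from adrnet.cohort import ClinicalTable
from adrnet.simulate import SimulationConfig, make_planted_table_cohort, simulate_clinical

cells = st.integers(1, 30)


class TestOddsRatio:
    def test_symmetric_table_is_one(self):
        est = odds_ratio(ContingencyTable(1, 1, 1, 1))
        assert est.or_value == pytest.approx(1.0)
        assert not est.haldane_applied

    def test_printed_cisplatin_triple(self):
        est = odds_ratio(ContingencyTable(7, 2, 2, 3))
        assert est.rounded() == (5.25, 0.49, 56.80)

    def test_haldane_applied_on_zero_cell(self):
        est = odds_ratio(ContingencyTable(0, 5, 3, 10))
        assert est.haldane_applied
        assert est.or_value == pytest.approx((0.5 * 10.5) / (5.5 * 3.5))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            odds_ratio(ContingencyTable(0, 0, 3, 10))
        with pytest.raises(ValueError, match="margin"):
            odds_ratio(ContingencyTable(0, 5, 0, 10))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    @pytest.mark.parametrize("table", [(7, 2, 2, 3), (5, 3, 1, 5), (10, 10, 5, 20)])
    def test_chi_square_matches_reference_implementation(self, table):
        est = odds_ratio(ContingencyTable(*table))
        a, b, c, d = table
        stat, p, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
        assert est.chi2 == pytest.approx(stat, rel=1e-12)
        assert est.p_chi2 == pytest.approx(p, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_reciprocal_symmetry(self, a, b, c, d):
        left = odds_ratio(ContingencyTable(a, b, c, d)).or_value
        right = odds_ratio(ContingencyTable(b, a, d, c)).or_value
        assert left * right == pytest.approx(1.0, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_diagonal_swap_invariance(self, a, b, c, d):
        base = odds_ratio(ContingencyTable(a, b, c, d)).or_value
        assert odds_ratio(ContingencyTable(d, b, c, a)).or_value == pytest.approx(base, rel=1e-12)
        assert odds_ratio(ContingencyTable(a, c, b, d)).or_value == pytest.approx(base, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(a=st.integers(0, 25), b=cells, c=cells, d=st.integers(0, 25))
    def test_woolf_geometric_mean_identity(self, a, b, c, d):
        table = ContingencyTable(a, b, c, d)
        if min(table.margins()) == 0:
            return
        est = odds_ratio(table)
        geo = math.exp((math.log(est.ci_low) + math.log(est.ci_high)) / 2)
        assert geo == pytest.approx(est.or_value, abs=1e-9, rel=1e-9)


def toy_cohort():
    """6 patients, 4 treated: 2 in-cluster (both ADR), 2 out (1 ADR)."""
    records = []
    spec = [
        ("P1", True, True, True),
        ("P2", True, True, True),
        ("P3", False, True, True),
        ("P4", False, True, False),
        ("P5", False, False, False),
        ("P6", False, False, False),
    ]
    labels = {}
    for pid, in_cluster, treated, adr in spec:
        records.append(
            {
                "patient_id": pid,
                "age": 60.0,
                "sex": "F",
                "stage": "IIIA",
                "treatments": ("cisplatin",) if treated else (),
                "adr_any": adr,
                "adr_categories": (),
            }
        )
        labels[pid] = 0 if in_cluster else 1
    return ClinicalTable.from_records(records), Clustering(labels=labels, q=0.0, n_clusters=2, seed=0)


class TestBuildContingency:
    def test_convention_a_among_treated(self):
        clinical, clustering = toy_cohort()
        t = build_contingency(clinical, clustering, "cisplatin", 0, convention="A")
        assert t.cells() == (2, 0, 1, 1)

    def test_convention_b_within_cluster(self):
        # same cohort, rows become (treated, untreated) within cluster 0;
        # both members are treated so the untreated row is empty
        clinical, clustering = toy_cohort()
        t = build_contingency(clinical, clustering, "cisplatin", 0, convention="B")
        assert t.cells() == (2, 0, 0, 0)
        assert t.cells() != (2, 0, 1, 1)

    def test_unknown_treatment_errors_with_name(self):
        clinical, clustering = toy_cohort()
        with pytest.raises(ValueError, match="vinorelbine"):
            build_contingency(clinical, clustering, "vinorelbine", 0)

    def test_planted_cisplatin_table_reproduced(self):
        clinical, clustering = make_planted_table_cohort(
            ContingencyTable(7, 2, 2, 3), "cisplatin", cluster=0, n_patients=70
        )
        t = build_contingency(clinical, clustering, "cisplatin", 0, convention="A")
        assert t.cells() == (7, 2, 2, 3)

    def test_planted_pemetrexed_table_hits_printed_upper_bound(self):
        clinical, clustering = make_planted_table_cohort(
            ContingencyTable(5, 3, 1, 5), "pemetrexed", cluster=1, n_patients=70
        )
        t = build_contingency(clinical, clustering, "pemetrexed", 1, convention="A")
        est = odds_ratio(t)
        assert est.rounded() == (8.33, 0.63, 110.03)


class TestRecoverTable:
    def test_recovers_cisplatin_table_at_total_14(self):
        tables = recover_table(5.25, (0.49, 56.80), n_max=14, exact_total=True)
        assert ContingencyTable(7, 2, 2, 3) in tables

    def test_recovers_pemetrexed_table_up_to_70(self):
        tables = recover_table(8.33, (0.63, 110.03), n_max=70)
        assert ContingencyTable(5, 3, 1, 5) in tables

    def test_or_outside_its_ci_matches_nothing(self):
        assert recover_table(2.0, (3.0, 4.0), n_max=20) == []

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(a=st.integers(0, 5), b=st.integers(1, 5), c=st.integers(1, 5), d=st.integers(0, 5))
    def test_round_trip_recovers_planted_table(self, a, b, c, d):
        table = ContingencyTable(a, b, c, d)
        if min(table.margins()) == 0:
            return
        printed = odds_ratio(table).rounded()
        found = recover_table(printed[0], (printed[1], printed[2]), n_max=table.total)
        assert table in found


class TestAssociateAll:
    def test_planted_cluster_effect_flags_risk(self):
        labels = np.repeat(np.arange(5), [21, 16, 27, 5, 1])
        lab = {f"P{i + 1:03d}": int(labels[i]) for i in range(70)}
        clustering = Clustering(labels=lab, q=0.0, n_clusters=5, seed=0)
        effect = {(0, "cisplatin"): float(np.log(5.25))}
        cluster0, others = [], []
        for seed in range(20):
            clinical = simulate_clinical(SimulationConfig(seed=seed, effect_log_odds=effect), labels)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                df = associate_all(clinical, clustering, treatments=["cisplatin"])
            for row in df.itertuples():
                (cluster0 if row.cluster == 0 else others).append(math.log(row.or_value))
        assert np.median(cluster0) > 0  # elevated odds in the planted cluster
        assert np.median(cluster0) > np.median(others)
        assert abs(np.median(others)) < np.median(cluster0) / 2

    def test_untreated_treatment_row_absent_with_warning(self):
        clinical, clustering = toy_cohort()
        with pytest.warns(UserWarning):
            df = associate_all(clinical, clustering, treatments=["cisplatin", "pemetrexed"])
        assert "pemetrexed" not in set(df["treatment"])

    def test_aggregate_counts_union_of_members(self, default_cohort, default_clustering):
        clinical = default_cohort.clinical
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = associate_all(clinical, default_clustering)
        platinum = df[df["treatment"] == "platinum_compounds"]
        expected = len(clinical.treated_ids(AGGREGATES["platinum_compounds"]))
        totals = platinum[["a", "b", "c", "d"]].sum(axis=1)
        assert (totals == expected).all()
        assert expected == 44  # cisplatin 14 + carboplatin 30, disjoint by design

    def test_risk_flag_tracks_point_estimate(self, default_cohort, default_clustering):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = associate_all(default_cohort.clinical, default_clustering)
        assert (df["risk"] == (df["or_value"] > 1)).all()
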