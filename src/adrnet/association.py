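"""Cluster x treatment odds-ratio association against ADR outcomes.

For each (treatment, cluster) pair a 2x2 table is built, by default among
treated patients with rows (in cluster, not in cluster) and columns
(ADR, no ADR).  The odds ratio gets a Woolf (logit) 95% confidence
interval, ``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``, with the
Haldane-Anscombe +0.5 applied to all four cells only when a zero cell is
present, and an uncorrected Pearson chi-square on the raw cells.

:func:`recover_table` inverts the report: it enumerates all integer tables
up to a total-count bound and returns those whose odds-ratio output rounds
to a printed OR / CI triple, which makes published values auditable
without patient-level data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._utils import round_half_up
from .clustering import Clustering
from .cohort import ClinicalTable

__all__ = [
    "Z_DEFAULT",
    "AGGREGATES",
    "ContingencyTable",
    "OREstimate",
    "odds_ratio",
    "build_contingency",
    "recover_table",
    "associate_all",
]

#: Normal quantile for the 95% Woolf interval.
Z_DEFAULT = 1.96

#: Aggregate exposure groups: the union of member treatments, each patient
#: counted once.
AGGREGATES = {
    "platinum_compounds": ("cisplatin", "carboplatin"),
    "carboplatin_pemetrexed": ("carboplatin", "pemetrexed"),
    "radiotherapy_platinum": ("radiotherapy", "cisplatin", "carboplatin"),
}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cell counts; rows = exposure, columns = (ADR, no ADR)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError(f"cells must be non-negative integers, got {self}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple:
        return (self.a, self.b, self.c, self.d)

    def margins(self) -> tuple:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass
class OREstimate:
    or_value: float
    ci_low: float
    ci_high: float
    z: float
    haldane_applied: bool
    chi2: float
    p_chi2: float

    def rounded(self, decimals: int = 2) -> tuple:
        """(OR, low, high) rounded half-up for report display."""
        return (
            round_half_up(self.or_value, decimals),
            round_half_up(self.ci_low, decimals),
            round_half_up(self.ci_high, decimals),
        )


def _pearson_chi2(a, b, c, d):
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    stat = n * (a * d - b * c) ** 2 / denom
    return float(stat), float(chi2.sf(stat, df=1))


def odds_ratio(table: ContingencyTable, z: float = Z_DEFAULT) -> OREstimate:
    """Woolf-interval odds ratio with the Haldane-Anscombe zero-cell rule.

    Raises if a raw row or column margin is zero (the odds ratio is not
    identified from such a table, correction or not).
    """
    if min(table.margins()) == 0:
        raise ValueError(f"zero row/column margin in table {table.cells()}")
    a, b, c, d = (float(x) for x in table.cells())
    haldane = 0.0 in (a, b, c, d)
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orv = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(orv)
    stat, p = _pearson_chi2(*(float(x) for x in table.cells()))
    return OREstimate(
        or_value=float(orv),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        z=z,
        haldane_applied=haldane,
        chi2=stat,
        p_chi2=p,
    )


def _resolve_treated(clinical: ClinicalTable, treatment: str) -> set:
    members = AGGREGATES.get(treatment, (treatment,))
    return clinical.treated_ids(members)


def build_contingency(
    clinical: ClinicalTable,
    clustering: Clustering,
    treatment: str,
    cluster: int,
    convention: str = "A",
) -> ContingencyTable:
    """Tabulate ADR outcomes for one (treatment, cluster) pair.

    Convention ``A`` (default): among treated patients, rows are
    (in cluster, out of cluster).  Convention ``B``: within the cluster,
    rows are (treated, untreated).  Aggregate treatment labels (see
    :data:`AGGREGATES`) expand to the union of their members.
    """
    if convention not in {"A", "B"}:
        raise ValueError(f"unknown convention {convention!r}")
    if not (0 <= cluster < clustering.n_clusters):
        raise ValueError(f"cluster {cluster} does not exist")
    treated = _resolve_treated(clinical, treatment)
    if not treated:
        raise ValueError(f"no patients treated with {treatment!r}")
    adr = clinical.adr_ids()
    in_cluster = set(clustering.members(cluster))
    everyone = set(clinical.patient_ids)
    if convention == "A":
        grp1, grp2 = treated & in_cluster, treated - in_cluster
    else:
        grp1, grp2 = in_cluster & treated, in_cluster - treated
    return ContingencyTable(
        a=len(grp1 & adr),
        b=len(grp1 - adr),
        c=len(grp2 & adr),
        d=len(grp2 - adr),
    )


def _enumerate_tables(n_max: int, exact_total: bool):
    """All (a,b,c,d) integer cell arrays with total == or <= n_max."""
    blocks = []
    for a in range(n_max + 1):
        rem = n_max - a
        bg, cg = np.meshgrid(np.arange(rem + 1), np.arange(rem + 1), indexing="ij")
        b, c = bg.ravel(), cg.ravel()
        keep = b + c <= rem
        b, c = b[keep], c[keep]
        if exact_total:
            d = rem - b - c
            av = np.full_like(b, a)
            blocks.append(np.stack([av, b, c, d], axis=1))
        else:
            # d from 0 to rem-b-c: expand via repeat
            dmax = rem - b - c
            reps = dmax + 1
            av = np.repeat(np.full_like(b, a), reps)
            bv = np.repeat(b, reps)
            cv = np.repeat(c, reps)
            dv = np.concatenate([np.arange(m + 1) for m in dmax]) if len(dmax) else np.array([], dtype=int)
            blocks.append(np.stack([av, bv, cv, dv], axis=1))
    return np.concatenate(blocks, axis=0)


def recover_table(
    or_target: float | None,
    ci_target: tuple,
    n_max: int,
    decimals: int = 2,
    z: float = Z_DEFAULT,
    exact_total: bool = False,
) -> list:
    """Find every integer 2x2 table reproducing a printed OR / CI pair.

    Enumerates all tables with total <= `n_max` (or exactly `n_max` when
    `exact_total`), computes the odds ratio and Woolf bounds exactly as
    :func:`odds_ratio` does, rounds half-up to `decimals`, and keeps tables
    matching the printed confidence bounds — and the printed OR as well
    when `or_target` is given.  An empty list is a valid result (e.g. a
    printed OR lying outside its own printed interval matches no table).
    """
    lo_t, hi_t = (float(ci_target[0]), float(ci_target[1]))
    cells = _enumerate_tables(int(n_max), exact_total).astype(float)
    a, b, c, d = cells[:, 0], cells[:, 1], cells[:, 2], cells[:, 3]
    ok = (a + b > 0) & (c + d > 0) & (a + c > 0) & (b + d > 0)
    cells = cells[ok]
    a, b, c, d = cells[:, 0], cells[:, 1], cells[:, 2], cells[:, 3]
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    ah = np.where(zero, a + 0.5, a)
    bh = np.where(zero, b + 0.5, b)
    ch = np.where(zero, c + 0.5, c)
    dh = np.where(zero, d + 0.5, d)
    log_or = np.log(ah) + np.log(dh) - np.log(bh) - np.log(ch)
    se = np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    lo = round_half_up(np.exp(log_or - z * se), decimals)
    hi = round_half_up(np.exp(log_or + z * se), decimals)
    match = (lo == round(lo_t, decimals)) & (hi == round(hi_t, decimals))
    if or_target is not None:
        orv = round_half_up(np.exp(log_or), decimals)
        match &= orv == round(float(or_target), decimals)
    found = cells[match].astype(int)
    return [ContingencyTable(*map(int, row)) for row in found]


def associate_all(
    clinical: ClinicalTable,
    clustering: Clustering,
    treatments=None,
    convention: str = "A",
    z: float = Z_DEFAULT,
    include_aggregates: bool = True,
) -> pd.DataFrame:
    """One association row per (treatment, cluster).

    Treatments default to every individual treatment observed in the
    clinical table plus the aggregate groups whose members are observed.
    Pairs whose table is degenerate (nobody treated, empty margin) are
    skipped with a warning.  ``risk`` flags OR > 1 (elevated ADR odds).
    """
    if treatments is None:
        treatments = [t for t in clinical.observed_treatments() if t != "other"]
        if include_aggregates:
            observed = set(clinical.observed_treatments())
            for agg, members in AGGREGATES.items():
                if observed & set(members):
                    treatments.append(agg)
    rows = []
    for treatment in treatments:
        for cluster in range(clustering.n_clusters):
            try:
                table = build_contingency(
                    clinical, clustering, treatment, cluster, convention=convention
                )
                est = odds_ratio(table, z=z)
            except ValueError as exc:
                warnings.warn(
                    f"skipping ({treatment}, cluster {cluster}): {exc}", stacklevel=2
                )
                continue
            rows.append(
                {
                    "treatment": treatment,
                    "cluster": cluster,
                    "a": table.a,
                    "b": table.b,
                    "c": table.c,
                    "d": table.d,
                    "or_value": est.or_value,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "chi2": est.chi2,
                    "p_chi2": est.p_chi2,
                    "haldane_applied": est.haldane_applied,
                    "risk": est.or_value > 1,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "treatment",
            "cluster",
            "a",
            "b",
            "c",
            "d",
            "or_value",
            "ci_low",
            "ci_high",
            "chi2",
            "p_chi2",
            "haldane_applied",
            "risk",
        ],
    )
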