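"""Hypergeometric over-representation analysis of term -> gene sets.

Per-cluster gene sets are tested against flat GMT-style term maps (e.g.
GO Biological Process / Molecular Function slims) with the hypergeometric
upper tail and Benjamini-Hochberg FDR control applied within each cluster.
No ontology traversal or parent-term propagation is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Term",
    "TermGeneMap",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich_clusters",
]

NAMESPACES = ("BP", "MF")


class Term(NamedTuple):
    name: str
    namespace: str
    genes: frozenset


@dataclass
class TermGeneMap:
    terms: dict = field(default_factory=dict)
    universe: frozenset = frozenset()

    def __post_init__(self):
        for tid, term in self.terms.items():
            if not term.genes <= self.universe:
                extra = sorted(term.genes - self.universe)[:5]
                raise ValueError(f"term {tid}: genes outside universe, e.g. {extra}")

    @classmethod
    def from_gmt(cls, path, namespaces=None, universe=None) -> "TermGeneMap":
        """Read a GMT file (term, description, genes...).

        `namespaces` is an optional term -> BP/MF mapping (dict or
        two-column TSV path); otherwise the GMT description column is used
        when it names a namespace.  The universe defaults to the union of
        all term genes.
        """
        ns_map = {}
        if namespaces is not None:
            if isinstance(namespaces, dict):
                ns_map = dict(namespaces)
            else:
                ns_df = pd.read_csv(namespaces, sep="\t", header=None, names=["term", "ns"])
                ns_map = dict(zip(ns_df["term"], ns_df["ns"]))
        terms = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                tid, desc = parts[0], parts[1]
                genes = frozenset(g for g in parts[2:] if g)
                ns = ns_map.get(tid, desc if desc in NAMESPACES else "BP")
                terms[tid] = Term(name=tid, namespace=ns, genes=genes)
        if universe is None:
            universe = frozenset().union(*(t.genes for t in terms.values())) if terms else frozenset()
        return cls(terms=terms, universe=frozenset(universe))

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for tid in sorted(self.terms):
                t = self.terms[tid]
                fh.write("\t".join([tid, t.namespace, *sorted(t.genes)]) + "\n")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"inconsistent counts: K={K}, n={n} exceed N={N}")
    # survival function at k-1 gives the upper tail including k
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_clusters(
    gene_sets: dict,
    term_map: TermGeneMap,
    alpha: float = 0.05,
    min_term_size: int = 3,
    max_term_size: int = 500,
) -> pd.DataFrame:
    """One hypergeometric test per (cluster, eligible term); BH within cluster.

    Query genes outside the universe are dropped with a warning.  Returns a
    frame with columns cluster/term/name/namespace/k/K/n/N/p/q/significant,
    sorted by (q, p).
    """
    if not term_map.universe:
        raise ValueError("empty gene universe")
    N = len(term_map.universe)
    eligible = {
        tid: t
        for tid, t in term_map.terms.items()
        if min_term_size <= len(t.genes) <= max_term_size
    }
    frames = []
    for cluster in sorted(gene_sets):
        query = set(gene_sets[cluster])
        dropped = query - term_map.universe
        if dropped:
            warnings.warn(
                f"cluster {cluster}: {len(dropped)} gene(s) outside universe dropped",
                stacklevel=2,
            )
        query &= term_map.universe
        n = len(query)
        if n == 0:
            continue
        rows = []
        for tid in sorted(eligible):
            t = eligible[tid]
            k = len(query & t.genes)
            K = len(t.genes)
            rows.append(
                {
                    "cluster": cluster,
                    "term": tid,
                    "name": t.name,
                    "namespace": t.namespace,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p": hypergeom_upper_tail(k, K, n, N),
                }
            )
        if not rows:
            continue
        sub = pd.DataFrame(rows)
        sub["q"] = bh_adjust(sub["p"])
        frames.append(sub)
    if not frames:
        return pd.DataFrame(
            columns=["cluster", "term", "name", "namespace", "k", "K", "n", "N", "p", "q", "significant"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["q"] <= alpha
    return out.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
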