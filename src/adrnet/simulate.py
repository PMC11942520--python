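"""Seeded synthetic study inputs: panel TSV, per-patient VCFs, clinical CSV,
drug annotations, and a GMT term map.

The generator emulates the structure the analysis assumes: a curated panel
of 326 variants of which 309 survive design filtering, a 70-patient cohort
partitioned into five latent groups of sizes 21/16/27/5/1, each group
owning a disjoint block of panel variants carried with high probability by
its members and low probability by everyone else, an overall ADR
prevalence near 52.8%, and the cohort treatment mix (14 cisplatin, 30
carboplatin — 44 on a platinum doublet — and 17 radiotherapy).  ADR
outcomes follow a logistic model,

    logit P(ADR_i) = logit(base_rate) + sum over received treatments t of
                     effect_log_odds[(cluster_i, t)],

so planted (cluster, treatment) effects are recoverable downstream and a
zero-effect configuration is an exact null.

All randomness flows from one seed through per-patient substreams, so
adding patients never perturbs earlier patients' draws, and a fixed seed
yields a byte-identical file bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._utils import rng_stream
from .cohort import ADR_CATEGORIES, ClinicalTable, GenotypeMatrix
from .clustering import Clustering
from .enrichment import Term, TermGeneMap
from .panel import CATEGORIES, DrugAnnotation, PanelManifest, PanelVariant
from .association import ContingencyTable

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "build_panel",
    "simulate_genotypes",
    "simulate_clinical",
    "simulate_cohort",
    "build_term_map",
    "make_planted_table_cohort",
]

# Drugs used to populate panel annotations.  The first four are the study
# treatments; the rest are common oncology agents used as filler so the
# drug-exclusivity statistics have realistic variety.
TREATMENT_DRUGS = ("cisplatin", "carboplatin", "pemetrexed", "radiotherapy")
FILLER_DRUGS = (
    "docetaxel", "gemcitabine", "paclitaxel", "vinorelbine", "etoposide",
    "irinotecan", "fluorouracil", "methotrexate", "doxorubicin",
    "cyclophosphamide", "ifosfamide", "topotecan", "erlotinib", "gefitinib",
    "afatinib", "osimertinib", "crizotinib", "alectinib", "bevacizumab",
    "nivolumab", "pembrolizumab", "durvalumab", "atezolizumab",
    "capecitabine", "oxaliplatin",
)

# hg19 chromosome lengths for the VCF contig header.
_HG19_LENGTHS = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566, "X": 155270560,
}

# Cohort composition mirrored by the generator (counts over 70 patients).
_STAGE_COUNTS = [
    ("IA", 6), ("IB", 7), ("IIA", 11), ("IIB", 7), ("IIIA", 13), ("IIIB", 6), ("IV", 20),
]
_N_MALE = 49
_ADR_CATEGORY_WEIGHTS = {  # relative frequency among ADR-positive patients
    "hematologic": 14, "gastrointestinal": 7, "asthenia": 13,
    "skin": 2, "pain": 8, "dyspnea": 5,
}


@dataclass
class SimulationConfig:
    n_patients: int = 70
    panel_size: int = 326
    n_design_excluded: int = 15
    n_duplicates: int = 2
    cluster_sizes: tuple = (21, 16, 27, 5, 1)
    within_cluster_carrier_prob: float = 0.8
    between_cluster_carrier_prob: float = 0.05
    adr_base_rate: float = 0.528
    treatment_counts: dict = field(
        default_factory=lambda: {"cisplatin": 14, "carboplatin": 30, "radiotherapy": 17}
    )
    pemetrexed_fraction: float = 0.8  # of carboplatin-treated patients
    effect_log_odds: dict = field(default_factory=dict)  # (cluster, treatment) -> shift
    missing_rate: float = 0.0
    n_genes: int = 176
    n_intergenic: int = 5
    seed: int = 17

    @property
    def n_analyzable(self) -> int:
        return self.panel_size - self.n_design_excluded - self.n_duplicates

    def validate(self) -> None:
        if sum(self.cluster_sizes) != self.n_patients:
            raise ValueError(
                f"cluster sizes {self.cluster_sizes} sum to {sum(self.cluster_sizes)}, "
                f"not n_patients={self.n_patients}"
            )
        for p in (
            self.within_cluster_carrier_prob,
            self.between_cluster_carrier_prob,
            self.adr_base_rate,
            self.missing_rate,
            self.pemetrexed_fraction,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_analyzable <= 0:
            raise ValueError("panel exclusions exceed panel size")
        for t, n in self.treatment_counts.items():
            if not 0 <= n <= self.n_patients:
                raise ValueError(f"treatment count {t}={n} exceeds cohort size")
        if self.n_intergenic > self.n_analyzable:
            raise ValueError("more intergenic variants than analyzable panel rows")


@dataclass
class SyntheticCohort:
    """In-memory bundle plus the simulation truth."""

    config: SimulationConfig
    panel: PanelManifest
    genotypes: GenotypeMatrix
    zygosity: np.ndarray
    clinical: ClinicalTable
    true_labels: dict
    variant_blocks: dict
    term_map: TermGeneMap

    def truth_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["effect_log_odds"] = {
            f"{c}:{t}": v for (c, t), v in self.config.effect_log_odds.items()
        }
        return {
            "config": cfg,
            "true_labels": self.true_labels,
            "variant_blocks": {str(c): sorted(v) for c, v in self.variant_blocks.items()},
        }


def _proportional_split(total: int, weights) -> list:
    """Largest-remainder split of `total` into len(weights) integer parts."""
    weights = np.asarray(weights, dtype=float)
    raw = total * weights / weights.sum()
    parts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - parts))[: total - parts.sum()]:
        parts[i] += 1
    return parts.tolist()


def build_panel(config: SimulationConfig) -> tuple[PanelManifest, dict]:
    """Deterministic panel manifest; returns (manifest, cluster -> variant block).

    Analyzable variants are laid out in coordinate order across the
    autosomes with the final variant on X, split into per-cluster disjoint
    blocks sized proportionally to cluster size.  Genes never span blocks,
    so gene exclusivity is exact on the truth.  Variant 4 is an indel; all
    others are SNVs.  Design-excluded and duplicate rows are appended after
    the analyzable set.
    """
    config.validate()
    n = config.n_analyzable
    k = len(config.cluster_sizes)
    block_sizes = _proportional_split(n, config.cluster_sizes)
    coding = n - config.n_intergenic
    gene_split = _proportional_split(config.n_genes, block_sizes)

    # spread intergenic variants across blocks (at most one per block here)
    intergenic_global = set()
    if config.n_intergenic:
        step = max(1, n // config.n_intergenic)
        i = step - 1
        while len(intergenic_global) < config.n_intergenic:
            intergenic_global.add(i % n)
            i += step

    # chrom/pos layout: contiguous chunks over autosomes, last variant on X
    chrom_of = []
    per_chrom_rank: dict[str, int] = {}
    positions = []
    for i in range(n):
        if i == n - 1:
            chrom = "X"
        else:
            chrom = str(1 + (i * 22) // max(n - 1, 1))
        rank = per_chrom_rank.get(chrom, 0)
        per_chrom_rank[chrom] = rank + 1
        chrom_of.append(chrom)
        positions.append(1_000_000 + 75_000 * rank)

    snv_cycle = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]

    # gene names per block, categories cycling the closed five-way set
    gene_names = []
    gid = 0
    for b in range(k):
        names = []
        for _ in range(max(gene_split[b], 1) if block_sizes[b] else 0):
            gid += 1
            names.append(f"GENE{gid:03d}")
        gene_names.append(names)
    category_of_gene = {}
    for b in range(k):
        for j, gname in enumerate(gene_names[b]):
            category_of_gene[gname] = CATEGORIES[(b + j) % len(CATEGORIES)]

    # drug annotation layout: per-block occurrence counts per drug
    treatment_weights = {
        "radiotherapy": [11, 2, 1, 1, 0],
        "cisplatin": [5, 3, 3, 1, 0],
        "carboplatin": [4, 5, 3, 0, 0],
        "pemetrexed": [2, 5, 2, 1, 0],
    }
    drug_slots: dict[int, list] = {b: [] for b in range(k)}
    for drug, weights in treatment_weights.items():
        for b in range(k):
            drug_slots[b].extend([drug] * (weights[b] if b < len(weights) else 0))
    for j, drug in enumerate(FILLER_DRUGS):
        b = j % (k - 1)  # filler drugs never reach the singleton block
        drug_slots[b].extend([drug] * (1 + j % 3))

    variants = []
    blocks: dict[int, list] = {}
    cursor = 0
    for b in range(k):
        blocks[b] = []
        block_genes = gene_names[b]
        slots = drug_slots[b]
        for j in range(block_sizes[b]):
            i = cursor + j
            rsid = f"rs{1000000 + i}"
            intergenic = i in intergenic_global
            gene = "" if intergenic or not block_genes else block_genes[j % len(block_genes)]
            ref, alt = snv_cycle[i % 4]
            if i == 4:
                ref, alt = "AT", "A"  # the single indel in the analyzable set
            anns = []
            # distribute the block's drug occurrences round-robin over variants
            for s, drug in enumerate(slots):
                if s % block_sizes[b] == j:
                    anns.append(DrugAnnotation(drug, "Toxicity", "synthetic"))
            radio = any(a.drug == "radiotherapy" for a in anns)
            variants.append(
                PanelVariant(
                    rsid=rsid,
                    chrom=chrom_of[i],
                    pos=positions[i],
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    category=category_of_gene.get(gene, "other_target_signaling"),
                    drug_annotations=tuple(anns),
                    radiotoxicity=radio,
                )
            )
            blocks[b].append(rsid)
        cursor += block_sizes[b]

    # design-excluded rows, then duplicate rows, appended after the
    # analyzable set (identities of the excluded rows are arbitrary)
    for j in range(config.n_design_excluded):
        variants.append(
            PanelVariant(
                rsid=f"rs{2000000 + j}",
                chrom=str(1 + j % 22),
                pos=9_000_000 + 75_000 * j,
                ref="A",
                alt="C",
                gene=f"GENE{(j % config.n_genes) + 1:03d}",
                category=CATEGORIES[j % len(CATEGORIES)],
                design_excluded=True,
            )
        )
    for j in range(config.n_duplicates):
        target = variants[j]
        variants.append(
            PanelVariant(
                rsid=f"rs{3000000 + j}",
                chrom=target.chrom,
                pos=target.pos,
                ref=target.ref,
                alt=target.alt,
                gene=target.gene,
                category=target.category,
                duplicate_of=target.rsid,
            )
        )
    manifest = PanelManifest(variants=variants, provenance="synthetic cohort generator")
    return manifest, {b: list(v) for b, v in blocks.items()}


def simulate_genotypes(
    config: SimulationConfig, blocks: dict, labels: np.ndarray
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Per-patient carrier draws over the analyzable panel.

    Patient i's stream is (seed, "genotype", i); each variant is carried
    with the within-block probability if the patient's cluster owns it and
    the between probability otherwise.  Returns the matrix and a parallel
    boolean homozygosity array used only for VCF serialization.
    """
    variant_ids = [rsid for b in sorted(blocks) for rsid in blocks[b]]
    vblock = np.concatenate(
        [np.full(len(blocks[b]), b) for b in sorted(blocks)]
    )
    n_var = len(variant_ids)
    n_pat = config.n_patients
    carrier = np.zeros((n_pat, n_var), dtype=np.int8)
    missing = np.zeros((n_pat, n_var), dtype=np.int8)
    hom = np.zeros((n_pat, n_var), dtype=bool)
    for i in range(n_pat):
        rng = rng_stream(config.seed, "genotype", i)
        p = np.where(
            vblock == labels[i],
            config.within_cluster_carrier_prob,
            config.between_cluster_carrier_prob,
        )
        carrier[i] = rng.random(n_var) < p
        hom[i] = (rng.random(n_var) < 0.3) & (carrier[i] > 0)
        if config.missing_rate > 0:
            miss = rng.random(n_var) < config.missing_rate
            missing[i] = miss
            carrier[i, miss] = 0
            hom[i, miss] = False
    ids = [f"P{i + 1:03d}" for i in range(n_pat)]
    matrix = GenotypeMatrix(
        patient_ids=ids, variant_ids=variant_ids, carrier=carrier, missing_mask=missing
    )
    return matrix, hom


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def simulate_clinical(
    config: SimulationConfig, labels: np.ndarray
) -> ClinicalTable:
    """Treatment assignment and logistic ADR outcomes.

    Cohort-level draws (treatment/stage/sex permutations) use the (seed,
    "clinical") stream; each patient's ADR outcome uses its own (seed,
    "adr", i) stream.
    """
    n = config.n_patients
    rng = rng_stream(config.seed, "clinical")
    ids = [f"P{i + 1:03d}" for i in range(n)]

    order = rng.permutation(n)
    n_cis = config.treatment_counts.get("cisplatin", 0)
    n_carbo = config.treatment_counts.get("carboplatin", 0)
    if n_cis + n_carbo > n:
        raise ValueError("cisplatin + carboplatin counts exceed cohort size")
    cis = set(order[:n_cis])
    carbo_list = list(order[n_cis : n_cis + n_carbo])
    carbo = set(carbo_list)
    n_pem = int(round(config.pemetrexed_fraction * len(carbo_list)))
    pem = set(carbo_list[:n_pem])
    radio = set(rng.permutation(n)[: config.treatment_counts.get("radiotherapy", 0)])

    treatments = []
    for i in range(n):
        ts = []
        if i in cis:
            ts.append("cisplatin")
        if i in carbo:
            ts.append("carboplatin")
        if i in pem:
            ts.append("pemetrexed")
        if i in radio:
            ts.append("radiotherapy")
        if i not in cis and i not in carbo:
            ts.append("other")  # non-platinum systemic therapy
        treatments.append(tuple(ts))

    stages = []
    for stage, count in _STAGE_COUNTS:
        stages.extend([stage] * count)
    stages = _resize(stages, n)
    stages = [stages[j] for j in rng.permutation(n)]
    sexes = _resize(["M"] * _N_MALE + ["F"] * (70 - _N_MALE), n)
    sexes = [sexes[j] for j in rng.permutation(n)]

    base = _logit(config.adr_base_rate)
    cat_names = list(_ADR_CATEGORY_WEIGHTS)
    cat_w = np.array([_ADR_CATEGORY_WEIGHTS[c] for c in cat_names], dtype=float)
    cat_w /= cat_w.sum()

    records = []
    for i in range(n):
        prng = rng_stream(config.seed, "adr", i)
        age = float(np.clip(np.round(prng.normal(69.5, 7.8)), 40, 84))
        shift = sum(
            config.effect_log_odds.get((int(labels[i]), t), 0.0) for t in treatments[i]
        )
        p_adr = 1 / (1 + np.exp(-(base + shift)))
        adr = bool(prng.random() < p_adr)
        cats = ()
        if adr:
            k = 1 + int(prng.random() < 0.3)  # one category, sometimes two
            cats = tuple(sorted(prng.choice(cat_names, size=k, replace=False, p=cat_w)))
            cats = tuple(c for c in ADR_CATEGORIES if c in cats)
        records.append(
            {
                "patient_id": ids[i],
                "age": age,
                "sex": sexes[i],
                "stage": stages[i],
                "treatments": treatments[i],
                "adr_any": adr,
                "adr_categories": cats,
            }
        )
    return ClinicalTable.from_records(records)


def _resize(values: list, n: int) -> list:
    if n <= len(values):
        return values[:n]
    reps = -(-n // len(values))
    return (values * reps)[:n]


def build_term_map(config: SimulationConfig, panel: PanelManifest, blocks: dict) -> TermGeneMap:
    """Flat BP/MF term map over the panel's genes.

    Each cluster block contributes one BP and one MF term over subsets of
    its own genes, plus pooled terms spanning blocks, so per-cluster
    enrichment has signal on the truth.
    """
    genes_by_block = {}
    by_rsid = {v.rsid: v for v in panel}
    for b, rsids in blocks.items():
        genes_by_block[b] = sorted(
            {by_rsid[r].gene for r in rsids if by_rsid[r].gene}
        )
    universe = sorted(set().union(*genes_by_block.values()))
    terms = {}
    for b, genes in genes_by_block.items():
        if len(genes) >= 3:
            terms[f"BP:block{b}_response"] = Term(
                f"BP:block{b}_response", "BP", frozenset(genes[: max(3, len(genes) // 2)])
            )
            terms[f"MF:block{b}_activity"] = Term(
                f"MF:block{b}_activity", "MF", frozenset(genes[max(0, len(genes) // 3):])
            )
    pooled = [g for b in sorted(genes_by_block) for g in genes_by_block[b][:4]]
    if len(pooled) >= 3:
        terms["BP:shared_metabolism"] = Term("BP:shared_metabolism", "BP", frozenset(pooled))
    return TermGeneMap(terms=terms, universe=frozenset(universe))


def _write_vcf(path: Path, sample: str, panel_variants, carrier_row, missing_row, hom_row) -> None:
    chroms = []
    for v in panel_variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##reference=hg19\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={_HG19_LENGTHS[c]}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for j, v in enumerate(panel_variants):
            if missing_row[j]:
                gt = "./."
            elif carrier_row[j] and hom_row[j]:
                gt = "1/1"
            elif carrier_row[j]:
                gt = "0/1"
            else:
                gt = "0/0"
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def simulate_cohort(config: SimulationConfig | None = None, out_dir=None) -> SyntheticCohort:
    """Generate the full synthetic bundle; optionally write it to `out_dir`.

    With an output directory the bundle is written as ``panel.tsv``,
    ``clinical.csv``, ``cohort/<patient>.vcf``, ``annotations.tsv``,
    ``terms.gmt``, ``namespaces.tsv`` and ``truth.json``.  The same config
    and seed always produce byte-identical files.
    """
    if config is None:
        config = SimulationConfig()
    config.validate()
    panel, blocks = build_panel(config)
    labels = np.repeat(
        np.arange(len(config.cluster_sizes)), config.cluster_sizes
    )
    genotypes, hom = simulate_genotypes(config, blocks, labels)
    clinical = simulate_clinical(config, labels)
    term_map = build_term_map(config, panel, blocks)
    cohort = SyntheticCohort(
        config=config,
        panel=panel,
        genotypes=genotypes,
        zygosity=hom,
        clinical=clinical,
        true_labels={pid: int(c) for pid, c in zip(genotypes.patient_ids, labels)},
        variant_blocks=blocks,
        term_map=term_map,
    )
    if out_dir is not None:
        write_bundle(cohort, out_dir)
    return cohort


def write_bundle(cohort: SyntheticCohort, out_dir) -> Path:
    from .panel import write_panel

    out = Path(out_dir)
    (out / "cohort").mkdir(parents=True, exist_ok=True)
    write_panel(cohort.panel, out / "panel.tsv")
    cohort.clinical.to_csv(out / "clinical.csv")
    by_rsid = {v.rsid: v for v in cohort.panel}
    ordered = [by_rsid[r] for r in cohort.genotypes.variant_ids]
    for i, pid in enumerate(cohort.genotypes.patient_ids):
        _write_vcf(
            out / "cohort" / f"{pid}.vcf",
            pid,
            ordered,
            cohort.genotypes.carrier[i],
            cohort.genotypes.missing_mask[i],
            cohort.zygosity[i],
        )
    with open(out / "annotations.tsv", "w") as fh:
        fh.write("rsid\tdrug\tphenotype_category\n")
        for v in cohort.panel:
            for ann in v.drug_annotations:
                fh.write(f"{v.rsid}\t{ann.drug}\t{ann.phenotype_category}\n")
    cohort.term_map.to_gmt(out / "terms.gmt")
    with open(out / "namespaces.tsv", "w") as fh:
        for tid in sorted(cohort.term_map.terms):
            fh.write(f"{tid}\t{cohort.term_map.terms[tid].namespace}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def make_planted_table_cohort(
    table: ContingencyTable,
    treatment: str,
    cluster: int = 0,
    convention: str = "A",
    n_patients: int | None = None,
) -> tuple[ClinicalTable, Clustering]:
    """Deterministic cohort whose contingency table is exactly `table`.

    Under convention A the four cells are treated patients cross-classified
    by cluster membership and ADR status; under convention B they are
    cluster members cross-classified by treatment and ADR status.  Any
    remaining patients are untreated non-ADR patients outside the cluster.
    """
    if table.total == 0:
        raise ValueError("empty table is infeasible")
    if convention not in {"A", "B"}:
        raise ValueError(f"unknown convention {convention!r}")
    n = table.total if n_patients is None else n_patients
    if n < table.total:
        raise ValueError(f"n_patients={n} smaller than table total {table.total}")
    other_cluster = 1 if cluster == 0 else 0
    records = []
    labels = {}

    def add(in_cluster: bool, treated: bool, adr: bool):
        i = len(records)
        pid = f"P{i + 1:03d}"
        ts = (treatment,) if treated else ()
        records.append(
            {
                "patient_id": pid,
                "age": 65.0,
                "sex": "M",
                "stage": "IV",
                "treatments": ts,
                "adr_any": adr,
                "adr_categories": (),
            }
        )
        labels[pid] = cluster if in_cluster else other_cluster

    if convention == "A":
        cells = [
            (True, True, True, table.a),
            (True, True, False, table.b),
            (False, True, True, table.c),
            (False, True, False, table.d),
        ]
    else:
        cells = [
            (True, True, True, table.a),
            (True, True, False, table.b),
            (True, False, True, table.c),
            (True, False, False, table.d),
        ]
    for in_cluster, treated, adr, count in cells:
        for _ in range(count):
            add(in_cluster, treated, adr)
    while len(records) < n:
        add(False, False, False)
    if not any(c != cluster for c in labels.values()):
        # keep two clusters so indices are contiguous
        first_out = f"P{len(records) + 1:03d}"
        records.append(
            {
                "patient_id": first_out,
                "age": 65.0,
                "sex": "M",
                "stage": "IV",
                "treatments": (),
                "adr_any": False,
                "adr_categories": (),
            }
        )
        labels[first_out] = other_cluster
    clinical = ClinicalTable.from_records(records)
    n_clusters = max(labels.values()) + 1
    clustering = Clustering(labels=labels, q=0.0, n_clusters=n_clusters, seed=0)
    return clinical, clustering
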