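"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the shapes of the real study inputs — a reference
collection of complete soil genomes with replicon-resolved arsenic
genotypes, a rooted phylogeny over those genomes, gene-targeted assembly
output (protein variants with coverage-adjusted abundances and per-site
rplB totals) across globally distributed soil sites, and 16S-inferred
organism weights — while planting exact, machine-readable truth so that
downstream recovery is testable without any external download.

Every generator is deterministic: identical arguments and seed give
byte-identical output files.  Truth ledgers are returned alongside the
data and written as ``truth/*.tsv`` next to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import (
    ELEVATED_GENES,
    GENES,
    HIT_COLUMNS,
    TreeDocument,
    write_hit_table,
    write_table,
    write_tree,
    write_variant_fasta,
)

# Approximate per-gene carriage among complete soil genomes (fraction of
# genomes testing positive).  arsM carriage is the one fraction printed in
# the source survey (5.2%); the others echo its per-gene carriage figure
# qualitatively: detoxification genes common, respiratory/oxidase genes rare.
DEFAULT_PREVALENCE: dict[str, float] = {
    "acr3": 0.30,
    "aioA": 0.03,
    "arrA": 0.012,
    "arsB": 0.22,
    "arsC_grx": 0.45,
    "arsC_trx": 0.38,
    "arsD": 0.10,
    "arsM": 0.052,
    "arxA": 0.008,
}

# Plasmid-borne share of each gene's copies, echoing the survey's observed
# plasmid fractions (acr3 6.1%, arsC_grx 4.6%, a single plasmid arsM case;
# oxidase/respiratory genes chromosomal).
DEFAULT_PLASMID_PROB: dict[str, float] = {
    "acr3": 0.061,
    "aioA": 0.0,
    "arrA": 0.0,
    "arsB": 0.05,
    "arsC_grx": 0.046,
    "arsC_trx": 0.06,
    "arsD": 0.08,
    "arsM": 0.01,
    "arxA": 0.0,
}

_PHYLA = (
    "Proteobacteria", "Firmicutes", "Actinobacteria", "Bacteroidetes",
    "Cyanobacteria", "Acidobacteria", "Verrucomicrobia", "Chloroflexi",
    "Planctomycetes", "Gemmatimonadetes", "Euryarchaeota", "Crenarchaeota",
    "Chlamydiae", "Spirochaetes", "Deinococcus-Thermus", "Nitrospirae",
    "Armatimonadetes", "Fusobacteria", "Aquificae", "Thermotogae",
    "Tenericutes", "Chlorobi", "Caldiserica", "Dictyoglomi", "Elusimicrobia",
)

_SOIL_ORDERS = (
    "Mollisol", "Alfisol", "Ultisol", "Andisol", "Inceptisol",
    "Entisol", "Histosol", "Spodosol", "Aridisol", "Oxisol",
)

# continental bounding boxes (lat_min, lat_max, lon_min, lon_max) so that
# geographic distances have real structure for the Mantel test
_REGIONS = (
    ("Brazil", -25.0, -2.0, -62.0, -43.0),
    ("USA", 30.0, 48.0, -120.0, -75.0),
    ("Canada", 52.0, 68.0, -130.0, -95.0),
    ("Russia", 55.0, 68.0, 60.0, 130.0),
    ("Malaysia", 0.5, 6.5, 100.0, 118.0),
)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

TRUE_SCORE_RANGE = (150.0, 2500.0)
TRUE_SCORE_RANGE_ELEVATED = (1100.0, 2500.0)
TRUE_ALIGN_RANGE = (92.0, 100.0)
DECOY_SCORE_RANGE = (20.0, 99.0)
DECOY_ALIGN_RANGE = (10.0, 89.0)
# mid-band decoys for elevated genes: pass the base score rule, fail the
# elevated one, while staying clear of both 100 and 1000 boundaries
DECOY_MID_SCORE_RANGE = (110.0, 990.0)


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

@dataclass
class GenomePlan:
    """Planted truth for one synthetic genome."""

    genome_id: str
    phylum: str
    replicons: list[tuple[str, str]]  # (replicon_id, replicon_type)
    genotype: dict[str, list[tuple[str, int]]]  # gene -> [(location, copies)]


@dataclass
class GenomeFixture:
    plans: list[GenomePlan]
    hits: pd.DataFrame
    genomes: pd.DataFrame
    truth_genotype: pd.DataFrame  # genome_id, gene, chromosome_copies, plasmid_copies
    summary: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "truth").mkdir(parents=True, exist_ok=True)
        write_hit_table(self.hits, out / "hits.tsv")
        write_table(self.genomes, out / "genomes.tsv")
        write_table(self.truth_genotype, out / "truth" / "genotypes.tsv")
        write_table(pd.DataFrame([self.summary]), out / "truth" / "genome_summary.tsv")


def generate_genomes(
    n_genomes: int = 922,
    n_phyla: int = 25,
    genotype_prevalence: Mapping[str, float] | None = None,
    none_fraction: float = 0.143,
    seed: int = 0,
    decoy_rate: float = 0.3,
    plasmid_prob: Mapping[str, float] | None = None,
    adversarial: bool = False,
) -> GenomeFixture:
    """Plant genotypes in *n_genomes* genomes and emit the raw hit table.

    True hits carry scores strictly above the retention thresholds
    (uniform 150-2500; 1100-2500 for aioA/arrA/arxA) and model coverage
    92-100%; decoys fall strictly below a threshold.  Score bands are
    disjoint from the thresholds, so exact planted-genotype recovery by
    the screening cascade is expected, not statistical.  ``adversarial``
    additionally plants hits exactly at the 100 / 1000 / 90% boundaries,
    all of which must be rejected under strict inequalities.
    """
    prevalence = dict(DEFAULT_PREVALENCE if genotype_prevalence is None else genotype_prevalence)
    plasmid_p = dict(DEFAULT_PLASMID_PROB if plasmid_prob is None else plasmid_prob)
    unknown = set(prevalence) - set(GENES)
    if unknown:
        raise ValueError(f"unknown genes in prevalence map: {sorted(unknown)}")
    if not 0 <= none_fraction < 1:
        raise ValueError("none_fraction must be in [0, 1)")
    for g, p in prevalence.items():
        if not 0 <= p <= 1:
            raise ValueError(f"prevalence for {g} outside [0, 1]")
        if p > 0 and p / (1.0 - none_fraction) > 1.0:
            raise ValueError(
                f"infeasible: prevalence {p} for {g} cannot be reached with "
                f"none_fraction {none_fraction}"
            )

    rng = np.random.default_rng(seed)
    phyla = list(_PHYLA[:n_phyla]) + [f"Phylum{i:02d}" for i in range(max(0, n_phyla - len(_PHYLA)))]
    phylum_w = 1.0 / (np.arange(n_phyla) + 1.0)
    phylum_w /= phylum_w.sum()

    plans: list[GenomePlan] = []
    hit_rows: list[tuple] = []
    truth_rows: list[dict] = []

    for i in range(n_genomes):
        gid = f"G{i:04d}"
        phylum = phyla[int(rng.choice(n_phyla, p=phylum_w))]
        n_plasmids = int(rng.choice([0, 1, 2, 3], p=[0.5, 0.3, 0.15, 0.05]))
        replicons = [(f"{gid}_chr1", "chromosome")] + [
            (f"{gid}_p{j + 1}", "plasmid") for j in range(n_plasmids)
        ]
        carrier = bool(rng.random() >= none_fraction)
        genotype: dict[str, list[tuple[str, int]]] = {}
        if carrier:
            q = {g: prevalence.get(g, 0.0) / (1.0 - none_fraction) for g in GENES}
            if sum(q.values()) > 0:
                for _ in range(1000):
                    chosen = [g for g in GENES if rng.random() < q[g]]
                    if chosen:
                        break
                else:  # pragma: no cover - probabilistically unreachable
                    chosen = []
            else:
                chosen = []
            orf_counter = 0
            for gene in chosen:
                copies = int(rng.choice([1, 2, 3], p=[0.85, 0.12, 0.03]))
                placements: list[tuple[str, int]] = []
                for _ in range(copies):
                    # plasmid_prob is the target MARGINAL plasmid share of the
                    # gene's copies; only half the genomes carry any plasmid
                    # under the default inventory, so the conditional draw
                    # compensates by 1 / P(n_plasmids > 0) = 2.
                    on_plasmid = n_plasmids > 0 and rng.random() < min(
                        1.0, 2.0 * plasmid_p.get(gene, 0.0)
                    )
                    if on_plasmid:
                        rep_id, rep_type = replicons[1 + int(rng.integers(n_plasmids))]
                    else:
                        rep_id, rep_type = replicons[0]
                    orf_counter += 1
                    orf_id = f"{gid}_orf{orf_counter:04d}"
                    lo, hi = (
                        TRUE_SCORE_RANGE_ELEVATED if gene in ELEVATED_GENES else TRUE_SCORE_RANGE
                    )
                    score = round(float(rng.uniform(lo, hi)), 2)
                    align = round(float(rng.uniform(*TRUE_ALIGN_RANGE)), 2)
                    hit_rows.append((gid, rep_id, rep_type, orf_id, gene, score, align))
                    placements.append((rep_type, 1))
                genotype[gene] = placements
        else:
            orf_counter = 0

        # decoys: sub-threshold score, sub-threshold alignment, or (for
        # elevated genes) a score between the base and elevated floors
        for _ in range(int(rng.poisson(decoy_rate))):
            gene = GENES[int(rng.integers(len(GENES)))]
            rep_id, rep_type = replicons[int(rng.integers(len(replicons)))]
            orf_counter += 1
            orf_id = f"{gid}_dorf{orf_counter:04d}"
            modes = ["low_score", "low_align"] + (["mid_score"] if gene in ELEVATED_GENES else [])
            mode = modes[int(rng.integers(len(modes)))]
            if mode == "low_score":
                score = round(float(rng.uniform(*DECOY_SCORE_RANGE)), 2)
                align = round(float(rng.uniform(*TRUE_ALIGN_RANGE)), 2)
            elif mode == "low_align":
                lo, hi = (
                    TRUE_SCORE_RANGE_ELEVATED if gene in ELEVATED_GENES else TRUE_SCORE_RANGE
                )
                score = round(float(rng.uniform(lo, hi)), 2)
                align = round(float(rng.uniform(*DECOY_ALIGN_RANGE)), 2)
            else:
                score = round(float(rng.uniform(*DECOY_MID_SCORE_RANGE)), 2)
                align = round(float(rng.uniform(*TRUE_ALIGN_RANGE)), 2)
            hit_rows.append((gid, rep_id, rep_type, orf_id, gene, score, align))

        plans.append(GenomePlan(gid, phylum, replicons, genotype))
        for gene, placements in genotype.items():
            truth_rows.append(
                {
                    "genome_id": gid,
                    "gene": gene,
                    "chromosome_copies": sum(n for loc, n in placements if loc == "chromosome"),
                    "plasmid_copies": sum(n for loc, n in placements if loc == "plasmid"),
                }
            )

    if adversarial and plans:
        gid = plans[0].genome_id
        chrom = plans[0].replicons[0][0]
        hit_rows.append((gid, chrom, "chromosome", f"{gid}_borf0001", "acr3", 100.0, 95.0))
        hit_rows.append((gid, chrom, "chromosome", f"{gid}_borf0002", "aioA", 1000.0, 95.0))
        hit_rows.append((gid, chrom, "chromosome", f"{gid}_borf0003", "arsM", 150.0, 90.0))

    hits = pd.DataFrame(hit_rows, columns=list(HIT_COLUMNS))
    hits = hits.iloc[rng.permutation(len(hits))].reset_index(drop=True)
    genomes = pd.DataFrame(
        {
            "genome_id": [p.genome_id for p in plans],
            "phylum": [p.phylum for p in plans],
            "taxonomy": [f"Bacteria;{p.phylum}" for p in plans],
            "n_plasmids": [len(p.replicons) - 1 for p in plans],
        }
    )
    truth = pd.DataFrame(truth_rows, columns=["genome_id", "gene", "chromosome_copies", "plasmid_copies"])
    n_none = sum(1 for p in plans if not p.genotype)
    summary = {
        "n_genomes": n_genomes,
        "none_count": n_none,
        "none_fraction": n_none / n_genomes,
        "n_true_hits": int(truth["chromosome_copies"].sum() + truth["plasmid_copies"].sum()) if len(truth) else 0,
        "n_hit_rows": len(hits),
    }
    return GenomeFixture(plans, hits, genomes, truth, summary)


# ---------------------------------------------------------------------------
# trees and traits
# ---------------------------------------------------------------------------

def generate_tree(tips: int | Sequence[str], seed: int = 0) -> TreeDocument:
    """Random Yule (pure-birth) tree with exponential waiting times.

    *tips* is either a tip count (labels T0001...) or explicit labels
    (e.g. genome ids); labels are attached to leaves in random order.
    """
    if isinstance(tips, int):
        labels = [f"T{i:04d}" for i in range(tips)]
    else:
        labels = list(tips)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    t = 0.0
    birth: dict[dendropy.Node, float] = {}
    root = tree.seed_node
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        birth[child] = 0.0
        active.append(child)
    while len(active) < n:
        t += float(rng.exponential(1.0 / len(active)))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        node.edge.length = t - birth[node]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth[child] = t
            active.append(child)
    t_end = t + float(rng.exponential(1.0 / n))
    order = rng.permutation(n)
    for node, lab in zip(active, (labels[i] for i in order)):
        node.edge.length = t_end - birth[node]
        node.taxon = taxa.new_taxon(label=lab)
    return TreeDocument(tree)


def simulate_traits_on_tree(
    tree: TreeDocument,
    mode: str,
    prevalence: float,
    seed: int = 0,
    name: str | None = None,
):
    """Binary control traits for the phylogenetic-signal test.

    ``brownian_threshold`` simulates Brownian motion along the tree and
    thresholds tip values at the prevalence quantile (positive control:
    phylogenetic signal present); ``random`` draws i.i.d. Bernoulli tips
    (negative control); ``clustered`` sets the clade whose tip fraction is
    closest to the prevalence to 1 (strong positive control).
    """
    from .phylosignal import TipTrait  # local import to avoid a cycle

    if tree.n_tips < 4:
        raise ValueError("tree must have at least 4 tips")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be strictly between 0 and 1 (degenerate trait)")
    rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    n = len(labels)

    if mode == "brownian_threshold":
        value = {tree.tree.seed_node: 0.0}
        tip_value: dict[str, float] = {}
        for node in tree.tree.preorder_node_iter():
            if node is tree.tree.seed_node:
                continue
            length = node.edge.length or 0.0
            value[node] = value[node.parent_node] + float(rng.normal(0.0, np.sqrt(length)))
            if node.is_leaf():
                tip_value[node.taxon.label] = value[node]
        x = np.array([tip_value[l] for l in labels])
        k = int(np.clip(round(prevalence * n), 1, n - 1))
        top = np.argsort(-x, kind="stable")[:k]
        values = np.zeros(n)
        values[top] = 1.0
    elif mode == "random":
        for _ in range(1000):
            values = (rng.random(n) < prevalence).astype(float)
            if 0 < values.sum() < n:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a non-constant random trait")
    elif mode == "clustered":
        best, best_gap = None, np.inf
        for node in tree.tree.postorder_internal_node_iter():
            clade = [l.taxon.label for l in node.leaf_iter()]
            if not 0 < len(clade) < n:
                continue
            gap = abs(len(clade) / n - prevalence)
            if gap < best_gap:
                best, best_gap = clade, gap
        assert best is not None
        members = set(best)
        values = np.array([1.0 if l in members else 0.0 for l in labels])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TipTrait(name=name or mode, tip_ids=labels, values=values)


# ---------------------------------------------------------------------------
# sites and assembled variants
# ---------------------------------------------------------------------------

@dataclass
class SitePlan:
    """Planted truth for one synthetic soil site."""

    site_id: str
    region: str
    latitude: float
    longitude: float
    rplb_total: int
    variant_pool: dict[str, list[tuple[str, float]]] = field(default_factory=dict)


@dataclass
class SiteFixture:
    plans: list[SitePlan]
    variants: pd.DataFrame  # variant_id, gene, site_id, sequence, abundance
    sites: pd.DataFrame  # site_id, region, latitude, longitude, rplb_total
    community: pd.DataFrame  # site_id, phylum, count
    truth_clusters: pd.DataFrame
    truth_site_gene: pd.DataFrame
    summary: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "truth").mkdir(parents=True, exist_ok=True)
        write_variant_fasta(self.variants, out / "variants.fasta", out / "abundance.tsv")
        write_table(self.sites, out / "sites.tsv")
        write_table(self.community, out / "community.tsv")
        write_table(self.truth_clusters, out / "truth" / "clusters.tsv")
        write_table(self.truth_site_gene, out / "truth" / "site_gene_abundance.tsv")
        write_table(pd.DataFrame([self.summary]), out / "truth" / "site_summary.tsv")


def _mutate(rng: np.random.Generator, seq: np.ndarray, n_subs: int) -> np.ndarray:
    out = seq.copy()
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    for p in pos:
        choices = _AA[_AA != out[p]]
        out[p] = choices[int(rng.integers(len(choices)))]
    return out


def generate_sites(
    n_sites: int = 16,
    genes: Sequence[str] = GENES,
    shared_variant_fraction: float = 0.007,
    variants_per_gene_site: int = 8,
    divergence: float = 0.35,
    within_divergence: float = 0.02,
    second_member_prob: float = 0.2,
    seed: int = 0,
) -> SiteFixture:
    """Plant per-gene variant clusters across sites with known endemicity.

    Each cluster's founder is the gene ancestor mutated at ``divergence``
    of its residues (founders are therefore separated far below the 90%
    identity threshold); within-cluster members differ from the founder at
    <= ``within_divergence`` of residues.  Shared-pool clusters are placed
    at >= 3 sites with an identical residue string at every site; local
    clusters at exactly one site.  The realized endemic fraction is
    recorded in the truth ledger.
    """
    if within_divergence >= divergence:
        raise ValueError("divergence bands overlap: within >= between")
    if divergence < 0.12:
        raise ValueError("between-cluster divergence must be >= 0.12")
    if within_divergence > 0.05:
        raise ValueError("within-cluster divergence must be <= 0.05")
    if shared_variant_fraction > 0 and n_sites < 3:
        raise ValueError("shared variants need at least 3 sites")
    if not 0 <= shared_variant_fraction <= 1:
        raise ValueError("shared_variant_fraction outside [0, 1]")

    rng = np.random.default_rng(seed)

    plans: list[SitePlan] = []
    for i in range(n_sites):
        region, lat_lo, lat_hi, lon_lo, lon_hi = _REGIONS[i % len(_REGIONS)]
        plans.append(
            SitePlan(
                site_id=f"S{i:02d}",
                region=region,
                latitude=round(float(rng.uniform(lat_lo, lat_hi)), 4),
                longitude=round(float(rng.uniform(lon_lo, lon_hi)), 4),
                rplb_total=int(rng.integers(50, 501)),
            )
        )

    # rplB community structure per site: skewed phylum proportions
    alpha = np.array([8.0, 5.0, 4.0, 3.0, 2.0, 1.0, 1.0, 0.5, 0.5, 0.5])
    comm_rows = []
    for plan in plans:
        props = rng.dirichlet(alpha)
        counts = np.round(props * plan.rplb_total).astype(int)
        for phylum, c in zip(_PHYLA[: len(alpha)], counts):
            comm_rows.append({"site_id": plan.site_id, "phylum": phylum, "count": int(c)})

    var_rows: list[dict] = []
    cluster_rows: list[dict] = []
    for gene in genes:
        length = 120 if gene.startswith("arsC") else 150
        ancestor = _AA[rng.integers(len(_AA), size=length)]
        n_clusters = n_sites * variants_per_gene_site
        n_shared = int(round(shared_variant_fraction * n_clusters))
        n_between = max(1, int(round(divergence * length)))
        max_within = max(1, int(round(within_divergence * length)))
        vid_counter = 0
        for c in range(n_clusters):
            founder = _mutate(rng, ancestor, n_between)
            cid = f"{gene}_c{c:04d}"
            shared = c < n_shared
            if shared:
                occ = int(rng.integers(3, min(6, n_sites) + 1))
                site_idx = rng.choice(n_sites, size=occ, replace=False)
                vid_counter += 1
                vid = f"{gene}_v{vid_counter:05d}_{c:04d}"
                seq = "".join(founder)
                sites_here = []
                for si in sorted(site_idx):
                    ab = round(float(rng.uniform(0.5, 30.0)), 3)
                    var_rows.append(
                        {
                            "variant_id": vid, "gene": gene,
                            "site_id": plans[si].site_id, "sequence": seq, "abundance": ab,
                        }
                    )
                    plans[si].variant_pool.setdefault(gene, []).append((vid, ab))
                    sites_here.append(plans[si].site_id)
                n_members = 1
            else:
                si = int(rng.integers(n_sites))
                n_members = 2 if rng.random() < second_member_prob else 1
                member = founder
                sites_here = [plans[si].site_id]
                for m in range(n_members):
                    if m > 0:
                        member = _mutate(rng, founder, int(rng.integers(1, max_within + 1)))
                    vid_counter += 1
                    vid = f"{gene}_v{vid_counter:05d}_{c:04d}"
                    ab = round(float(rng.uniform(0.5, 30.0)), 3)
                    var_rows.append(
                        {
                            "variant_id": vid, "gene": gene,
                            "site_id": plans[si].site_id,
                            "sequence": "".join(member), "abundance": ab,
                        }
                    )
                    plans[si].variant_pool.setdefault(gene, []).append((vid, ab))
            cluster_rows.append(
                {
                    "cluster_id": cid,
                    "gene": gene,
                    "n_members": n_members,
                    "occupancy": len(set(sites_here)),
                    "endemic": len(set(sites_here)) < 3,
                    "sites": ";".join(sorted(set(sites_here))),
                }
            )

    variants = pd.DataFrame(var_rows)
    variants = variants.iloc[rng.permutation(len(variants))].reset_index(drop=True)
    sites = pd.DataFrame(
        {
            "site_id": [p.site_id for p in plans],
            "region": [p.region for p in plans],
            "latitude": [p.latitude for p in plans],
            "longitude": [p.longitude for p in plans],
            "rplb_total": [p.rplb_total for p in plans],
        }
    )
    community = pd.DataFrame(comm_rows)
    truth_clusters = pd.DataFrame(cluster_rows)

    site_gene = (
        variants.groupby(["site_id", "gene"], as_index=False)["abundance"].sum()
        .rename(columns={"abundance": "total_abundance"})
    )
    site_gene = site_gene.merge(sites[["site_id", "rplb_total"]], on="site_id")
    site_gene["normalized"] = site_gene["total_abundance"] / site_gene["rplb_total"]

    n_clusters_total = len(truth_clusters)
    n_endemic = int(truth_clusters["endemic"].sum())
    n_seq = int(truth_clusters["n_members"].sum())
    n_seq_endemic = int(truth_clusters.loc[truth_clusters["endemic"], "n_members"].sum())
    summary = {
        "n_sites": n_sites,
        "n_clusters": n_clusters_total,
        "endemic_count": n_endemic,
        "cosmopolitan_count": n_clusters_total - n_endemic,
        "endemic_fraction": n_endemic / n_clusters_total,
        "endemic_fraction_sequences": n_seq_endemic / n_seq,
        "total_abundance": float(variants["abundance"].sum()),
    }
    return SiteFixture(plans, variants, sites, community, truth_clusters, site_gene, summary)


# ---------------------------------------------------------------------------
# organism weights
# ---------------------------------------------------------------------------

def generate_organism_weights(
    genomes: pd.DataFrame,
    n_samples: int = 38,
    n_soil_orders: int = 7,
    seed: int = 0,
    concentration: float = 0.3,
) -> pd.DataFrame:
    """16S-inferred relative abundances of reference genomes per sample.

    Per-sample weights over all genomes are Dirichlet(concentration) draws
    (sparse, a few dominant organisms) and sum to 1 within 1e-9.  Samples
    are labeled with soil orders round-robin.
    """
    if n_samples < n_soil_orders:
        raise ValueError("need n_samples >= n_soil_orders")
    if n_soil_orders > len(_SOIL_ORDERS):
        raise ValueError(f"at most {len(_SOIL_ORDERS)} soil orders supported")
    rng = np.random.default_rng(seed)
    gids = genomes["genome_id"].astype(str).tolist()
    rows = []
    for s in range(n_samples):
        sample = f"EMP{s:03d}"
        order = _SOIL_ORDERS[s % n_soil_orders]
        w = rng.dirichlet(np.full(len(gids), concentration))
        for gid, wi in zip(gids, w):
            rows.append(
                {"sample_id": sample, "soil_order": order, "genome_id": gid, "weight": float(wi)}
            )
    return pd.DataFrame(rows)
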