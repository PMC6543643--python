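"""Variant clustering and endemism classification across soil sites.

Assembled protein variants of each gene are dereplicated, clustered at 90%
amino-acid identity (greedy, abundance-ordered, UCLUST-style), and each
cluster is classified by occupancy: endemic when present at fewer than
three sites, cosmopolitan at three or more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .abundance import SiteProfiles

#: identity-point margin under the threshold below which the exact-length
#: Hamming prefilter may reject a pair without running the aligner.
_PREFILTER_MARGIN = 8.0


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity between two protein sequences under global alignment.

    Scoring guides the alignment only (match +1, mismatch 0, gap open -5,
    gap extend -1).  Identity = 100 × matches / alignment columns, where
    terminal-gap columns (the ragged overhangs at either end) are excluded
    from the denominator.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 100.0
    aln = _ALIGNER.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    cols = [(x, y) for x, y in zip(sa, sb)]
    start = 0
    while start < len(cols) and ("-" in cols[start]):
        start += 1
    end = len(cols)
    while end > start and ("-" in cols[end - 1]):
        end -= 1
    core = cols[start:end]
    if not core:
        return 0.0
    matches = sum(x == y for x, y in core)
    return 100.0 * matches / len(core)


def _hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)


def dereplicate(variants: pd.DataFrame) -> pd.DataFrame:
    """Merge exact-duplicate sequences within a gene, per site.

    Abundances are summed per (gene, sequence, site); the retained
    variant_id is the lexicographically smallest of the merged ids, so the
    result does not depend on input row order.  Total abundance is
    conserved.
    """
    required = {"variant_id", "gene", "site_id", "sequence", "abundance"}
    if not required <= set(variants.columns):
        raise ValueError(f"variant table needs columns {sorted(required)}")
    out = (
        variants.groupby(["gene", "sequence", "site_id"], as_index=False)
        .agg(variant_id=("variant_id", "min"), abundance=("abundance", "sum"))
    )
    return out[["variant_id", "gene", "site_id", "sequence", "abundance"]].sort_values(
        ["gene", "variant_id", "site_id"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class VariantCluster:
    """One 90%-identity cluster of a gene's assembled variants."""

    cluster_id: str
    gene: str
    centroid_id: str
    centroid_sequence: str
    member_ids: list[str] = field(default_factory=list)
    member_sequences: list[str] = field(default_factory=list)
    site_abundance: dict[str, float] = field(default_factory=dict)

    @property
    def occupancy(self) -> int:
        return sum(1 for v in self.site_abundance.values() if v > 0)

    @property
    def total_abundance(self) -> float:
        return float(sum(self.site_abundance.values()))


def greedy_cluster(
    variants: pd.DataFrame,
    identity_threshold: float = 90.0,
    use_prefilter: bool = True,
) -> list[VariantCluster]:
    """Greedy centroid clustering of dereplicated variants, within gene.

    Distinct sequences are processed in order of decreasing total
    abundance (ties: longer sequence first, then smallest variant_id); a
    sequence joins the first centroid, in founding order, with identity >=
    the threshold, else founds a new cluster.  Deterministic; membership
    is a partition of the input sequences.

    When two sequences have equal length, a Hamming-identity prefilter
    skips the aligner for pairs more than 8 identity points below the
    threshold (gapped realignment cannot bridge that margin at the gap
    penalties used); near-threshold pairs are always verified by the
    aligner.
    """
    derep = dereplicate(variants)
    clusters: list[VariantCluster] = []
    for gene, sub in derep.groupby("gene", sort=True):
        per_seq = (
            sub.groupby("sequence")
            .agg(total=("abundance", "sum"), vid=("variant_id", "min"))
            .reset_index()
        )
        per_seq["length"] = per_seq["sequence"].str.len()
        per_seq = per_seq.sort_values(
            ["total", "length", "vid"], ascending=[False, False, True], kind="mergesort"
        )
        site_ab = sub.groupby(["sequence", "site_id"])["abundance"].sum()

        gene_clusters: list[VariantCluster] = []
        for row in per_seq.itertuples(index=False):
            seq = row.sequence
            home = None
            for cl in gene_clusters:
                cen = cl.centroid_sequence
                if use_prefilter and len(cen) == len(seq):
                    if _hamming_identity(cen, seq) < identity_threshold - _PREFILTER_MARGIN:
                        continue
                if pairwise_identity(cen, seq) >= identity_threshold:
                    home = cl
                    break
            if home is None:
                home = VariantCluster(
                    cluster_id=f"{gene}_c{len(gene_clusters):04d}",
                    gene=gene,
                    centroid_id=row.vid,
                    centroid_sequence=seq,
                )
                gene_clusters.append(home)
            home.member_ids.append(row.vid)
            home.member_sequences.append(seq)
            for site, ab in site_ab.loc[seq].items():
                home.site_abundance[site] = home.site_abundance.get(site, 0.0) + float(ab)
        clusters.extend(gene_clusters)
    return clusters


def clusters_table(clusters: list[VariantCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "gene": [c.gene for c in clusters],
            "centroid_id": [c.centroid_id for c in clusters],
            "n_members": [len(c.member_ids) for c in clusters],
            "occupancy": [c.occupancy for c in clusters],
            "total_abundance": [c.total_abundance for c in clusters],
        }
    )


def abundance_occurrence_table(clusters: list[VariantCluster]) -> pd.DataFrame:
    """Long table (cluster × site) of summed abundances, for occupancy plots."""
    rows = []
    for c in clusters:
        for site, ab in sorted(c.site_abundance.items()):
            rows.append(
                {"cluster_id": c.cluster_id, "gene": c.gene, "site_id": site, "abundance": ab}
            )
    return pd.DataFrame(rows)


def classify_occupancy(
    clusters: list[VariantCluster], min_cosmopolitan_sites: int = 3
) -> tuple[pd.DataFrame, dict]:
    """Label clusters endemic (< 3 sites) vs cosmopolitan (>= 3 sites).

    Returns the labeled cluster table and a summary with counts, the
    endemic proportion over clusters (default denominator) and over
    dereplicated sequences, and the gene composition of the cosmopolitan
    clusters.
    """
    tab = clusters_table(clusters)
    tab["endemic"] = tab["occupancy"] < min_cosmopolitan_sites
    n_endemic = int(tab["endemic"].sum())
    n_cosmo = int((~tab["endemic"]).sum())
    n_seq_endemic = int(tab.loc[tab["endemic"], "n_members"].sum())
    n_seq_total = int(tab["n_members"].sum())
    cosmo = tab[~tab["endemic"]]
    composition = (
        (cosmo.groupby("gene").size() / len(cosmo)).to_dict() if len(cosmo) else {}
    )
    summary = {
        "n_clusters": len(tab),
        "endemic_count": n_endemic,
        "cosmopolitan_count": n_cosmo,
        "endemic_proportion": n_endemic / len(tab) if len(tab) else float("nan"),
        "endemic_proportion_sequences": (
            n_seq_endemic / n_seq_total if n_seq_total else float("nan")
        ),
        "cosmopolitan_gene_composition": composition,
    }
    return tab, summary


def rank_abundance(profiles: SiteProfiles) -> pd.DataFrame:
    """Sites ordered by mean rplB-normalized abundance (ties: site id)."""
    if len(profiles.sites) == 0:
        raise ValueError("no sites")
    means = profiles.normalized.mean(axis=1, skipna=True)
    order = pd.DataFrame(
        {"site_id": list(means.index), "mean_abundance": means.to_numpy()}
    ).sort_values(["mean_abundance", "site_id"], ascending=[False, True], kind="mergesort")
    order["rank"] = np.arange(1, len(order) + 1)
    return order.reset_index(drop=True)
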