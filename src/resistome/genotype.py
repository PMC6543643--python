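"""Genome-level genotype summaries: who carries which gene, where, how often.

The central object is the genotype matrix: for every genome and every gene,
the number of retained hits on chromosomes and on plasmids.  Genomes with
no retained hits stay in the matrix as all-zero rows — "none" genomes are a
result, not missing data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GENES

LOCATIONS = ("chromosome", "plasmid")


@dataclass
class GenotypeMatrix:
    """genome × (gene, location) copy counts with per-genome phylum labels.

    ``counts`` has a row per genome and a two-level column index
    (gene, location); ``phylum`` is aligned to ``counts.index``.
    """

    counts: pd.DataFrame
    phylum: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.phylum.index):
            raise ValueError("phylum labels not aligned to genotype rows")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative copy count")

    @property
    def n_genomes(self) -> int:
        return len(self.counts)

    def total_copies(self) -> pd.DataFrame:
        """genome × gene total copies (chromosome + plasmid)."""
        return self.counts.T.groupby(level="gene").sum().T

    def carriers(self) -> pd.DataFrame:
        """genome × gene boolean: at least one copy at either location."""
        return self.total_copies() > 0


def build_genotype_matrix(hits: pd.DataFrame, genomes: pd.DataFrame) -> GenotypeMatrix:
    """Tally screened, deduped, annotated hits into a genotype matrix.

    Every genome in *genomes* appears, including zero-hit genomes.
    """
    index = pd.Index(genomes["genome_id"].astype(str), name="genome_id")
    if index.has_duplicates:
        raise ValueError("duplicate genome_id in metadata")
    columns = pd.MultiIndex.from_product([GENES, LOCATIONS], names=["gene", "location"])
    counts = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    if len(hits):
        tally = (
            hits.groupby(["genome_id", "gene", "replicon_type"], observed=True)
            .size()
            .reset_index(name="n")
        )
        for row in tally.itertuples(index=False):
            counts.loc[row.genome_id, (row.gene, row.replicon_type)] += row.n
    phylum = genomes.set_index(genomes["genome_id"].astype(str))["phylum"].reindex(index)
    return GenotypeMatrix(counts=counts, phylum=phylum)


def none_fraction(matrix: GenotypeMatrix) -> tuple[int, float]:
    """Count and proportion of genomes with no retained gene at all."""
    if matrix.n_genomes == 0:
        raise ValueError("empty genotype matrix")
    none = (matrix.counts.sum(axis=1) == 0)
    return int(none.sum()), float(none.mean())


def phylum_gene_proportions(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per gene, carrier counts and proportions by phylum.

    A carrier is a genome with >= 1 copy at either location.  Proportions
    for each gene sum to 1 over the phyla of its carriers; genes with no
    carriers appear with a single flagged row (n_carriers = 0).
    """
    carriers = matrix.carriers()
    rows = []
    for gene in GENES:
        sub = matrix.phylum[carriers[gene]]
        if sub.empty:
            rows.append({"gene": gene, "phylum": pd.NA, "n_carriers": 0, "proportion": np.nan})
            continue
        tab = sub.value_counts()
        for phylum, n in tab.items():
            rows.append(
                {
                    "gene": gene,
                    "phylum": phylum,
                    "n_carriers": int(n),
                    "proportion": float(n / tab.sum()),
                }
            )
    return pd.DataFrame(rows)


def copy_number_histogram(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Distribution of total (chromosome + plasmid) copies per carrier genome."""
    total = matrix.total_copies()
    rows = []
    for gene in GENES:
        col = total[gene]
        col = col[col > 0]
        for copies, n in col.value_counts().sort_index().items():
            rows.append({"gene": gene, "total_copies": int(copies), "n_genomes": int(n)})
    return pd.DataFrame(rows, columns=["gene", "total_copies", "n_genomes"])


def plasmid_fraction(matrix: GenotypeMatrix, gene: str) -> float:
    """Fraction of a gene's retained copies that are plasmid-borne."""
    chrom = int(matrix.counts[(gene, "chromosome")].sum())
    plas = int(matrix.counts[(gene, "plasmid")].sum())
    if chrom + plas == 0:
        raise ValueError(f"no retained hits for {gene}")
    return plas / (chrom + plas)
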