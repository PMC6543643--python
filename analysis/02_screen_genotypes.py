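"""Screen raw hits and profile arsenic genotypes across the genome collection.

Applies the retention cascade (score > 100, alignment > 90%, score > 1000
for aioA/arrA/arxA, best hit per ORF), builds the genome x gene x location
genotype matrix, and writes the genotype summaries: the fraction of
genomes with no arsenic-related gene, carrier proportions by phylum,
per-gene copy-number histograms, and plasmid-borne fractions.
"""

import argparse
from pathlib import Path

import pandas as pd

from resistome import genotype, io, screening


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = args.out / "data"
    hits = io.read_hit_table(data / "genomes" / "hits.tsv")
    genomes = io.read_table(data / "genomes" / "genomes.tsv")

    retained, report = screening.screen_hits(hits)
    deduped = screening.dedup_orfs(retained)
    annotated = screening.annotate_hits(deduped, genomes)
    print(
        f"screening: {report.n_input} hits -> {report.n_retained} retained "
        f"(score {report.n_rejected_score}, alignment {report.n_rejected_alignment}, "
        f"elevated {report.n_rejected_elevated} rejected), {len(deduped)} after ORF dedup"
    )

    gm = genotype.build_genotype_matrix(annotated, genomes)
    count, prop = genotype.none_fraction(gm)
    print(f"genomes with no arsenic-related gene: {count} ({100 * prop:.1f}%)")

    out = args.out / "genotype"
    out.mkdir(parents=True, exist_ok=True)
    io.write_hit_table(deduped, out / "retained_hits.tsv")

    wide = gm.counts.copy()
    wide.columns = [f"{g}:{loc}" for g, loc in wide.columns]
    wide.insert(0, "phylum", gm.phylum)
    wide.reset_index().to_csv(out / "genotype_matrix.tsv", sep="\t", index=False)

    io.write_table(genotype.phylum_gene_proportions(gm), out / "phylum_proportions.tsv")
    io.write_table(genotype.copy_number_histogram(gm), out / "copy_number_histogram.tsv")

    rows = []
    for gene in io.GENES:
        try:
            frac = genotype.plasmid_fraction(gm, gene)
        except ValueError:
            continue
        rows.append({"gene": gene, "plasmid_fraction": frac})
        print(f"plasmid-borne share of {gene}: {100 * frac:.1f}%")
    io.write_table(pd.DataFrame(rows), out / "plasmid_fractions.tsv")


if __name__ == "__main__":
    main()
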