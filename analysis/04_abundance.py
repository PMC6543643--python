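"""Estimate arsenic-gene abundances two ways and compare gene groups.

Cultivation-dependent: expected copies per genome under 16S-inferred
organism weights, averaged by soil order.  Cultivation-independent:
per-site assembled gene counts normalized by rplB.  Mann-Whitney U tests
compare detoxification genes (acr3, arsB, arsC_grx, arsC_trx, arsD)
against metabolism genes (aioA, arrA, arsM, arxA), and the classic
within-mechanism pairs.
"""

import argparse
from pathlib import Path

import pandas as pd

from resistome import abundance, genotype, io, screening, stats

DETOX = ("acr3", "arsB", "arsC_grx", "arsC_trx", "arsD")
METABOLISM = ("aioA", "arrA", "arsM", "arxA")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = args.out / "data"
    hits = io.read_hit_table(data / "genomes" / "hits.tsv")
    genomes = io.read_table(data / "genomes" / "genomes.tsv")
    annotated, _ = screening.screen_cascade(hits, genomes)
    gm = genotype.build_genotype_matrix(annotated, genomes)

    out = args.out / "abundance"
    out.mkdir(parents=True, exist_ok=True)

    weights = io.read_table(data / "organism_weights.tsv")
    est, by_order = abundance.cultivation_weighted_abundance(gm, weights)
    est.reset_index().to_csv(out / "weighted_by_sample.tsv", sep="\t", index=False)
    by_order.reset_index().to_csv(out / "weighted_by_soil_order.tsv", sep="\t", index=False)

    detox = est[list(DETOX)].to_numpy().ravel()
    metab = est[list(METABOLISM)].to_numpy().ravel()
    res = stats.mann_whitney(detox, metab)
    print(
        f"cultivation-weighted: detoxification vs metabolism genes "
        f"U = {res.U:.1f}, p = {res.p_value:.2e} ({res.method})"
    )
    for a, b in (("acr3", "arsB"), ("arsC_grx", "arsC_trx")):
        r = stats.mann_whitney(est[a], est[b])
        print(f"cultivation-weighted: {a} vs {b} p = {r.p_value:.2e}")

    variants = io.read_variant_fasta(
        data / "sites" / "variants.fasta", data / "sites" / "abundance.tsv"
    )
    sites = io.read_table(data / "sites" / "sites.tsv")
    counts = (
        variants.groupby(["site_id", "gene"], as_index=False)["abundance"].sum()
        .rename(columns={"abundance": "count"})
    )
    prof = abundance.rplb_normalize(
        counts, sites.set_index("site_id")["rplb_total"],
        coordinates=sites[["site_id", "latitude", "longitude"]],
    )
    prof.normalized.reset_index().to_csv(out / "rplb_normalized.tsv", sep="\t", index=False)
    io.write_table(
        abundance.gene_summaries(prof).reset_index(names="gene"),
        out / "gene_summaries_conservative.tsv",
    )

    ref = abundance.refsoil_normalized_abundance(gm)
    io.write_table(
        ref.rename("per_genome_abundance").reset_index(),
        out / "reference_normalized.tsv",
    )
    print("reference-collection per-genome abundance (top 3):")
    print(ref.sort_values(ascending=False).head(3).to_string())

    community = io.read_table(data / "sites" / "community.tsv")
    io.write_table(abundance.community_structure(community), out / "community_structure.tsv")


if __name__ == "__main__":
    main()
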