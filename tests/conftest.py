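"""Shared fixtures: small planted datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from resistome import genotype, io, screening, synth


@pytest.fixture(scope="session")
def genome_fixture():
    """200 synthetic genomes with planted genotypes and decoy hits."""
    return synth.generate_genomes(n_genomes=200, seed=7)


@pytest.fixture(scope="session")
def screened_matrix(genome_fixture):
    """Genotype matrix recovered by running the full screening cascade."""
    annotated, _ = screening.screen_cascade(genome_fixture.hits, genome_fixture.genomes)
    return genotype.build_genotype_matrix(annotated, genome_fixture.genomes)


@pytest.fixture(scope="session")
def tree64():
    return synth.generate_tree(64, seed=3)


@pytest.fixture(scope="session")
def vcv64(tree64):
    from resistome.phylosignal import phylo_vcv

    return phylo_vcv(tree64)


@pytest.fixture(scope="session")
def site_fixture():
    """Small 6-site fixture with a planted 10% shared-cluster pool."""
    return synth.generate_sites(
        n_sites=6,
        genes=("acr3", "arsC_grx", "arsM"),
        shared_variant_fraction=0.1,
        variants_per_gene_site=3,
        seed=11,
    )


@pytest.fixture()
def tiny_hits():
    """Hand-written hit table covering both replicon types and a multi-hit ORF."""
    return pd.DataFrame(
        {
            "genome_id": ["G1", "G1", "G1", "G2"],
            "replicon_id": ["G1_chr1", "G1_chr1", "G1_p1", "G2_chr1"],
            "replicon_type": ["chromosome", "chromosome", "plasmid", "chromosome"],
            "orf_id": ["G1_orf1", "G1_orf1", "G1_orf2", "G2_orf1"],
            "gene": ["acr3", "arsB", "arsC_grx", "arsM"],
            "score": [150.0, 120.0, 400.0, 2000.0],
            "percent_alignment": [95.0, 96.0, 99.0, 93.0],
        }
    )


@pytest.fixture()
def tiny_genomes():
    return pd.DataFrame(
        {
            "genome_id": ["G1", "G2", "G3"],
            "phylum": ["Proteobacteria", "Firmicutes", "Proteobacteria"],
            "taxonomy": ["Bacteria;Proteobacteria", "Bacteria;Firmicutes", "Bacteria;Proteobacteria"],
            "n_plasmids": [1, 0, 0],
        }
    )
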