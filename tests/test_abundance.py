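"""Cultivation-weighted and rplB-normalized abundance estimators."""

import numpy as np
import pandas as pd
import pytest

from resistome import abundance, genotype, synth
from resistome.io import GENES


def _matrix(copies: dict[str, dict[str, int]], phyla=None):
    """Build a GenotypeMatrix from {genome: {gene: chromosome copies}}."""
    genomes = sorted(copies)
    cols = pd.MultiIndex.from_product([GENES, ("chromosome", "plasmid")],
                                      names=["gene", "location"])
    counts = pd.DataFrame(0, index=pd.Index(genomes, name="genome_id"), columns=cols)
    for g, genes in copies.items():
        for gene, n in genes.items():
            counts.loc[g, (gene, "chromosome")] = n
    phylum = pd.Series(phyla or "Proteobacteria", index=counts.index)
    return genotype.GenotypeMatrix(counts=counts, phylum=phylum)


def _weights(rows):
    return pd.DataFrame(rows, columns=["sample_id", "soil_order", "genome_id", "weight"])


class TestCultivationWeighted:
    def test_expectation_arithmetic(self):
        gm = _matrix({"G1": {"acr3": 1}, "G2": {}})
        w = _weights([("s1", "Mollisol", "G1", 0.5), ("s1", "Mollisol", "G2", 0.5)])
        est, _ = abundance.cultivation_weighted_abundance(gm, w)
        assert est.loc["s1", "acr3"] == pytest.approx(0.5)

    def test_all_weight_on_zero_copy_genome(self):
        gm = _matrix({"G1": {"acr3": 1}, "G2": {}})
        w = _weights([("s1", "Mollisol", "G2", 1.0)])
        est, _ = abundance.cultivation_weighted_abundance(gm, w)
        assert est.loc["s1", "acr3"] == 0.0

    def test_gene_in_half_the_genomes_under_uniform_weights_gives_half(self):
        gm = _matrix({f"G{i}": ({"arsM": 1} if i < 5 else {}) for i in range(10)})
        w = _weights([("s1", "Alfisol", f"G{i}", 0.1) for i in range(10)])
        est, _ = abundance.cultivation_weighted_abundance(gm, w)
        assert est.loc["s1", "arsM"] == pytest.approx(0.5)

    def test_dirichlet_fixture_matches_brute_force_dot_product(self, screened_matrix):
        genomes = pd.DataFrame({"genome_id": screened_matrix.counts.index})
        w = synth.generate_organism_weights(genomes, n_samples=6, n_soil_orders=3, seed=2)
        est, by_order = abundance.cultivation_weighted_abundance(screened_matrix, w)
        total = screened_matrix.total_copies()
        for sample, sub in w.groupby("sample_id"):
            vec = sub.set_index("genome_id")["weight"].reindex(total.index).fillna(0.0)
            for gene in GENES:
                brute = float(vec.to_numpy() @ total[gene].to_numpy())
                assert est.loc[sample, gene] == pytest.approx(brute, abs=1e-12)
        assert set(by_order.index) == set(w["soil_order"])

    def test_linear_in_weights(self):
        gm = _matrix({"G1": {"acr3": 2}, "G2": {"acr3": 1}})
        wa = _weights([("s", "o", "G1", 1.0), ("s", "o", "G2", 0.0)])
        wb = _weights([("s", "o", "G1", 0.0), ("s", "o", "G2", 1.0)])
        wmix = _weights([("s", "o", "G1", 0.3), ("s", "o", "G2", 0.7)])
        ea, _ = abundance.cultivation_weighted_abundance(gm, wa)
        eb, _ = abundance.cultivation_weighted_abundance(gm, wb)
        em, _ = abundance.cultivation_weighted_abundance(gm, wmix)
        assert em.loc["s", "acr3"] == pytest.approx(
            0.3 * ea.loc["s", "acr3"] + 0.7 * eb.loc["s", "acr3"]
        )

    def test_unnormalized_weights_raise(self):
        gm = _matrix({"G1": {"acr3": 1}})
        with pytest.raises(ValueError, match="not normalized"):
            abundance.cultivation_weighted_abundance(
                gm, _weights([("s1", "o", "G1", 0.7)])
            )

    def test_unknown_genome_raises(self):
        gm = _matrix({"G1": {"acr3": 1}})
        with pytest.raises(KeyError, match="GX"):
            abundance.cultivation_weighted_abundance(
                gm, _weights([("s1", "o", "GX", 1.0)])
            )


class TestRplbNormalize:
    def _profiles(self):
        counts = pd.DataFrame(
            {"site_id": ["A", "A", "B"], "gene": ["acr3", "arsM", "acr3"],
             "count": [5.0, 2.0, 3.0]}
        )
        totals = pd.Series([10.0, 30.0], index=pd.Index(["A", "B"], name="site_id"))
        return abundance.rplb_normalize(counts, totals)

    def test_ratio_arithmetic(self):
        prof = self._profiles()
        assert prof.normalized.loc["A", "acr3"] == pytest.approx(0.5)
        assert prof.normalized.loc["B", "acr3"] == pytest.approx(0.1)

    def test_not_detected_is_nan_not_zero(self):
        prof = self._profiles()
        assert np.isnan(prof.normalized.loc["B", "arsM"])

    def test_depth_invariance_under_rescaling(self):
        counts = pd.DataFrame(
            {"site_id": ["A", "A"], "gene": ["acr3", "arsM"], "count": [5.0, 2.0]}
        )
        totals = pd.Series([10.0], index=pd.Index(["A"], name="site_id"))
        base = abundance.rplb_normalize(counts, totals)
        scaled = abundance.rplb_normalize(
            counts.assign(count=counts["count"] * 7), totals * 7
        )
        pd.testing.assert_frame_equal(base.normalized, scaled.normalized)

    def test_zero_rplb_total_is_error(self):
        counts = pd.DataFrame({"site_id": ["A"], "gene": ["acr3"], "count": [5.0]})
        with pytest.raises(ValueError, match="rplB"):
            abundance.rplb_normalize(counts, pd.Series([0.0], index=["A"]))

    def test_fixture_matches_generator_ledger(self, site_fixture):
        counts = site_fixture.variants.groupby(["site_id", "gene"], as_index=False)[
            "abundance"
        ].sum().rename(columns={"abundance": "count"})
        totals = site_fixture.sites.set_index("site_id")["rplb_total"]
        prof = abundance.rplb_normalize(counts, totals)
        for row in site_fixture.truth_site_gene.itertuples():
            assert prof.normalized.loc[row.site_id, row.gene] == pytest.approx(
                row.normalized, abs=1e-12
            )

    def test_conservative_summary_ignores_non_detections(self):
        prof = self._profiles()
        cons = abundance.gene_summaries(prof)
        wide = abundance.gene_summaries(prof, include_zeros=True)
        assert cons.loc["arsM", "median"] == pytest.approx(0.2)  # site A only
        assert wide.loc["arsM", "median"] == pytest.approx(0.1)  # zero-filled site B


class TestComposition:
    def test_proportions(self):
        counts = pd.DataFrame(
            {"site_id": ["A", "A"], "gene": ["acr3", "arsM"], "count": [3.0, 1.0]}
        )
        prof = abundance.rplb_normalize(counts, pd.Series([10.0], index=["A"]))
        comp = abundance.relative_gene_composition(prof)
        assert comp.loc["A", "acr3"] == pytest.approx(0.75)
        assert comp.loc["A", "arsM"] == pytest.approx(0.25)

    def test_single_gene_site_is_one(self):
        counts = pd.DataFrame({"site_id": ["A"], "gene": ["acr3"], "count": [3.0]})
        prof = abundance.rplb_normalize(counts, pd.Series([10.0], index=["A"]))
        assert abundance.relative_gene_composition(prof).loc["A", "acr3"] == 1.0

    def test_rows_sum_to_one_on_fixture(self, site_fixture):
        counts = site_fixture.variants.groupby(["site_id", "gene"], as_index=False)[
            "abundance"
        ].sum().rename(columns={"abundance": "count"})
        totals = site_fixture.sites.set_index("site_id")["rplb_total"]
        comp = abundance.relative_gene_composition(abundance.rplb_normalize(counts, totals))
        np.testing.assert_allclose(comp.sum(axis=1, skipna=True), 1.0, atol=1e-9)


class TestReferenceNormalized:
    def test_copies_over_genomes(self):
        gm = _matrix({f"G{i}": ({"acr3": 1} if i < 5 else {}) for i in range(10)})
        out = abundance.refsoil_normalized_abundance(gm)
        assert out["acr3"] == pytest.approx(0.5)
        assert out["arrA"] == 0.0


class TestCommunityStructure:
    def test_single_phylum_site(self):
        tab = abundance.community_structure(
            pd.DataFrame({"site_id": ["A"], "phylum": ["Proteobacteria"], "count": [10]})
        )
        assert tab["proportion"].iloc[0] == 1.0 and tab["is_top"].iloc[0]

    def test_seven_equal_phyla_no_warning(self, recwarn):
        df = pd.DataFrame(
            {"site_id": "A", "phylum": [f"P{i}" for i in range(7)], "count": 10}
        )
        tab = abundance.community_structure(df)
        assert tab[tab["is_top"]]["proportion"].sum() == pytest.approx(6 / 7)
        assert not recwarn.list

    def test_warns_when_top_six_cover_too_little(self):
        df = pd.DataFrame(
            {"site_id": "A", "phylum": [f"P{i}" for i in range(20)], "count": 5}
        )
        with pytest.warns(UserWarning, match="cover"):
            abundance.community_structure(df)

    def test_all_zero_site_is_error(self):
        df = pd.DataFrame({"site_id": ["A"], "phylum": ["P"], "count": [0]})
        with pytest.raises(ValueError, match="all-zero"):
            abundance.community_structure(df)

    def test_matches_brute_force_group_by(self, site_fixture):
        tab = abundance.community_structure(site_fixture.community)
        for site, sub in site_fixture.community.groupby("site_id"):
            brute = sub.groupby("phylum")["count"].sum()
            brute = brute / brute.sum()
            got = tab[tab["site_id"] == site].set_index("phylum")["proportion"]
            pd.testing.assert_series_equal(
                got.sort_index(), brute.sort_index(), check_names=False
            )
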