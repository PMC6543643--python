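"""Pairwise identity, greedy 90% clustering, endemic/cosmopolitan labels."""

import numpy as np
import pandas as pd
import pytest
from oracles import gotoh_score

from resistome import abundance, endemism


AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_seq(rng, n):
    return "".join(rng.choice(list(AA), size=n))


def _mutate(rng, seq, k):
    pos = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([c for c in AA if c != out[p]])
    return "".join(out)


def _variants(rows):
    return pd.DataFrame(
        rows, columns=["variant_id", "gene", "site_id", "sequence", "abundance"]
    )


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        rng = np.random.default_rng(0)
        s = _random_seq(rng, 100)
        assert endemism.pairwise_identity(s, s) == 100.0

    def test_ten_substitutions_in_hundred(self):
        rng = np.random.default_rng(1)
        a = _random_seq(rng, 100)
        b = _mutate(rng, a, 10)
        assert endemism.pairwise_identity(a, b) == pytest.approx(90.0)

    def test_internal_deletion_counts_gap_columns(self):
        rng = np.random.default_rng(2)
        a = _random_seq(rng, 100)
        b = a[:40] + a[45:]  # 5-residue internal deletion, no terminal gaps
        b = _mutate(np.random.default_rng(3), b, 0)
        assert endemism.pairwise_identity(a, b) == pytest.approx(95.0)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = _random_seq(rng, int(rng.integers(50, 150)))
            b = _random_seq(rng, int(rng.integers(50, 150)))
            assert endemism.pairwise_identity(a, b) == pytest.approx(
                endemism.pairwise_identity(b, a)
            )

    def test_alignment_score_matches_gotoh_oracle(self):
        from resistome.endemism import _ALIGNER

        rng = np.random.default_rng(5)
        for _ in range(15):
            a = _random_seq(rng, int(rng.integers(20, 60)))
            b = _random_seq(rng, int(rng.integers(20, 60)))
            assert _ALIGNER.score(a, b) == pytest.approx(gotoh_score(a, b))

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            endemism.pairwise_identity("", "ACD")


class TestDereplicate:
    def test_merges_exact_duplicates_and_sums_abundance(self):
        v = _variants(
            [
                ("v1", "acr3", "S1", "ACDEF", 2.0),
                ("v2", "acr3", "S1", "ACDEF", 3.0),
                ("v3", "acr3", "S2", "ACDEF", 1.0),
            ]
        )
        out = endemism.dereplicate(v)
        s1 = out[out["site_id"] == "S1"]
        assert len(s1) == 1 and s1["abundance"].iloc[0] == 5.0 and s1["variant_id"].iloc[0] == "v1"
        assert len(out) == 2  # S2 record kept separate

    def test_no_duplicates_is_identity_up_to_order(self):
        v = _variants(
            [("v1", "acr3", "S1", "ACDEF", 2.0), ("v2", "acr3", "S1", "ACDEG", 3.0)]
        )
        out = endemism.dereplicate(v)
        assert len(out) == 2 and set(out["variant_id"]) == {"v1", "v2"}

    def test_total_abundance_conserved_on_fixture(self, site_fixture):
        out = endemism.dereplicate(site_fixture.variants)
        assert out["abundance"].sum() == pytest.approx(
            site_fixture.summary["total_abundance"], abs=1e-9
        )


class TestGreedyCluster:
    def test_two_sequences_at_89_percent_split(self):
        rng = np.random.default_rng(6)
        a = _random_seq(rng, 100)
        b = _mutate(rng, a, 11)  # 89% identity: strictly below threshold
        v = _variants(
            [("v1", "acr3", "S1", a, 5.0), ("v2", "acr3", "S1", b, 1.0)]
        )
        assert len(endemism.greedy_cluster(v, identity_threshold=90.0)) == 2

    def test_exact_90_percent_joins(self):
        rng = np.random.default_rng(7)
        a = _random_seq(rng, 100)
        b = _mutate(rng, a, 10)
        v = _variants([("v1", "acr3", "S1", a, 5.0), ("v2", "acr3", "S1", b, 1.0)])
        assert len(endemism.greedy_cluster(v)) == 1

    def test_identical_sequences_one_cluster(self):
        v = _variants(
            [("v1", "acr3", "S1", "ACDEF" * 10, 1.0), ("v2", "acr3", "S2", "ACDEF" * 10, 2.0)]
        )
        clusters = endemism.greedy_cluster(v)
        assert len(clusters) == 1 and clusters[0].occupancy == 2

    def test_recovers_planted_partition(self, site_fixture):
        clusters = endemism.greedy_cluster(site_fixture.variants)
        got = {frozenset(c.member_ids) for c in clusters}
        truth_ids = site_fixture.variants.copy()
        truth_ids["cluster"] = truth_ids["variant_id"].str.rsplit("_", n=1).str[-1]
        want = {
            frozenset(sub["variant_id"].unique())
            for _, sub in truth_ids.groupby(["gene", "cluster"])
        }
        assert got == want

    def test_partition_property(self, site_fixture):
        clusters = endemism.greedy_cluster(site_fixture.variants)
        derep = endemism.dereplicate(site_fixture.variants)
        member_ids = [vid for c in clusters for vid in c.member_ids]
        assert len(member_ids) == len(set(member_ids))
        assert set(member_ids) == set(derep["variant_id"])

    def test_abundance_conserved(self, site_fixture):
        clusters = endemism.greedy_cluster(site_fixture.variants)
        total = sum(c.total_abundance for c in clusters)
        assert total == pytest.approx(site_fixture.summary["total_abundance"], abs=1e-9)

    def test_raising_threshold_never_merges_clusters(self, site_fixture):
        v = site_fixture.variants[site_fixture.variants["gene"] == "acr3"]
        n80 = len(endemism.greedy_cluster(v, identity_threshold=80.0))
        n90 = len(endemism.greedy_cluster(v, identity_threshold=90.0))
        n97 = len(endemism.greedy_cluster(v, identity_threshold=97.0))
        assert n80 <= n90 <= n97

    def test_prefilter_agrees_with_full_alignment_path(self, site_fixture):
        v = site_fixture.variants[site_fixture.variants["gene"] == "arsM"]
        fast = endemism.clusters_table(endemism.greedy_cluster(v, use_prefilter=True))
        slow = endemism.clusters_table(endemism.greedy_cluster(v, use_prefilter=False))
        pd.testing.assert_frame_equal(fast, slow)


class TestClassifyOccupancy:
    def _clusters(self, occupancies, gene="acr3"):
        out = []
        for i, occ in enumerate(occupancies):
            c = endemism.VariantCluster(
                cluster_id=f"{gene}_c{i}", gene=gene, centroid_id=f"v{i}",
                centroid_sequence="ACDEF",
            )
            c.member_ids = [f"v{i}"]
            c.site_abundance = {f"S{j}": 1.0 for j in range(occ)}
            out.append(c)
        return out

    def test_boundary_two_endemic_three_cosmopolitan(self):
        tab, summary = endemism.classify_occupancy(self._clusters([2, 3]))
        assert list(tab["endemic"]) == [True, False]
        assert summary["endemic_count"] == 1 and summary["cosmopolitan_count"] == 1

    def test_single_site_dataset_all_endemic(self):
        tab, summary = endemism.classify_occupancy(self._clusters([1, 1, 1]))
        assert summary["endemic_proportion"] == 1.0

    def test_counts_partition_clusters(self, site_fixture):
        clusters = endemism.greedy_cluster(site_fixture.variants)
        tab, summary = endemism.classify_occupancy(clusters)
        assert summary["endemic_count"] + summary["cosmopolitan_count"] == len(tab)

    def test_endemic_proportion_matches_planted_ledger(self, site_fixture):
        clusters = endemism.greedy_cluster(site_fixture.variants)
        _, summary = endemism.classify_occupancy(clusters)
        assert summary["endemic_proportion"] == pytest.approx(
            site_fixture.summary["endemic_fraction"], abs=0
        )
        assert summary["endemic_proportion_sequences"] == pytest.approx(
            site_fixture.summary["endemic_fraction_sequences"], abs=0
        )

    def test_cosmopolitan_gene_composition_sums_to_one(self, site_fixture):
        clusters = endemism.greedy_cluster(site_fixture.variants)
        _, summary = endemism.classify_occupancy(clusters)
        comp = summary["cosmopolitan_gene_composition"]
        if comp:
            assert sum(comp.values()) == pytest.approx(1.0)


class TestRankAbundance:
    def test_orders_by_mean_descending(self):
        norm = pd.DataFrame(
            {"acr3": [0.1, 0.3, 0.2]}, index=pd.Index(["s1", "s2", "s3"], name="site_id")
        )
        prof = abundance.SiteProfiles(
            normalized=norm, raw=norm * 10.0,
            rplb_totals=pd.Series(10.0, index=norm.index),
        )
        order = endemism.rank_abundance(prof)
        assert list(order["site_id"]) == ["s2", "s3", "s1"]

    def test_single_site(self):
        norm = pd.DataFrame({"acr3": [0.5]}, index=pd.Index(["s1"], name="site_id"))
        prof = abundance.SiteProfiles(
            normalized=norm, raw=norm * 2.0, rplb_totals=pd.Series(2.0, index=norm.index)
        )
        assert list(endemism.rank_abundance(prof)["site_id"]) == ["s1"]

    def test_matches_brute_force_sort(self, site_fixture):
        counts = site_fixture.variants.groupby(["site_id", "gene"], as_index=False)[
            "abundance"
        ].sum().rename(columns={"abundance": "count"})
        totals = site_fixture.sites.set_index("site_id")["rplb_total"]
        prof = abundance.rplb_normalize(counts, totals)
        order = endemism.rank_abundance(prof)
        means = prof.normalized.mean(axis=1)
        brute = sorted(means.index, key=lambda s: (-means[s], s))
        assert list(order["site_id"]) == brute
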