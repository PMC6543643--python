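"""Abundance estimators for arsenic-related genes.

Two complementary views:

* cultivation-dependent — expected gene copies per genome in a community,
  obtained by weighting each reference genome's copy number by its
  16S-inferred relative abundance in a sample;
* cultivation-independent — per-site gene counts from gene-targeted
  assembly, normalized by the site's total count of the single-copy
  marker rplB, which puts counts on a per-genome scale.

A gene that was not assembled at a site is "not detected" (NaN), which is
deliberately distinct from an observed zero: cross-site summaries in the
default conservative mode are computed over detecting sites only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix
from .io import GENES


@dataclass
class SiteProfiles:
    """Per-site per-gene rplB-normalized abundances plus site coordinates.

    ``normalized`` and ``raw`` are site × gene frames with NaN marking
    "not detected"; ``rplb_totals`` is a per-site Series.
    """

    normalized: pd.DataFrame
    raw: pd.DataFrame
    rplb_totals: pd.Series
    coordinates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        recomputed = self.raw.div(self.rplb_totals, axis=0)
        if not np.allclose(
            recomputed.fillna(-1).to_numpy(), self.normalized.fillna(-1).to_numpy()
        ):
            raise ValueError("normalized abundances inconsistent with raw / rplB")

    @property
    def sites(self) -> pd.Index:
        return self.normalized.index


def cultivation_weighted_abundance(
    matrix: GenotypeMatrix,
    weights: pd.DataFrame,
    presence_only: bool = False,
    tol: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expected gene copies per genome under 16S-inferred community weights.

    *weights* has columns sample_id, soil_order, genome_id, weight with
    per-sample weights summing to 1.  Returns (per-sample estimates,
    per-soil-order means); estimate(sample, gene) = Σ_g w(sample, g) ×
    total copies(g, gene).  Linear in the weights by construction.
    """
    required = {"sample_id", "soil_order", "genome_id", "weight"}
    if not required <= set(weights.columns):
        raise ValueError(f"weight table needs columns {sorted(required)}")
    unknown = sorted(set(weights["genome_id"]) - set(matrix.counts.index))
    if unknown:
        raise KeyError(f"weight rows reference unknown genomes: {unknown[:10]}")
    sums = weights.groupby("sample_id")["weight"].sum()
    off = sums[(sums - 1.0).abs() > tol]
    if len(off):
        raise ValueError(f"weights not normalized for samples: {list(off.index[:5])}")

    copies = matrix.total_copies()
    if presence_only:
        copies = (copies > 0).astype(float)
    W = weights.pivot_table(
        index="sample_id", columns="genome_id", values="weight", fill_value=0.0
    )
    W = W.reindex(columns=copies.index, fill_value=0.0)
    est = pd.DataFrame(
        W.to_numpy() @ copies.to_numpy(), index=W.index, columns=copies.columns
    )
    orders = weights.drop_duplicates("sample_id").set_index("sample_id")["soil_order"]
    est.insert(0, "soil_order", orders.reindex(est.index))
    by_order = est.groupby("soil_order").mean(numeric_only=True)
    return est, by_order


def rplb_normalize(
    gene_counts: pd.DataFrame,
    rplb_totals: pd.Series | pd.DataFrame,
    coordinates: pd.DataFrame | None = None,
) -> SiteProfiles:
    """Normalize per-site gene counts by per-site rplB totals.

    *gene_counts* is long (site_id, gene, count) or wide (site × gene, NaN
    for not-detected).  Depth-invariant: scaling a site's counts and its
    rplB total together leaves the profile unchanged.
    """
    if isinstance(rplb_totals, pd.DataFrame):
        rplb_totals = rplb_totals.set_index("site_id")["rplb_total"]
    rplb_totals = rplb_totals.astype(float)
    if (rplb_totals <= 0).any():
        bad = list(rplb_totals[rplb_totals <= 0].index)
        raise ValueError(f"rplB total must be > 0; offending sites: {bad}")

    if set(gene_counts.columns) >= {"site_id", "gene", "count"}:
        wide = gene_counts.pivot_table(
            index="site_id", columns="gene", values="count", aggfunc="sum"
        )
    else:
        wide = gene_counts.copy()
    wide = wide.reindex(index=rplb_totals.index)
    wide = wide.reindex(columns=[g for g in GENES if g in wide.columns] or wide.columns)
    normalized = wide.div(rplb_totals, axis=0)
    return SiteProfiles(
        normalized=normalized, raw=wide, rplb_totals=rplb_totals, coordinates=coordinates
    )


def relative_gene_composition(profiles: SiteProfiles) -> pd.DataFrame:
    """Per-site proportions over the detected arsenic genes (rows sum to 1)."""
    raw = profiles.raw
    out = {}
    for site, row in raw.iterrows():
        detected = row.dropna()
        if detected.empty or detected.sum() == 0:
            raise ValueError(f"no genes detected at site {site!r}")
        out[site] = detected / detected.sum()
    comp = pd.DataFrame(out).T.reindex(columns=raw.columns)
    comp.index.name = "site_id"
    return comp


def refsoil_normalized_abundance(matrix: GenotypeMatrix) -> pd.Series:
    """Reference-collection analogue of rplB normalization.

    Every complete genome contributes exactly one rplB, so total gene
    copies / number of genomes is the per-genome abundance.
    """
    if matrix.n_genomes == 0:
        raise ValueError("empty genotype matrix")
    return matrix.total_copies().sum(axis=0) / matrix.n_genomes


def gene_summaries(profiles: SiteProfiles, include_zeros: bool = False) -> pd.DataFrame:
    """Cross-site per-gene summaries of normalized abundance.

    Conservative mode (default) summarizes over detecting sites only — an
    undetected gene never contributes a zero.  ``include_zeros=True`` fills
    non-detections with 0 for sensitivity analysis.
    """
    norm = profiles.normalized
    if include_zeros:
        norm = norm.fillna(0.0)
    return pd.DataFrame(
        {
            "n_sites_detected": profiles.normalized.notna().sum(),
            "median": norm.median(),
            "mean": norm.mean(),
        }
    )


def community_structure(
    rplb_otus: pd.DataFrame, n_top: int = 6, min_top_coverage: float = 0.75
) -> pd.DataFrame:
    """Per-site phylum proportions from rplB counts, with top-phyla flags.

    The *n_top* most abundant phyla per site are flagged; if they jointly
    cover less than *min_top_coverage* of the community a warning is
    emitted (the extraction no longer represents the community).
    """
    required = {"site_id", "phylum", "count"}
    if not required <= set(rplb_otus.columns):
        raise ValueError(f"rplB OTU table needs columns {sorted(required)}")
    if (rplb_otus["count"] < 0).any():
        raise ValueError("negative rplB counts")
    rows = []
    for site, sub in rplb_otus.groupby("site_id"):
        counts = sub.groupby("phylum")["count"].sum().sort_values(ascending=False)
        total = counts.sum()
        if total == 0:
            raise ValueError(f"all-zero community at site {site!r}")
        props = counts / total
        top = set(props.index[:n_top])
        if props[list(top)].sum() < min_top_coverage:
            warnings.warn(
                f"site {site!r}: top {n_top} phyla cover "
                f"{props[list(top)].sum():.2f} < {min_top_coverage} of community"
            )
        for phylum, p in props.items():
            rows.append(
                {
                    "site_id": site,
                    "phylum": phylum,
                    "proportion": float(p),
                    "is_top": phylum in top,
                }
            )
    return pd.DataFrame(rows)
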