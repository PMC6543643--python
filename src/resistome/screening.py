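"""Quality-filter cascade for homology-search hits against complete genomes.

Hits against the nine arsenic-related gene HMMs are retained only when the
bit score and model coverage clear strict thresholds (score > 100, percent
alignment > 90), with an elevated score floor (> 1000) for the arsenite
oxidase / respiratory arsenate reductase genes (aioA, arrA, arxA) that are
prone to cross-family false positives.  When one ORF carries hits to more
than one model, only the highest-scoring hit is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ELEVATED_GENES, GENES, HIT_COLUMNS, validate_hit_table

_GENE_RANK = {g: i for i, g in enumerate(GENES)}


@dataclass
class ScreenReport:
    """Per-rule rejection tally for one screening run."""

    n_input: int
    n_rejected_score: int
    n_rejected_alignment: int
    n_rejected_elevated: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.n_rejected_score
            + self.n_rejected_alignment
            + self.n_rejected_elevated
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError("screen report does not partition the input rows")


def screen_hits(
    hits: pd.DataFrame,
    base_score_min: float = 100.0,
    alignment_min: float = 90.0,
    elevated_genes: frozenset[str] | set[str] = ELEVATED_GENES,
    elevated_score_min: float = 1000.0,
) -> tuple[pd.DataFrame, ScreenReport]:
    """Apply the retention cascade; returns (retained hits, report).

    All thresholds are strict inequalities.  Input row order is preserved;
    each rejected row is attributed to the first rule it fails, in the
    order score, alignment, elevated score.
    """
    validate_hit_table(hits)
    score = hits["score"].to_numpy(float)
    align = hits["percent_alignment"].to_numpy(float)
    elevated = hits["gene"].isin(elevated_genes).to_numpy()

    fail_score = ~(score > base_score_min)
    fail_align = ~fail_score & ~(align > alignment_min)
    fail_elev = ~fail_score & ~fail_align & elevated & ~(score > elevated_score_min)
    keep = ~(fail_score | fail_align | fail_elev)

    report = ScreenReport(
        n_input=len(hits),
        n_rejected_score=int(fail_score.sum()),
        n_rejected_alignment=int(fail_align.sum()),
        n_rejected_elevated=int(fail_elev.sum()),
        n_retained=int(keep.sum()),
    )
    return hits.loc[keep].reset_index(drop=True), report


def dedup_orfs(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep one hit per (genome_id, orf_id): the maximum-score hit.

    Equal-score ties are broken toward the gene earliest in the canonical
    gene ordering, then the lexicographically smallest replicon id, so the
    result is invariant to input row order.  Output is sorted by
    (genome_id, orf_id).
    """
    validate_hit_table(hits)
    if hits.empty:
        return hits.reset_index(drop=True)
    work = hits.copy()
    work["_rank"] = work["gene"].map(_GENE_RANK)
    work = work.sort_values(
        ["genome_id", "orf_id", "score", "_rank", "replicon_id"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    )
    out = work.drop_duplicates(["genome_id", "orf_id"], keep="first")
    return out.drop(columns="_rank").reset_index(drop=True)


def annotate_hits(hits: pd.DataFrame, genomes: pd.DataFrame) -> pd.DataFrame:
    """Attach phylum and taxonomy string from the genome metadata table.

    Every genome_id in *hits* must occur in *genomes*; unknown ids are a
    hard error (silently dropping hits would bias every downstream tally).
    """
    validate_hit_table(hits)
    meta_cols = ["genome_id", "phylum"]
    if "taxonomy" in genomes.columns:
        meta_cols.append("taxonomy")
    unknown = sorted(set(hits["genome_id"]) - set(genomes["genome_id"]))
    if unknown:
        raise KeyError(f"genome ids absent from metadata: {unknown[:10]}")
    merged = hits.merge(genomes[meta_cols], on="genome_id", how="left", validate="m:1")
    assert len(merged) == len(hits)
    return merged


def screen_cascade(
    hits: pd.DataFrame, genomes: pd.DataFrame, **thresholds
) -> tuple[pd.DataFrame, ScreenReport]:
    """Convenience: screen, dedup, annotate in the published order."""
    retained, report = screen_hits(hits, **thresholds)
    deduped = dedup_orfs(retained)
    return annotate_hits(deduped, genomes), report
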