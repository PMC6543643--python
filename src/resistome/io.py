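"""Readers and writers for the pipeline's external formats.

Everything on disk is plain text: tab-separated tables with a header row
(UTF-8, Unix newlines), protein FASTA wrapped at 80 columns, and newick
trees with branch lengths.  Readers validate eagerly and fail loudly —
a malformed row is a hard error naming the row, never a silent drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical ordering of the nine arsenic resistance / metabolism genes.
GENES: tuple[str, ...] = (
    "acr3",
    "aioA",
    "arrA",
    "arsB",
    "arsC_grx",
    "arsC_trx",
    "arsD",
    "arsM",
    "arxA",
)

#: Genes whose hits require the elevated bit-score threshold (arsenite
#: oxidases and the respiratory arsenate reductase).
ELEVATED_GENES: frozenset[str] = frozenset({"aioA", "arrA", "arxA"})

REPLICON_TYPES: frozenset[str] = frozenset({"chromosome", "plasmid"})

HIT_COLUMNS: tuple[str, ...] = (
    "genome_id",
    "replicon_id",
    "replicon_type",
    "orf_id",
    "gene",
    "score",
    "percent_alignment",
)

#: Twenty standard residues plus X (unknown).
AMINO_ACIDS: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """A file violated the format contract (bad value, missing field...)."""


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def validate_hit_table(hits: pd.DataFrame) -> None:
    """Raise :class:`FormatError` if *hits* violates the hit-table contract."""
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise FormatError(f"hit table missing columns: {missing}")
    bad_type = ~hits["replicon_type"].isin(REPLICON_TYPES)
    if bad_type.any():
        row = int(np.flatnonzero(bad_type.to_numpy())[0])
        raise FormatError(
            f"row {row}: replicon_type {hits['replicon_type'].iloc[row]!r} "
            f"not in {sorted(REPLICON_TYPES)}"
        )
    bad_gene = ~hits["gene"].isin(GENES)
    if bad_gene.any():
        row = int(np.flatnonzero(bad_gene.to_numpy())[0])
        raise FormatError(
            f"row {row}: unknown gene {hits['gene'].iloc[row]!r}; "
            f"expected one of {list(GENES)}"
        )
    score = pd.to_numeric(hits["score"], errors="coerce")
    if score.isna().any() or not np.isfinite(score).all():
        row = int(np.flatnonzero(~np.isfinite(score.to_numpy(float)))[0])
        raise FormatError(f"row {row}: score {hits['score'].iloc[row]!r} is not finite")
    pa = pd.to_numeric(hits["percent_alignment"], errors="coerce")
    bad_pa = ~(pa.between(0.0, 100.0))
    if bad_pa.any():
        row = int(np.flatnonzero(bad_pa.to_numpy())[0])
        raise FormatError(
            f"row {row}: percent_alignment {hits['percent_alignment'].iloc[row]!r} "
            "outside [0, 100]"
        )


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated homology-search hit table.

    Returns a DataFrame with the canonical column order, row order
    preserved.  Any invariant violation is a hard error naming the
    offending (0-based) data row.
    """
    try:
        hits = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    validate_hit_table(hits)
    hits = hits[list(HIT_COLUMNS)].copy()
    for col in ("score", "percent_alignment"):
        try:
            hits[col] = pd.to_numeric(hits[col])
        except ValueError as exc:
            raise FormatError(f"malformed numeric in column {col}: {exc}") from exc
    return hits.reset_index(drop=True)


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    """Write a hit table in canonical form (fixed column order, TSV)."""
    validate_hit_table(hits)
    hits = hits[list(HIT_COLUMNS)]
    hits.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic TSV table with header."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a generic TSV table with header, no index."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeDocument:
    """A rooted phylogeny with branch lengths over genome tips.

    Wraps a :class:`dendropy.Tree`; tip labels are unique genome ids and
    every non-root edge carries a non-negative length (substitutions/site).
    Polytomies are allowed and preserved.
    """

    tree: dendropy.Tree
    tip_labels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.tree.is_rooted = True
        labels = []
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise FormatError("tree has an unlabeled tip")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise FormatError(f"duplicate tip labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:  # root edge may be lengthless
                continue
            if edge.length is None:
                raise FormatError("tree edge missing branch length")
            if edge.length < 0:
                raise FormatError(f"negative branch length {edge.length}")
        self.tip_labels = tuple(labels)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.tree.preorder_edge_iter() if e.tail_node is not None
        )


def _get_tree(**kwargs) -> TreeDocument:
    from dendropy.dataio.newickreader import NewickReader

    try:
        tree = dendropy.Tree.get(
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            **kwargs,
        )
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise FormatError(f"duplicate tip labels: {exc}") from exc
    return TreeDocument(tree)


def read_tree(path: str | Path) -> TreeDocument:
    """Read a rooted newick tree with branch lengths."""
    return _get_tree(path=str(path))


def parse_tree(newick: str) -> TreeDocument:
    """Parse a newick string (same contract as :func:`read_tree`)."""
    return _get_tree(data=newick)


def write_tree(doc: TreeDocument, path: str | Path) -> None:
    Path(path).write_text(to_newick(doc), encoding="utf-8")


def to_newick(doc: TreeDocument) -> str:
    return (
        doc.tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True).strip()
        + "\n"
    )


# ---------------------------------------------------------------------------
# assembled protein variants
# ---------------------------------------------------------------------------

VARIANT_COLUMNS: tuple[str, ...] = ("variant_id", "gene", "site_id", "abundance")


def read_variant_fasta(path: str | Path, abundance_path: str | Path) -> pd.DataFrame:
    """Load assembled protein variants plus their per-site abundances.

    *path* is a protein FASTA (ids unique); *abundance_path* is a TSV with
    columns variant_id, gene, site_id, abundance — exactly one row per
    (variant_id, site_id).  Returns one VariantRecord row per abundance
    row, with the sequence attached.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {rec.id!r}")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise FormatError(
                f"sequence {rec.id!r} contains illegal residue(s) {sorted(bad)}"
            )
        seqs[rec.id] = seq

    ab = pd.read_csv(abundance_path, sep="\t", dtype={"variant_id": str, "site_id": str})
    missing = [c for c in VARIANT_COLUMNS if c not in ab.columns]
    if missing:
        raise FormatError(f"abundance table missing columns: {missing}")
    if ab.duplicated(["variant_id", "site_id"]).any():
        raise FormatError("duplicate (variant_id, site_id) abundance rows")
    unknown = sorted(set(ab["variant_id"]) - set(seqs))
    if unknown:
        raise FormatError(f"abundance rows without FASTA sequence: {unknown[:5]}")
    orphans = sorted(set(seqs) - set(ab["variant_id"]))
    if orphans:
        raise FormatError(f"sequences without abundance row: {orphans[:5]}")
    if (pd.to_numeric(ab["abundance"]) < 0).any():
        raise FormatError("negative coverage-adjusted abundance")

    out = ab[list(VARIANT_COLUMNS)].copy()
    out["abundance"] = pd.to_numeric(out["abundance"])
    out["sequence"] = out["variant_id"].map(seqs)
    return out.reset_index(drop=True)


def write_variant_fasta(
    variants: pd.DataFrame, fasta_path: str | Path, abundance_path: str | Path
) -> None:
    """Write variants back to FASTA (80-column wrap) + abundance TSV."""
    seqs = variants.drop_duplicates("variant_id")[["variant_id", "sequence"]]
    records = [
        SeqRecord(Seq(s), id=v, description="")
        for v, s in zip(seqs["variant_id"], seqs["sequence"])
    ]
    with open(fasta_path, "w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)
    write_table(variants[list(VARIANT_COLUMNS)], abundance_path)
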