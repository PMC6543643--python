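"""Blomberg's K and its permutation test for gene presence/absence traits.

Under Brownian-motion evolution a trait's covariance between two tips is
proportional to their shared root-to-ancestor path length.  Blomberg's K
compares the observed ratio of non-phylogenetic to phylogenetic mean
squared error with its Brownian expectation on the same tree: K ≈ 1 for a
Brownian trait, K → 0 for a trait shuffled independently of the phylogeny.
Presence/absence genotypes are analyzed with the continuous-trait K, the
convention of the source analysis for binary genotype data.

Significance comes from a tip-shuffling permutation null: phylogenetic
signal means the observed phylogenetically corrected MSE is smaller than
for permuted tip assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import TreeDocument

_RIDGE = 1e-8


@dataclass
class TipTrait:
    """Binary trait over phylogeny tips, e.g. 'acr3 on chromosome'."""

    name: str
    tip_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.tip_ids) != len(self.values):
            raise ValueError("tip_ids and values length mismatch")

    @property
    def is_constant(self) -> bool:
        return bool(np.all(self.values == self.values[0]))

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.values == 1))


@dataclass
class SignalResult:
    """Outcome of one phylogenetic-signal test."""

    trait: str
    K: float
    p_value: float
    n_permutations: int
    seed: int
    n_tips: int
    n_positive: int
    testable: bool = True
    low_power: bool = False
    p_adjusted: float = float("nan")


def phylo_vcv(doc: TreeDocument) -> tuple[np.ndarray, tuple[str, ...]]:
    """Tip × tip phylogenetic variance-covariance matrix.

    V[i, i] is the root-to-tip path length of tip i; V[i, j] the root-to-MRCA
    shared path length of tips i and j.  Polytomies are handled naturally.
    """
    tree = doc.tree
    labels = doc.tip_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))

    # postorder sweep: each node knows its tip set; at each internal node,
    # tips in different child subtrees share exactly that node's depth.
    depth: dict = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            V[i, i] = depth[node]
            tipsets[node] = [i]
        else:
            children = [tipsets.pop(c) for c in node.child_nodes()]
            merged: list[int] = []
            for k, a in enumerate(children):
                for b in children[k + 1 :]:
                    for i in a:
                        V[i, b] = depth[node]
                        V[b, i] = depth[node]
                merged.extend(a)
            tipsets[node] = merged
    if not np.any(np.diag(V) > 0):
        raise ValueError("zero-length tree: all root-to-tip path lengths are 0")
    return V, labels


def _phylo_mse(x: np.ndarray, Vinv: np.ndarray) -> float:
    one = np.ones(len(x))
    denom = one @ Vinv @ one
    a = (one @ Vinv @ x) / denom
    r = x - a
    return float(r @ Vinv @ r) / (len(x) - 1)


def blomberg_k(values: np.ndarray, V: np.ndarray) -> float:
    """Blomberg's K for a trait vector against a phylogenetic VCV matrix.

    K = (MSE0/MSE)_observed / (MSE0/MSE)_Brownian-expected with the
    phylogenetic GLS mean as the ancestral estimate.  Invariant to affine
    rescaling of the trait and to uniform rescaling of branch lengths.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n != V.shape[0]:
        raise ValueError("trait length does not match VCV dimension")
    if np.all(x == x[0]):
        raise ValueError("zero variance: trait is constant")
    Vinv = _safe_inverse(V)
    one = np.ones(n)
    a = (one @ Vinv @ x) / (one @ Vinv @ one)
    mse0 = float(np.sum((x - a) ** 2)) / (n - 1)
    mse = float((x - a) @ Vinv @ (x - a)) / (n - 1)
    expected = (np.trace(V) - n / Vinv.sum()) / (n - 1)
    return (mse0 / mse) / expected


def _safe_inverse(V: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(V)
    except np.linalg.LinAlgError:
        # near-singular VCV (e.g. zero-length terminal branches): ridge it
        return np.linalg.inv(V + _RIDGE * np.eye(len(V)))


def signal_test(
    trait: TipTrait,
    tree: TreeDocument | None = None,
    n_permutations: int = 999,
    seed: int = 0,
    V: np.ndarray | None = None,
    labels: tuple[str, ...] | None = None,
    low_power_min: int = 5,
) -> SignalResult:
    """Permutation test for phylogenetic signal in one binary trait.

    p = (1 + #{permutations with MSE_perm <= MSE_obs}) / (n_permutations + 1),
    shuffling the tip-to-value assignment uniformly.  Constant traits are
    returned flagged untestable (K, p = NaN) and are excluded from the FDR
    family by :func:`fdr_adjust`.
    """
    if V is None or labels is None:
        if tree is None:
            raise ValueError("provide either tree or a precomputed (V, labels)")
        V, labels = phylo_vcv(tree)
    order = {lab: i for i, lab in enumerate(labels)}
    if set(trait.tip_ids) != set(labels):
        raise ValueError(f"trait {trait.name!r} tips do not match tree tips")
    x = np.empty(len(labels))
    x[[order[t] for t in trait.tip_ids]] = trait.values

    n_pos = int(np.sum(x == 1))
    low_power = min(n_pos, len(x) - n_pos) < low_power_min
    if np.all(x == x[0]):
        return SignalResult(
            trait=trait.name, K=float("nan"), p_value=float("nan"),
            n_permutations=n_permutations, seed=seed, n_tips=len(x),
            n_positive=n_pos, testable=False, low_power=True,
        )

    Vinv = _safe_inverse(V)
    one = np.ones(len(x))
    denom = one @ Vinv @ one
    w = Vinv @ one  # GLS mean weights

    def mse_of(mat: np.ndarray) -> np.ndarray:
        a = (mat @ w) / denom
        r = mat - a[:, None]
        return np.einsum("ij,jk,ik->i", r, Vinv, r) / (len(x) - 1)

    mse_obs = mse_of(x[None, :])[0]
    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, len(x)))
    for i in range(n_permutations):
        perms[i] = x[rng.permutation(len(x))]
    p = (1.0 + float(np.sum(mse_of(perms) <= mse_obs))) / (n_permutations + 1)

    return SignalResult(
        trait=trait.name, K=blomberg_k(x, V), p_value=p,
        n_permutations=n_permutations, seed=seed, n_tips=len(x),
        n_positive=n_pos, testable=True, low_power=low_power,
    )


def fdr_adjust(results: list[SignalResult]) -> list[SignalResult]:
    """Benjamini-Hochberg adjustment over the testable traits in one family."""
    testable = [r for r in results if r.testable]
    if not testable:
        raise ValueError("no testable traits in family")
    pvals = [r.p_value for r in testable]
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(testable, adj):
        r.p_adjusted = float(q)
    return results


def traits_from_genotype(matrix_counts: pd.DataFrame, tip_ids: tuple[str, ...]) -> list[TipTrait]:
    """One presence/absence TipTrait per (gene, location) over the given tips."""
    traits = []
    sub = matrix_counts.reindex(list(tip_ids))
    if sub.isna().any().any():
        missing = sorted(set(tip_ids) - set(matrix_counts.index))
        raise KeyError(f"tree tips absent from genotype matrix: {missing[:10]}")
    for gene, location in matrix_counts.columns:
        vals = (sub[(gene, location)].to_numpy() > 0).astype(float)
        traits.append(TipTrait(name=f"{gene}|{location}", tip_ids=tuple(tip_ids), values=vals))
    return traits


def results_table(results: list[SignalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trait": [r.trait for r in results],
            "K": [r.K for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "n_positive": [r.n_positive for r in results],
            "n_tips": [r.n_tips for r in results],
            "testable": [r.testable for r in results],
            "low_power": [r.low_power for r in results],
        }
    )
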