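"""Felsenstein phylogenetic independent contrasts (PICs).

Under Brownian-motion trait evolution, the standardized difference
between the trait values of two sister lineages,

    contrast = (x_i - x_j) / sqrt(b_i + b_j),

is independent across nodes of the tree, turning T correlated tip values
into T - 1 independent rows.  The pruning recursion replaces each cherry
by its ancestor, with the ancestral value the 1/b-weighted average of
the children and the ancestral branch extended by b_i b_j / (b_i + b_j).

Branch lengths default to 1 on every edge (the unit-length convention);
trees are read from Newick via dendropy.  Contrast covariances are
computed through the origin, since contrasts have expected mean zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "ContrastSet",
    "PhyloError",
    "read_newick",
    "independent_contrasts",
    "contrasts_covariance",
    "contrasts_correlation",
]


class PhyloError(ValueError):
    """Invalid tree or tree/data mismatch."""


@dataclass
class Phylogeny:
    """A rooted tree with unique tip labels."""

    tree: dendropy.Tree
    polytomies: int = 0

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)


def read_newick(source, taxa: list[str] | None = None) -> Phylogeny:
    """Parse a Newick tree from a path or string.

    ``taxa``, when given, must contain every tip label; unmatched tips
    are reported in the error.  Polytomies are accepted and counted
    (resolution policy is applied at contrast time).
    """
    text = None
    try:
        text = source.read()
    except AttributeError:
        s = str(source)
        if s.rstrip().endswith(";") and "(" in s:
            text = s
        else:
            with open(s) as fh:
                text = fh.read()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise PhyloError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise PhyloError("tree must have at least 2 tips")
    dup = {x for x in labels if labels.count(x) > 1}
    if dup:
        raise PhyloError(f"duplicate tip labels: {sorted(dup)}")
    if taxa is not None:
        missing = [x for x in labels if x not in set(taxa)]
        if missing:
            raise PhyloError(f"tips absent from trait table: {missing}")
    polytomies = sum(
        1 for nd in tree.preorder_internal_node_iter() if len(nd.child_nodes()) > 2
    )
    return Phylogeny(tree=tree, polytomies=polytomies)


@dataclass
class ContrastSet:
    """(tips - 1) x traits matrix of standardized contrasts with
    per-node bookkeeping (children, adjusted branch lengths, ancestral
    trait estimates)."""

    contrasts: pd.DataFrame
    nodes: list[dict] = field(default_factory=list)

    @property
    def n(self) -> int:
        """Effective sample size for downstream fitting: contrast rows."""
        return len(self.contrasts)


def _resolve_polytomies(tree: dendropy.Tree) -> int:
    """Arbitrarily bifurcate polytomies with zero-length internal edges.

    Returns the number of polytomies resolved.  Children are attached in
    their existing order, so the resolution is deterministic.
    """
    count = 0
    for nd in list(tree.preorder_internal_node_iter()):
        while len(nd.child_nodes()) > 2:
            count += 1 if len(nd.child_nodes()) == 3 else 0
            children = nd.child_nodes()
            a, b = children[0], children[1]
            new = dendropy.Node()
            nd.remove_child(a)
            nd.remove_child(b)
            new.add_child(a)
            new.add_child(b)
            new.edge.length = 0.0
            nd.insert_child(0, new)
    return count


def independent_contrasts(
    phylogeny: Phylogeny,
    table,
    unit_lengths: bool = True,
    strict: bool = False,
) -> ContrastSet:
    """Compute independent contrasts for every trait column.

    ``table`` is a TraitTable (species column + trait columns) or a
    DataFrame indexed by species.  With ``unit_lengths`` (default, the
    convention used throughout this package) every original branch is
    set to 1 before the recursion; zero-length branches introduced by
    polytomy resolution stay 0.  ``strict`` errors on polytomies
    instead of resolving them.
    """
    df = getattr(table, "data", table)
    if "species" in df.columns:
        df = df.set_index("species")
    trait_cols = [c for c in df.columns if np.issubdtype(df[c].dtype, np.number)]
    tree = phylogeny.tree.clone(depth=1)

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [x for x in labels if x not in df.index]
    if missing:
        raise PhyloError(f"missing trait values for tips: {missing}")

    if phylogeny.polytomies:
        if strict:
            raise PhyloError(
                f"tree has {phylogeny.polytomies} polytomies (strict mode)"
            )
        warnings.warn(
            f"resolving {phylogeny.polytomies} polytomies arbitrarily with "
            "zero-length branches"
        )
    if unit_lengths:
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node:
                edge.length = 1.0
    _resolve_polytomies(tree)

    x = {leaf.taxon.label: df.loc[leaf.taxon.label, trait_cols].to_numpy(float)
         for leaf in tree.leaf_node_iter()}

    rows: list[np.ndarray] = []
    nodes: list[dict] = []

    def blen(node) -> float:
        return node.edge.length if node.edge.length is not None else 1.0

    # postorder pruning: values and working branch lengths per node
    val: dict[int, np.ndarray] = {}
    wlen: dict[int, float] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            val[id(nd)] = x[nd.taxon.label]
            wlen[id(nd)] = blen(nd)
            continue
        kids = nd.child_nodes()
        if len(kids) != 2:  # root may be left with a single child after ops
            if len(kids) == 1:
                val[id(nd)] = val[id(kids[0])]
                wlen[id(nd)] = blen(nd) + wlen[id(kids[0])]
                continue
            raise PhyloError("internal node with >2 children after resolution")
        ca, cb = kids
        ba, bb = wlen[id(ca)], wlen[id(cb)]
        if ba + bb <= 0:
            # degenerate zero-length cherry from polytomy resolution:
            # treat as an infinitesimally short pair of equal branches
            ba = bb = 1e-12
        contrast = (val[id(ca)] - val[id(cb)]) / np.sqrt(ba + bb)
        anc = (val[id(ca)] / ba + val[id(cb)] / bb) / (1.0 / ba + 1.0 / bb)
        val[id(nd)] = anc
        wlen[id(nd)] = blen(nd) + ba * bb / (ba + bb)
        rows.append(contrast)
        nodes.append({
            "children": (
                ca.taxon.label if ca.is_leaf() else f"node{len(nodes)}",
                cb.taxon.label if cb.is_leaf() else f"node{len(nodes)}",
            ),
            "branch_sum": ba + bb,
            "ancestral_estimate": anc,
        })

    contrasts = pd.DataFrame(rows, columns=trait_cols)
    expected = phylogeny.n_tips - 1
    if len(contrasts) != expected:
        raise PhyloError(
            f"expected {expected} contrasts from {phylogeny.n_tips} tips, "
            f"got {len(contrasts)}"
        )
    return ContrastSet(contrasts=contrasts, nodes=nodes)


def contrasts_covariance(
    cs: ContrastSet, center: bool = False
) -> pd.DataFrame:
    """Cross-product covariance of contrasts, through the origin by
    default (contrasts have expected mean zero); divisor is the row
    count.  ``center=True`` gives the mean-centered version for
    sensitivity analysis."""
    z = cs.contrasts.to_numpy(float)
    if z.shape[0] < 2:
        raise PhyloError("need at least 2 contrast rows")
    if z.shape[0] < z.shape[1]:
        warnings.warn("fewer contrasts than traits: covariance is singular")
    if center:
        z = z - z.mean(axis=0)
    c = z.T @ z / z.shape[0]
    cols = list(cs.contrasts.columns)
    return pd.DataFrame(c, index=cols, columns=cols)


def contrasts_correlation(cs: ContrastSet, center: bool = False) -> pd.DataFrame:
    """Correlations of contrasts (through the origin by default)."""
    c = contrasts_covariance(cs, center=center).to_numpy()
    d = np.sqrt(np.diag(c))
    r = c / np.outer(d, d)
    cols = list(cs.contrasts.columns)
    return pd.DataFrame(r, index=cols, columns=cols)
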