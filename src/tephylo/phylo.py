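"""Rooted phylogenies with branch lengths: parsing, pruning, Brownian-motion
covariance, Felsenstein's independent contrasts, and evolutionary-path branch
labeling.

Trees are stored as thin wrappers around :class:`dendropy.Tree`.  Branch
lengths are in expected substitutions per site.  The root may be a
trifurcation (as in the 12-species *Drosophila* tree this package ships);
polytomies are resolved deterministically with zero-length internal branches
before contrasts are computed, which leaves the Brownian-motion covariance
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "NewickParseError",
    "PhylogenyError",
    "Phylogeny",
    "Contrast",
    "ContrastSet",
    "PathLabeling",
    "parse_newick",
    "apply_lambda",
    "read_tagged_newick",
]


class NewickParseError(ValueError):
    """A Newick string could not be parsed (message names the offset)."""


class PhylogenyError(ValueError):
    """Structurally invalid tree, or an invalid query against a valid tree."""


def _fmt_length(x: float) -> str:
    # >= 8 significant digits so serialize/parse round-trips printed trees
    return format(float(x), ".10g")


class Phylogeny:
    """A rooted tree with unique tip labels and non-negative branch lengths.

    Node identifiers are stable: tips are identified by their label, internal
    nodes by ``"node<k>"`` with ``k`` assigned in preorder.  Edges are
    identified by the id of their child node.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._index()
        self._validate()
        self._V_cache: pd.DataFrame | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        tree.is_rooted = True
        return cls(tree)

    def _index(self) -> None:
        self._nodes: dict[str, dendropy.Node] = {}
        k = 0
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon is not None else nd.label
                if label is None:
                    raise PhylogenyError("tip without a label")
                nd_id = str(label)
            else:
                nd_id = f"node{k}"
                k += 1
            nd._tephylo_id = nd_id
            if nd_id in self._nodes:
                raise PhylogenyError(f"duplicate tip label: {nd_id!r}")
            self._nodes[nd_id] = nd

    def _validate(self) -> None:
        root = self._tree.seed_node
        for nd in self._tree.preorder_node_iter():
            if nd is root:
                continue
            if nd.edge.length is None:
                raise PhylogenyError(
                    f"missing branch length on edge above {nd._tephylo_id!r}"
                )
            if nd.edge.length < 0:
                raise PhylogenyError(
                    f"negative branch length on edge above {nd._tephylo_id!r}"
                )
        if len(self.tip_labels) < 2:
            raise PhylogenyError("a phylogeny needs at least 2 tips")

    # -- basic queries -----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [
            nd._tephylo_id
            for nd in self._tree.preorder_node_iter()
            if nd.is_leaf()
        ]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def node_ids(self) -> list[str]:
        return [nd._tephylo_id for nd in self._tree.preorder_node_iter()]

    def node(self, node_id: str) -> dendropy.Node:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise PhylogenyError(f"unknown node id: {node_id!r}") from None

    def parent_id(self, node_id: str) -> str | None:
        p = self.node(node_id).parent_node
        return None if p is None else p._tephylo_id

    def branch_length(self, node_id: str) -> float | None:
        """Length of the edge above *node_id* (None for the root)."""
        nd = self.node(node_id)
        return None if nd.parent_node is None else float(nd.edge.length)

    def mrca(self, labels: Iterable[str]) -> str:
        labels = list(labels)
        unknown = [t for t in labels if t not in self._nodes]
        if unknown:
            raise PhylogenyError(f"unknown tip label(s): {unknown}")
        nd = self._tree.mrca(taxon_labels=labels)
        if nd is None:
            raise PhylogenyError(f"no MRCA found for {labels}")
        return nd._tephylo_id

    def has_polytomy(self) -> bool:
        return any(
            len(nd.child_nodes()) > 2
            for nd in self._tree.preorder_node_iter()
            if not nd.is_leaf()
        )

    # -- serialization -----------------------------------------------------

    def to_newick(self, tagged: frozenset | set | None = None) -> str:
        """Serialize to Newick.  Branch lengths are printed with 10
        significant digits.  If *tagged* is given, every node id in it has
        ``#1`` appended after its name (PAML-style foreground branch marks).
        """
        tagged = frozenset(tagged or ())

        def rec(nd: dendropy.Node) -> str:
            if nd.is_leaf():
                s = nd._tephylo_id
            else:
                s = "(" + ",".join(rec(c) for c in nd.child_nodes()) + ")"
            if nd._tephylo_id in tagged:
                s += "#1"
            if nd.parent_node is not None:
                s += ":" + _fmt_length(nd.edge.length)
            return s

        return rec(self._tree.seed_node) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips>"

    # -- pruning -----------------------------------------------------------

    def prune(self, keep: Iterable[str]) -> "Phylogeny":
        """Restrict the tree to the tips in *keep*.

        Retained tip-to-tip path lengths are unchanged; unary internal nodes
        are collapsed with their branch lengths summed.
        """
        keep = list(dict.fromkeys(keep))
        tips = set(self.tip_labels)
        unknown = [t for t in keep if t not in tips]
        if unknown:
            raise PhylogenyError(f"unknown tip label(s): {unknown}")
        if len(keep) < 2:
            raise PhylogenyError("pruning must retain at least 2 tips")
        tree = dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        tree.retain_taxa_with_labels(keep)
        # collapse a uniforking root left behind by the pruning
        root = tree.seed_node
        while len(root.child_nodes()) == 1:
            child = root.child_nodes()[0]
            child.parent_node = None
            child.edge.length = None
            tree.seed_node = child
            root = child
        return Phylogeny(tree)

    # -- Brownian-motion covariance ---------------------------------------

    def root_to_tip_lengths(self) -> pd.Series:
        depth: dict[dendropy.Node, float] = {}
        out = {}
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                depth[nd] = 0.0
            else:
                depth[nd] = depth[nd.parent_node] + float(nd.edge.length)
            if nd.is_leaf():
                out[nd._tephylo_id] = depth[nd]
        return pd.Series(out, name="root_to_tip").loc[self.tip_labels]

    def bm_covariance(self) -> pd.DataFrame:
        """Tip covariance under Brownian motion: V[i, j] is the summed branch
        length shared by the root-to-tip paths of i and j.
        """
        if self._V_cache is not None:
            return self._V_cache.copy()
        tips = self.tip_labels
        pos = {t: k for k, t in enumerate(tips)}
        n = len(tips)
        V = np.zeros((n, n))
        depth: dict[dendropy.Node, float] = {}
        clade: dict[dendropy.Node, list[int]] = {}
        for nd in self._tree.preorder_node_iter():
            depth[nd] = (
                0.0
                if nd.parent_node is None
                else depth[nd.parent_node] + float(nd.edge.length)
            )
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                k = pos[nd._tephylo_id]
                V[k, k] = depth[nd]
                clade[nd] = [k]
            else:
                groups = [clade[c] for c in nd.child_nodes()]
                d = depth[nd]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        for i in groups[a]:
                            for j in groups[b]:
                                V[i, j] = V[j, i] = d
                clade[nd] = [i for g in groups for i in g]
        self._V_cache = pd.DataFrame(V, index=tips, columns=tips)
        return self._V_cache.copy()

    # -- polytomy resolution and contrasts ---------------------------------

    def resolve_polytomies(self) -> "Phylogeny":
        """Make the tree strictly bifurcating by repeatedly grouping the
        first two children (input order) of any polytomy under a new
        zero-length internal branch.  Deterministic; leaves the BM
        covariance unchanged.
        """
        tree = dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        for nd in list(tree.preorder_node_iter()):
            while len(nd.child_nodes()) > 2:
                c1, c2 = nd.child_nodes()[0], nd.child_nodes()[1]
                nd.remove_child(c1)
                nd.remove_child(c2)
                grp = dendropy.Node()
                grp.edge.length = 0.0
                grp.add_child(c1)
                grp.add_child(c2)
                nd.insert_child(0, grp)
        return Phylogeny(tree)

    def independent_contrasts(self, trait: Mapping[str, float]) -> "ContrastSet":
        """Felsenstein's phylogenetically independent contrasts.

        At each cherry with (adjusted) branch lengths b1, b2 the standardized
        contrast is (x1 - x2)/sqrt(b1 + b2), the inferred ancestral value is
        the branch-length-weighted mean, and the parent edge is lengthened by
        b1*b2/(b1 + b2).  Polytomies are resolved first (zero-length
        branches, deterministic).  Returns n_tips - 1 contrasts in postorder.
        """
        trait = dict(trait) if not isinstance(trait, pd.Series) else trait
        missing = [t for t in self.tip_labels if t not in trait]
        if missing:
            raise PhylogenyError(f"trait value missing for tip(s): {missing}")
        tree = self.resolve_polytomies() if self.has_polytomy() else self
        xval: dict[dendropy.Node, float] = {}
        extra: dict[dendropy.Node, float] = {}
        contrasts: list[Contrast] = []
        for nd in tree._tree.postorder_node_iter():
            if nd.is_leaf():
                xval[nd] = float(trait[nd._tephylo_id])
                extra[nd] = 0.0
                continue
            c1, c2 = nd.child_nodes()
            b1 = float(c1.edge.length) + extra[c1]
            b2 = float(c2.edge.length) + extra[c2]
            tot = b1 + b2
            x1, x2 = xval[c1], xval[c2]
            if tot <= 0.0:
                raise PhylogenyError(
                    "zero-length cherry at "
                    f"{nd._tephylo_id!r} (trait values {x1!r}, {x2!r}): "
                    "contrast cannot be standardized"
                )
            contrasts.append(
                Contrast(
                    node_id=nd._tephylo_id,
                    value=(x1 - x2) / math.sqrt(tot),
                    divisor=math.sqrt(tot),
                )
            )
            if b1 == 0.0:
                xval[nd] = x1
            elif b2 == 0.0:
                xval[nd] = x2
            else:
                xval[nd] = (x1 / b1 + x2 / b2) / (1.0 / b1 + 1.0 / b2)
            extra[nd] = b1 * b2 / tot
        return ContrastSet(contrasts=contrasts, n_tips=self.n_tips)

    # -- evolutionary-path labeling ----------------------------------------

    def label_path(self, tip: str, ancestor: str) -> "PathLabeling":
        """Mark the branches connecting *tip* to *ancestor* as foreground.

        The foreground consists of every edge on the path whose child node
        lies between the tip (inclusive) and the ancestor (exclusive); the
        edge above the ancestor itself is background.  Also emits a
        PAML-style Newick string with foreground branches tagged ``#1``.
        """
        nd = self.node(tip)
        if not nd.is_leaf():
            raise PhylogenyError(f"{tip!r} is not a tip")
        anc = self.node(ancestor)
        path: list[str] = []
        cur = nd
        while cur is not anc:
            path.append(cur._tephylo_id)
            cur = cur.parent_node
            if cur is None:
                raise PhylogenyError(
                    f"{ancestor!r} is not an ancestor of tip {tip!r}"
                )
        foreground = frozenset(path)
        all_edges = frozenset(
            n._tephylo_id
            for n in self._tree.preorder_node_iter()
            if n.parent_node is not None
        )
        return PathLabeling(
            tip=tip,
            ancestor=ancestor,
            foreground=foreground,
            background=all_edges - foreground,
            tagged_newick=self.to_newick(tagged=foreground),
        )


@dataclass(frozen=True)
class Contrast:
    node_id: str
    value: float
    divisor: float


@dataclass(frozen=True)
class ContrastSet:
    contrasts: list[Contrast]
    n_tips: int

    def __post_init__(self):
        if len(self.contrasts) != self.n_tips - 1:
            raise PhylogenyError(
                f"expected {self.n_tips - 1} contrasts, got {len(self.contrasts)}"
            )

    @property
    def values(self) -> np.ndarray:
        return np.array([c.value for c in self.contrasts])

    @property
    def divisors(self) -> np.ndarray:
        return np.array([c.divisor for c in self.contrasts])

    @property
    def node_ids(self) -> list[str]:
        return [c.node_id for c in self.contrasts]

    def __len__(self) -> int:
        return len(self.contrasts)


@dataclass(frozen=True)
class PathLabeling:
    tip: str
    ancestor: str
    foreground: frozenset
    background: frozenset
    tagged_newick: str


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string with branch lengths into a :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)


def read_tagged_newick(text: str) -> tuple[Phylogeny, frozenset]:
    """Parse a ``#1``-tagged Newick string, returning the clean tree and the
    foreground edge set (node ids in the clean tree's numbering)."""
    tagged = Phylogeny.from_newick(text)
    marked_clades = []
    for nd in tagged._tree.preorder_node_iter():
        label = nd._tephylo_id if nd.is_leaf() else (nd.label or "")
        if str(label).endswith("#1"):
            marked_clades.append(
                frozenset(
                    l._tephylo_id.removesuffix("#1")
                    for l in nd.leaf_iter()
                )
            )
    clean = Phylogeny.from_newick(text.replace("#1", ""))
    fg = set()
    for nd in clean._tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        clade = frozenset(l._tephylo_id for l in nd.leaf_iter())
        if clade in marked_clades:
            fg.add(nd._tephylo_id)
    return clean, frozenset(fg)


def apply_lambda(V: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Pagel's lambda transform: multiply off-diagonal entries of the BM
    covariance by lam in [0, 1] (0 = star phylogeny, 1 = full tree)."""
    if not 0.0 <= lam <= 1.0:
        raise PhylogenyError(f"lambda must lie in [0, 1], got {lam}")
    A = V.to_numpy(dtype=float, copy=True)
    d = np.diag(A).copy()
    A *= lam
    np.fill_diagonal(A, d)
    return pd.DataFrame(A, index=V.index, columns=V.columns)
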