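"""Time-calibrated phylogenies and Brownian-motion covariance matrices.

Trees are rooted, with branch lengths in Ma. The central product is the
Brownian-motion (BM) covariance matrix C whose (i, j) entry is the shared
root-to-MRCA path length of tips i and j; every phylogenetic statistic in
the package (Blomberg's K, K_mult, phylogenetic HSD, pFDA whitening) is
built on C.

Newick reading/writing is delegated to dendropy; the in-memory
representation is a flat parent-array tree that the grafting, scaling and
pruning operations manipulate directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Replacement for zero or absent branch lengths (Ma). Keeps the BM
#: covariance positive definite so GLS and whitening stay invertible.
MIN_BRANCH_LENGTH = 1e-8


class PhylogenyError(ValueError):
    """Raised for malformed trees or infeasible tree operations."""


@dataclass
class Phylogeny:
    """Rooted tree: node ``i`` has parent ``parent[i]`` (-1 at the root) and
    a branch of ``length[i]`` Ma above it. ``labels[i]`` is the tip label or
    ``None`` for internal nodes. Node ids are preorder positions and are
    reassigned by operations that change topology."""

    parent: np.ndarray
    length: np.ndarray
    labels: list
    root: int = 0

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.length = np.asarray(self.length, dtype=float)
        n_roots = int(np.sum(self.parent < 0))
        if n_roots != 1:
            raise PhylogenyError(f"tree must have exactly one root, found {n_roots}")
        zero = (self.length <= 0) & (self.parent >= 0)
        if np.any(zero):
            logger.warning(
                "replaced %d zero/absent branch lengths with %g Ma",
                int(zero.sum()), MIN_BRANCH_LENGTH,
            )
            self.length = self.length.copy()
            self.length[zero] = MIN_BRANCH_LENGTH
        tips = self.tip_labels
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise PhylogenyError(f"duplicate tip labels: {dup}")

    # ---------------------------------------------------------------- basic
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_ids(self) -> np.ndarray:
        is_parent = np.zeros(self.n_nodes, dtype=bool)
        is_parent[self.parent[self.parent >= 0]] = True
        return np.flatnonzero(~is_parent)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_ids]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    def children(self, node: int) -> np.ndarray:
        return np.flatnonzero(self.parent == node)

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (Ma)."""
        d = np.zeros(self.n_nodes)
        for i in self._preorder():
            if self.parent[i] >= 0:
                d[i] = d[self.parent[i]] + self.length[i]
        return d

    @property
    def depth(self) -> float:
        """Maximum root-to-tip distance (Ma): the tree's temporal depth."""
        return float(self.depths()[self.tip_ids].max())

    def node_age(self, node: int) -> float:
        """Age of a node in Ma before present (present = deepest tip)."""
        return self.depth - float(self.depths()[node])

    def _preorder(self) -> list:
        order, stack = [], [self.root]
        kids = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(kids[v]))
        return order

    def mrca(self, taxa) -> int:
        """Node id of the most recent common ancestor of the given tip labels."""
        label_to_id = {self.labels[i]: i for i in self.tip_ids}
        unknown = [t for t in taxa if t not in label_to_id]
        if unknown:
            raise PhylogenyError(f"unknown tip labels: {unknown}")
        paths = []
        for t in taxa:
            node, path = label_to_id[t], []
            while node >= 0:
                path.append(node)
                node = self.parent[node]
            paths.append(path[::-1])
        mrca = self.root
        for nodes in zip(*paths):
            if len(set(nodes)) == 1:
                mrca = nodes[0]
            else:
                break
        return mrca

    # ------------------------------------------------------------------ io
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        length = np.zeros(len(nodes))
        labels: list = [None] * len(nodes)
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                parent[i] = index[id(n.parent_node)]
                length[i] = n.edge.length if n.edge.length is not None else 0.0
            if n.is_leaf():
                labels[i] = n.taxon.label if n.taxon is not None else None
        tips_without_label = [i for i in range(len(nodes))
                              if labels[i] is None and not np.any(parent == i)]
        if tips_without_label:
            raise PhylogenyError("tree contains unlabeled tips")
        return cls(parent=parent, length=length, labels=labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        dn = {self.root: tree.seed_node}
        for i in self._preorder():
            if i == self.root:
                continue
            node = dendropy.Node()
            node.edge.length = float(self.length[i])
            dn[self.parent[i]].add_child(node)
            dn[i] = node
        for i in self.tip_ids:
            dn[i].taxon = taxa.new_taxon(self.labels[i])
        return tree

    def write_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True
        ).strip()


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (plain or quoted labels, ``:length`` branch
    lengths) into a :class:`Phylogeny`.

    Raises :class:`PhylogenyError` naming the offending token on malformed
    input or duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise PhylogenyError(f"newick parse error: {exc}") from exc
    # dendropy merges duplicate labels into one taxon; detect from raw text
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if len(labels) != n_leaves:
        raise PhylogenyError("newick parse error: unlabeled tip")
    if len(set(labels)) != n_leaves or _count_label_occurrences(text, labels):
        dup = _count_label_occurrences(text, labels) or sorted(
            {t for t in labels if labels.count(t) > 1})
        raise PhylogenyError(f"duplicate tip labels: {dup}")
    return Phylogeny.from_dendropy(tree)


def _count_label_occurrences(text: str, labels: list) -> list:
    """Duplicate labels that dendropy silently merged into one taxon."""
    import re
    dup = []
    for lbl in set(labels):
        hits = len(re.findall(rf"[(,]\s*'?{re.escape(lbl)}'?\s*[:,)]", text))
        if hits > 1:
            dup.append(lbl)
    return sorted(dup)


@dataclass
class BMCovariance:
    """Brownian-motion covariance: entry (i, j) is the root-to-MRCA path
    length (Ma) shared by tips i and j; the diagonal holds root-to-tip
    distances."""

    taxon_order: list
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.taxon_order),) * 2:
            raise ValueError("covariance shape does not match taxon count")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("covariance must be symmetric")
        ev = np.linalg.eigvalsh(self.matrix)
        if ev.min() < -1e-8 * max(ev.max(), 1.0):
            raise ValueError("covariance is not positive semi-definite")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.taxon_order,
                            columns=self.taxon_order)

    def reorder(self, taxa) -> "BMCovariance":
        idx = [self.taxon_order.index(t) for t in taxa]
        return BMCovariance(list(taxa), self.matrix[np.ix_(idx, idx)])


def bm_covariance(tree: Phylogeny) -> BMCovariance:
    """BM covariance of a tree's tips: C[i, j] = depth of MRCA(i, j)."""
    if tree.n_tips < 2:
        raise PhylogenyError("need at least 2 tips for a covariance matrix")
    depths = tree.depths()
    tip_ids = tree.tip_ids
    tip_pos = {t: k for k, t in enumerate(tip_ids)}
    n = len(tip_ids)
    C = np.zeros((n, n))
    # postorder accumulation: tips in different child subtrees of node v
    # share exactly the root-to-v path
    order = tree._preorder()[::-1]
    tipsets: dict = {}
    for v in order:
        kids = tree.children(v)
        if len(kids) == 0:
            tipsets[v] = [tip_pos[v]]
            continue
        groups = [tipsets.pop(c) for c in kids]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        C[i, j] = C[j, i] = depths[v]
        tipsets[v] = [i for g in groups for i in g]
    C[np.diag_indices(n)] = depths[tip_ids]
    return BMCovariance([tree.labels[i] for i in tip_ids], C)


def prune_to(tree: Phylogeny, taxa) -> Phylogeny:
    """Induced subtree on the given tip labels.

    Pairwise path lengths between retained tips are preserved and internal
    degree-2 nodes are suppressed (their branch lengths merged). The
    original root is retained — possibly with a single child — so that
    root-to-MRCA depths, and hence the BM covariance submatrix, are
    preserved exactly.
    """
    taxa = list(taxa)
    labels = set(tree.tip_labels)
    unknown = sorted(set(taxa) - labels)
    if unknown:
        raise PhylogenyError(f"unknown tip labels: {unknown}")
    if len(taxa) < 2:
        raise PhylogenyError("need at least 2 taxa to prune to")
    keep_tip = {i for i in tree.tip_ids if tree.labels[i] in set(taxa)}
    keep = set()
    for i in keep_tip:
        node = i
        while node >= 0 and node not in keep:
            keep.add(node)
            node = tree.parent[node]
    # rebuild, suppressing non-root unifurcations
    new_parent, new_length, new_labels = [], [], []
    mapping: dict = {}

    def add(old: int, parent_new: int, acc_len: float) -> None:
        kids = [c for c in tree.children(old) if c in keep]
        blen = acc_len + (tree.length[old] if tree.parent[old] >= 0 else 0.0)
        if len(kids) == 1 and old != tree.root and old not in keep_tip:
            add(kids[0], parent_new, blen)
            return
        new_id = len(new_parent)
        mapping[old] = new_id
        new_parent.append(parent_new)
        new_length.append(blen)
        new_labels.append(tree.labels[old] if old in keep_tip else None)
        for c in kids:
            add(c, new_id, 0.0)

    add(tree.root, -1, 0.0)
    return Phylogeny(np.array(new_parent), np.array(new_length), new_labels)


def scale_clade_depth(tree: Phylogeny, clade_root: int,
                      target_depth: float) -> Phylogeny:
    """Multiply every branch length inside the clade under ``clade_root`` by
    ``target_depth / current_depth``; branches outside are untouched."""
    depths = tree.depths()
    inside = np.zeros(tree.n_nodes, dtype=bool)
    for i in tree._preorder():
        if i == clade_root:
            inside[i] = True
        elif tree.parent[i] >= 0 and inside[tree.parent[i]]:
            inside[i] = True
    clade_tips = [i for i in tree.tip_ids if inside[i]]
    current = max(depths[i] for i in clade_tips) - depths[clade_root]
    if current <= 0:
        raise PhylogenyError("clade has zero depth; cannot rescale")
    factor = target_depth / current
    length = tree.length.copy()
    scale_mask = inside.copy()
    scale_mask[clade_root] = False  # stem branch above the clade untouched
    length[scale_mask] *= factor
    return Phylogeny(tree.parent.copy(), length, list(tree.labels))


def graft_fossil_tips(host: Phylogeny, subtree: Phylogeny, attach_node: int,
                      attach_age: float, tip_ages: dict,
                      divergence_duration: float = 0.001) -> Phylogeny:
    """Attach a fossil subtree to ``host`` at absolute age ``attach_age``
    (Ma before the host's present).

    The grafted subtree keeps its topology but its internal divergences are
    compressed: a node k edges below the subtree root divides at age
    ``attach_age − k·divergence_duration`` (the study convention of near-
    instant species divergences, default 0.001 Ma = 1,000 years). Each
    grafted tip ends at its own age from ``tip_ages``. If ``attach_age``
    exceeds the age of ``attach_node``, the attachment point is inserted on
    the branch above it.
    """
    if divergence_duration <= 0:
        raise PhylogenyError("divergence_duration must be > 0")
    host_depth = host.depth
    bad = {t: a for t, a in tip_ages.items() if a >= attach_age}
    if bad:
        raise PhylogenyError(
            f"infeasible graft: tip ages {bad} not younger than "
            f"attach_age {attach_age}")

    node_age = host.node_age(attach_node)
    parent = list(host.parent)
    length = list(host.length)
    labels = list(host.labels)

    if attach_age > node_age + 1e-12:
        if attach_node == host.root:
            raise PhylogenyError("attach_age above the root age")
        stem = length[attach_node]
        if attach_age > node_age + stem + 1e-12:
            raise PhylogenyError("attach_age above the parent of attach_node")
        # split the branch above attach_node at attach_age
        new_id = len(parent)
        parent.append(parent[attach_node])
        length.append(stem - (attach_age - node_age))
        labels.append(None)
        parent[attach_node] = new_id
        length[attach_node] = attach_age - node_age
        attach_point = new_id
    else:
        attach_point = attach_node

    # copy the subtree, recomputing branch lengths from ages
    sub_order = subtree._preorder()
    edge_depth = {subtree.root: 0}
    for i in sub_order:
        if i != subtree.root:
            edge_depth[i] = edge_depth[subtree.parent[i]] + 1
    sub_tip_ids = set(subtree.tip_ids)
    new_ids: dict = {}

    def age_of(i: int) -> float:
        if i in sub_tip_ids:
            lbl = subtree.labels[i]
            if lbl not in tip_ages:
                raise PhylogenyError(f"no age given for grafted tip {lbl!r}")
            return tip_ages[lbl]
        return attach_age - edge_depth[i] * divergence_duration

    if subtree.n_tips == 1:
        # single fossil: pendant branch straight from the attach point
        tip = next(iter(sub_tip_ids))
        parent.append(attach_point)
        length.append(attach_age - age_of(tip))
        labels.append(subtree.labels[tip])
    else:
        for i in sub_order:
            new_ids[i] = len(parent)
            if i == subtree.root:
                parent.append(attach_point)
                length.append(MIN_BRANCH_LENGTH)
            else:
                parent.append(new_ids[subtree.parent[i]])
                length.append(age_of(subtree.parent[i]) - age_of(i))
            labels.append(subtree.labels[i] if i in sub_tip_ids else None)

    grafted = Phylogeny(np.array(parent), np.array(length), labels)
    if grafted.depth > host_depth + 1e-9:
        logger.warning("grafted tips extend below the host's present")
    return grafted
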