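"""Phylogeny container, Newick I/O, covariance algebra and branch-length transforms.

A phylogeny is held as a rooted :class:`dendropy.Tree`.  All regression and
prediction machinery in this package works from the phylogenetic
variance-covariance matrix ``V`` derived here: ``V[i, j]`` is the summed branch
length from the root down to the most recent common ancestor of tips *i* and
*j*, so the diagonal holds root-to-tip path lengths.  Under Brownian motion
with unit rate, ``V`` is the covariance matrix of the tip states.

Branch lengths are in arbitrary time units.  A root edge length, if present in
the input Newick, is ignored for covariance purposes (it would add a constant
shared by every pair and is not identifiable in a GLS fit with an intercept).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "CovarianceStructure",
    "ShapeMetrics",
    "TreeError",
    "read_newick",
    "write_newick",
    "vcv",
    "standardize_height",
    "standardize_total_length",
    "transform_lambda",
    "transform_kappa",
    "tree_descriptors",
    "shape_metrics",
    "graft_tip",
    "prune_to_taxa",
    "balanced_tree",
    "pectinate_tree",
]


class TreeError(ValueError):
    """Malformed tree input or an operation violating a tree precondition."""


@dataclass
class Phylogeny:
    """A rooted phylogenetic tree with optional branch lengths.

    Wraps a :class:`dendropy.Tree`.  Tip labels must be unique.  Tips whose
    depth equals the tree height (within a relative tolerance) are *extant*;
    shallower tips represent extinct lineages.
    """

    dtree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            seen, dups = set(), set()
            for lab in labels:
                (dups if lab in seen else seen).add(lab)
            raise TreeError(f"duplicate tip labels: {sorted(dups)}")

    # -- basic structure ---------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.dtree.leaf_node_iter())

    @property
    def has_branch_lengths(self) -> bool:
        """True when every non-root edge carries a branch length."""
        root = self.dtree.seed_node
        return all(
            node.edge.length is not None
            for node in self.dtree.preorder_node_iter()
            if node is not root
        )

    def copy(self) -> "Phylogeny":
        """Structural copy (topology, branch lengths, tip labels).

        Iterative: dendropy's clone() recurses per nesting level and
        overflows the interpreter stack on deep (e.g. pectinate) trees.
        """
        tns = dendropy.TaxonNamespace()
        new_root = dendropy.Node()
        stack = [(self.dtree.seed_node, new_root)]
        while stack:
            old, new = stack.pop()
            new.edge.length = old.edge.length
            if old.taxon is not None:
                taxon = dendropy.Taxon(label=old.taxon.label)
                tns.add_taxon(taxon)
                new.taxon = taxon
            for child in old.child_nodes():
                new_child = dendropy.Node()
                new.add_child(new_child)
                stack.append((child, new_child))
        out = dendropy.Tree(taxon_namespace=tns)
        out.seed_node = new_root
        out.is_rooted = True
        return Phylogeny(out)

    # -- depths ------------------------------------------------------------
    def node_depths(self) -> dict[dendropy.Node, float]:
        """Root-to-node path length for every node (root depth 0)."""
        self._require_lengths()
        depths: dict[dendropy.Node, float] = {}
        root = self.dtree.seed_node
        for node in self.dtree.preorder_node_iter():
            if node is root:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    def tip_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {
            leaf.taxon.label: depths[leaf] for leaf in self.dtree.leaf_node_iter()
        }

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length."""
        return max(self.tip_depths().values())

    def extant_tips(self, rel_tol: float = 1e-8) -> list[str]:
        """Tips whose depth equals the tree height within ``rel_tol`` (relative)."""
        depths = self.tip_depths()
        h = max(depths.values())
        if h == 0.0:
            return sorted(depths)
        return [lab for lab, d in depths.items() if abs(d - h) <= rel_tol * h]

    def _require_lengths(self) -> None:
        if not self.has_branch_lengths:
            raise TreeError("tree has absent branch lengths; transform or assign first")


@dataclass
class CovarianceStructure:
    """Phylogenetic variance-covariance matrix with its tip ordering."""

    V: np.ndarray
    taxon_order: list[str]

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        n = len(self.taxon_order)
        if self.V.shape != (n, n):
            raise ValueError("V shape does not match taxon_order")

    def restrict(self, taxa: list[str]) -> "CovarianceStructure":
        """Sub-matrix for ``taxa`` in the given order."""
        index = {t: i for i, t in enumerate(self.taxon_order)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise KeyError(f"taxa not in covariance structure: {missing}")
        idx = np.array([index[t] for t in taxa])
        return CovarianceStructure(self.V[np.ix_(idx, idx)], list(taxa))

    def cross(self, target: str, taxa: list[str]) -> tuple[np.ndarray, float]:
        """(covariance vector target vs ``taxa``, target self-variance)."""
        index = {t: i for i, t in enumerate(self.taxon_order)}
        h = index[target]
        idx = np.array([index[t] for t in taxa])
        return self.V[h, idx].copy(), float(self.V[h, h])


@dataclass
class ShapeMetrics:
    """Topological balance and branch-length distribution summaries."""

    colless: int
    sackin: int
    stemminess: float


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick string.

    Quoted labels are honoured, underscores are kept literal, and internal
    node labels are ignored.  Missing branch lengths are recorded as absent.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises a zoo of error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    if not any(True for _ in dtree.leaf_node_iter()):
        raise TreeError("empty tree")
    return Phylogeny(dtree)


def write_newick(tree: Phylogeny) -> str:
    """Serialise to Newick with 10 significant digits on branch lengths."""
    out = tree.dtree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )
    return out.strip() + "\n"


# ---------------------------------------------------------------------------
# Covariance
# ---------------------------------------------------------------------------

def vcv(tree: Phylogeny) -> CovarianceStructure:
    """Phylogenetic variance-covariance matrix of the tips.

    ``V[i, j]`` is the root-to-MRCA path length of tips *i* and *j*;
    the diagonal holds root-to-tip paths.  O(n^2) via a single postorder pass.
    """
    tree._require_lengths()
    depths = tree.node_depths()
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))

    # tips_below[node] -> array of tip indices; cross-child pairs coalesce here
    tips_below: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.dtree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            V[i, i] = depths[node]
            tips_below[node] = np.array([i])
        else:
            groups = [tips_below.pop(ch) for ch in node.child_nodes()]
            d = depths[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    V[np.ix_(groups[a], groups[b])] = d
                    V[np.ix_(groups[b], groups[a])] = d
            tips_below[node] = np.concatenate(groups)
    return CovarianceStructure(V, labels)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def standardize_height(tree: Phylogeny) -> Phylogeny:
    """Divide every branch length by the tree height, giving height 1."""
    h = tree.height
    if h <= 0:
        raise TreeError("cannot standardize a zero-height tree")
    return _scale_branches(tree, 1.0 / h)


def standardize_total_length(tree: Phylogeny) -> Phylogeny:
    """Divide every branch length by the summed branch length of the tree.

    The rescaled tree has total branch length 1; relative topology, heights
    and ultrametricity are preserved.
    """
    tree._require_lengths()
    root = tree.dtree.seed_node
    total = sum(
        node.edge.length
        for node in tree.dtree.preorder_node_iter()
        if node is not root
    )
    if total <= 0:
        raise TreeError("cannot standardize a zero-length tree")
    return _scale_branches(tree, 1.0 / total)


def _scale_branches(tree: Phylogeny, factor: float) -> Phylogeny:
    out = tree.copy()
    root = out.dtree.seed_node
    for node in out.dtree.preorder_node_iter():
        if node is not root and node.edge.length is not None:
            node.edge.length = node.edge.length * factor
    return out


def transform_lambda(cov: CovarianceStructure, lam: float) -> CovarianceStructure:
    """Pagel's lambda: multiply off-diagonal covariances by ``lam``.

    ``lam`` measures phylogenetic signal: 0 erases shared history (diagonal
    V), 1 leaves the Brownian expectation untouched.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    V = cov.V * lam
    np.fill_diagonal(V, np.diag(cov.V))
    return CovarianceStructure(V, list(cov.taxon_order))


def transform_kappa(tree: Phylogeny, kappa: float) -> Phylogeny:
    """Pagel's kappa: raise every branch length to the power ``kappa``.

    ``kappa = 0`` maps every branch (including zero-length branches attached
    at polytomies) to length 1, the conventional equal-branch-length tree.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    tree._require_lengths()
    out = tree.copy()
    root = out.dtree.seed_node
    for node in out.dtree.preorder_node_iter():
        if node is root:
            continue
        b = node.edge.length
        node.edge.length = 1.0 if kappa == 0.0 else b**kappa
    return out


# ---------------------------------------------------------------------------
# Descriptors and shape
# ---------------------------------------------------------------------------

def tree_descriptors(tree: Phylogeny) -> tuple[dict[str, float], float, float]:
    """(terminal branch length per tip, mean root-to-tip path, height)."""
    tree._require_lengths()
    terminal = {
        leaf.taxon.label: leaf.edge.length for leaf in tree.dtree.leaf_node_iter()
    }
    depths = tree.tip_depths()
    mean_path = float(np.mean(list(depths.values())))
    return terminal, mean_path, max(depths.values())


def shape_metrics(tree: Phylogeny, strict: bool = True) -> ShapeMetrics:
    """Colless and Sackin imbalance plus stemminess.

    Colless sums ``|n_left - n_right|`` over internal nodes and requires a
    binary topology (``strict=True`` raises on polytomies).  Sackin sums, over
    tips, the number of internal nodes on the root-to-tip path.  Stemminess
    averages, over non-root internal nodes, the fraction of the node's subtree
    branch length (stem edge included) contributed by the stem edge itself:
    values near 1 concentrate branch length toward the root.
    """
    colless = 0
    sackin = 0
    stem_parts: list[float] = []
    root = tree.dtree.seed_node

    n_below: dict[dendropy.Node, int] = {}
    sub_len: dict[dendropy.Node, float] = {}
    for node in tree.dtree.postorder_node_iter():
        children = node.child_nodes()
        if not children:
            n_below[node] = 1
            sub_len[node] = 0.0
            continue
        if len(children) != 2 and strict:
            raise TreeError(
                f"polytomy ({len(children)} children) not allowed in strict shape metrics"
            )
        counts = [n_below[c] for c in children]
        n_below[node] = sum(counts)
        edge_sum = 0.0
        for c in children:
            edge_sum += (c.edge.length or 0.0) + sub_len[c]
        sub_len[node] = edge_sum
        if len(children) == 2:
            colless += abs(counts[0] - counts[1])
        else:
            # generalized Colless: mean pairwise imbalance among children
            for a in range(len(counts)):
                for b in range(a + 1, len(counts)):
                    colless += abs(counts[a] - counts[b])
        if node is not root and node.edge.length is not None:
            b = node.edge.length
            denom = b + sub_len[node]
            if denom > 0:
                stem_parts.append(b / denom)

    for leaf in tree.dtree.leaf_node_iter():
        d = 0
        anc = leaf.parent_node
        while anc is not None:
            d += 1
            anc = anc.parent_node
        sackin += d

    stemminess = float(np.mean(stem_parts)) if stem_parts else math.nan
    return ShapeMetrics(colless=colless, sackin=sackin, stemminess=stemminess)


# ---------------------------------------------------------------------------
# Grafting
# ---------------------------------------------------------------------------

def graft_tip(
    tree: Phylogeny,
    anchor: str | list[str],
    divergence_age: float,
    tip_age: float,
    label: str,
) -> Phylogeny:
    """Attach a new tip, working in ages before the present.

    Ages count backwards from the present (= depth of the deepest tip).  With
    a single ``anchor`` tip label the new lineage diverges along the anchor's
    stem branch at ``divergence_age`` (sister mode).  With a list of labels it
    is added to the basal node of their MRCA clade, which must sit at
    ``divergence_age`` (polytomy mode).  The new terminal branch runs from
    ``divergence_age`` down to ``tip_age`` (its last appearance), so fossils
    get shallower depths than extant tips.
    """
    if tip_age >= divergence_age:
        raise TreeError(
            f"tip_age ({tip_age}) must be younger than divergence_age ({divergence_age})"
        )
    if label in tree.tip_labels:
        raise TreeError(f"label {label!r} already present in tree")
    out = tree.copy()
    depths = out.node_depths()
    height = max(d for n, d in depths.items() if n.is_leaf())
    tol = 1e-9 * max(height, 1.0)

    def node_age(node: dendropy.Node) -> float:
        return height - depths[node]

    leaves = {leaf.taxon.label: leaf for leaf in out.dtree.leaf_node_iter()}
    new_terminal = divergence_age - tip_age

    if isinstance(anchor, str):
        if anchor not in leaves:
            raise TreeError(f"anchor tip {anchor!r} not found")
        node = leaves[anchor]
        parent = node.parent_node
        if parent is None:
            raise TreeError("cannot graft as sister to the root")
        stem_old, stem_young = node_age(parent), node_age(node)
        if not (stem_young - tol <= divergence_age <= stem_old + tol):
            raise TreeError(
                f"divergence age {divergence_age} outside anchor stem branch "
                f"[{stem_young:.6g}, {stem_old:.6g}]"
            )
        # split the stem edge at the divergence point
        upper = divergence_age  # age of the new internal node
        new_internal = dendropy.Node()
        parent.remove_child(node)
        parent.add_child(new_internal)
        new_internal.edge.length = max(stem_old - upper, 0.0)
        new_internal.add_child(node)
        node.edge.length = max(upper - stem_young, 0.0)
        attach = new_internal
    else:
        mrca = out.dtree.mrca(taxon_labels=list(anchor))
        if mrca is None:
            raise TreeError(f"no MRCA found for anchor clade {anchor}")
        if abs(node_age(mrca) - divergence_age) > max(tol, 1e-6 * max(height, 1.0)):
            raise TreeError(
                f"divergence age {divergence_age} does not match clade basal node age "
                f"{node_age(mrca):.6g}"
            )
        attach = mrca

    taxon = dendropy.Taxon(label=label)
    out.dtree.taxon_namespace.add_taxon(taxon)
    new_tip = dendropy.Node(taxon=taxon)
    attach.add_child(new_tip)
    new_tip.edge.length = new_terminal
    return Phylogeny(out.dtree)


def prune_to_taxa(tree: Phylogeny, keep: list[str]) -> Phylogeny:
    """Retain only ``keep`` tips; unifurcations are suppressed with branch
    lengths summed, so covariances among surviving tips are unchanged."""
    present = set(tree.tip_labels)
    missing = [t for t in keep if t not in present]
    if missing:
        raise TreeError(f"taxa not in tree: {missing}")
    out = tree.copy()
    out.dtree.retain_taxa_with_labels(keep)
    out.dtree.purge_taxon_namespace()
    # dendropy keeps the root even if it became a unifurcation with an edge;
    # suppress it so root-to-tip paths stay interpretable
    out.dtree.suppress_unifurcations()
    root = out.dtree.seed_node
    while len(root.child_nodes()) == 1:
        (child,) = root.child_nodes()
        out.dtree.seed_node = child
        child.parent_node = None
        child.edge.length = None
        root = child
    return Phylogeny(out.dtree)


# ---------------------------------------------------------------------------
# Deterministic end-member topologies
# ---------------------------------------------------------------------------

def balanced_tree(n_tips: int, height: float = 1.0) -> Phylogeny:
    """Fully balanced binary tree (requires ``n_tips`` a power of two).

    Every split is even, so Colless imbalance is 0; branch lengths divide the
    height evenly over the log2(n) levels.
    """
    k = int(round(math.log2(n_tips)))
    if 2**k != n_tips:
        raise ValueError("balanced tree needs a power-of-two tip count")
    step = height / k if k else height

    def build(labels: list[str]) -> str:
        if len(labels) == 1:
            return f"{labels[0]}:{step}"
        mid = len(labels) // 2
        return f"({build(labels[:mid])},{build(labels[mid:])}):{step}"

    labels = [f"t{i+1}" for i in range(n_tips)]
    if k == 0:
        return read_newick(f"{labels[0]}:{height};")
    mid = n_tips // 2
    inner = f"({build(labels[:mid])},{build(labels[mid:])});"
    return read_newick(inner)


def pectinate_tree(n_tips: int, height: float = 1.0) -> Phylogeny:
    """Maximally imbalanced ladder (caterpillar) tree, ultrametric."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    steps = n_tips - 1
    step = height / steps
    # innermost cherry sits at depth height - step
    text = f"(t1:{step},t2:{step})"
    for i in range(2, n_tips):
        depth_remaining = i * step
        text = f"({text}:{step},t{i+1}:{depth_remaining})"
    return read_newick(text + ";")
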