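"""Rooted phylogenies with fossil tips: Newick IO, covariance matrices, rate rescaling.

A :class:`Phylogeny` is a rooted, binary (after polytomy resolution) tree with
non-negative branch lengths in time units.  Extinct species appear as tips whose
root-to-tip depth is smaller than the tree height, so trees need not be
ultrametric.  Each branch is identified by the label of its child node; internal
nodes without a label receive deterministic ``N<k>`` labels in preorder.

Under Brownian motion the expected trait covariance between two tips equals the
depth of their most recent common ancestor, which :meth:`Phylogeny.vcv` returns
for all tip pairs at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "read_newick",
    "parse_newick",
    "write_newick",
]


class NewickError(ValueError):
    """Raised for malformed or incomplete Newick input."""


@dataclass
class PhyloCovariance:
    """Brownian-motion covariance of a tree: shared root-to-MRCA path lengths.

    ``matrix[i, j]`` is the depth of the MRCA of tips ``tip_order[i]`` and
    ``tip_order[j]``; the diagonal holds tip depths.  Symmetric and positive
    semi-definite by construction.
    """

    matrix: np.ndarray
    tip_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("covariance matrix must be square")
        if len(self.tip_order) != self.matrix.shape[0]:
            raise ValueError("tip_order length must match matrix dimension")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def reorder(self, tip_order: list[str]) -> "PhyloCovariance":
        """Return the covariance restricted/permuted to ``tip_order``."""
        pos = {t: i for i, t in enumerate(self.tip_order)}
        missing = [t for t in tip_order if t not in pos]
        if missing:
            raise KeyError(f"tips not in covariance: {missing}")
        idx = np.array([pos[t] for t in tip_order])
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(tip_order))


class Phylogeny:
    """Array-backed rooted tree built from a dendropy tree.

    Nodes are stored in preorder; ``parent[i]`` indexes the parent of node ``i``
    (``-1`` for the root) and ``lengths[i]`` is the length of the branch above
    node ``i`` (0 for the root).  Branches are named by their child node.
    """

    def __init__(self, dtree: dendropy.Tree, _validated: bool = False):
        if not _validated:
            _validate(dtree)
            _resolve_polytomies(dtree)
        self._dtree = dtree
        self._build_arrays()

    # -- construction ------------------------------------------------------

    def _build_arrays(self) -> None:
        nodes = list(self._dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.lengths = np.zeros(n, dtype=float)
        labels: list[str] = []
        auto = 0
        seen: set[str] = set()
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[i] = index[id(nd.parent_node)]
                self.lengths[i] = float(nd.edge.length or 0.0)
            if nd.is_leaf():
                lab = nd.taxon.label
            else:
                lab = nd.label
                if not lab or lab in seen:
                    auto += 1
                    lab = f"N{auto}"
                    while lab in seen:
                        auto += 1
                        lab = f"N{auto}"
            labels.append(lab)
            seen.add(lab)
        self.node_labels = labels
        self._nodes = nodes
        self.tip_indices = np.array([i for i, nd in enumerate(nodes) if nd.is_leaf()])
        self.tip_labels = [labels[i] for i in self.tip_indices]
        # depths by preorder accumulation (parents precede children)
        depth = np.zeros(n, dtype=float)
        for i in range(1, n):
            depth[i] = depth[self.parent[i]] + self.lengths[i]
        self.node_depths = depth
        # branches: every non-root node, in preorder
        self.branch_nodes = np.arange(1, n)
        self.branch_ids = [labels[i] for i in self.branch_nodes]
        self.branch_lengths = self.lengths[self.branch_nodes]

    # -- basic properties --------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def tip_depths(self) -> np.ndarray:
        return self.node_depths[self.tip_indices]

    @property
    def height(self) -> float:
        return float(self.tip_depths.max())

    def fossil_tips(self, rel_tol: float = 1e-9) -> list[str]:
        """Tips that do not reach the present (depth < height)."""
        h = self.height
        return [
            lab
            for lab, d in zip(self.tip_labels, self.tip_depths)
            if d < h * (1.0 - rel_tol)
        ]

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    # -- matrices ----------------------------------------------------------

    def incidence_matrix(self) -> np.ndarray:
        """0/1 matrix (tips x branches): 1 where the branch lies on the
        root-to-tip path."""
        n_br = len(self.branch_nodes)
        branch_col = {node: j for j, node in enumerate(self.branch_nodes)}
        inc = np.zeros((self.n_tips, n_br))
        for row, tip in enumerate(self.tip_indices):
            node = tip
            while node != 0:  # root is preorder index 0
                inc[row, branch_col[node]] = 1.0
                node = self.parent[node]
        return inc

    def vcv(self) -> PhyloCovariance:
        """Brownian-motion covariance: shared path length from the root."""
        inc = self.incidence_matrix()
        mat = (inc * self.branch_lengths) @ inc.T
        mat = 0.5 * (mat + mat.T)
        return PhyloCovariance(mat, list(self.tip_labels))

    # -- manipulation ------------------------------------------------------

    def with_branch_lengths(self, new_lengths: np.ndarray) -> "Phylogeny":
        """Copy of the tree with branch lengths replaced (aligned to
        ``branch_ids``)."""
        new_lengths = np.asarray(new_lengths, dtype=float)
        if new_lengths.shape != self.branch_lengths.shape:
            raise ValueError("length vector does not match branch count")
        if not np.all(np.isfinite(new_lengths)) or np.any(new_lengths < 0):
            raise ValueError("branch lengths must be finite and >= 0")
        clone = dendropy.Tree(self._dtree)
        nodes = list(clone.preorder_node_iter())
        for node_idx, length in zip(self.branch_nodes, new_lengths):
            nodes[node_idx].edge.length = float(length)
        return Phylogeny(clone, _validated=True)

    def rescale_by_rates(
        self,
        rates: np.ndarray | dict[str, float],
        preserve: str = "sum",
        floor_frac: float = 1e-8,
    ) -> "Phylogeny":
        """Multiply each branch by the absolute value of its evolutionary rate,
        then renormalize so total evolutionary time is conserved.

        ``preserve='sum'`` (default) conserves the sum of branch lengths, which
        is well defined for non-ultrametric trees; ``preserve='height'``
        conserves the maximum tip depth instead.  Branches whose rate is zero
        are floored at ``floor_frac`` times the mean rescaled branch length so
        the covariance stays positive definite.
        """
        if isinstance(rates, dict):
            missing = [b for b in self.branch_ids if b not in rates]
            if missing:
                raise KeyError(f"rates missing for branches: {missing[:5]}...")
            rates = np.array([rates[b] for b in self.branch_ids], dtype=float)
        rates = np.abs(np.asarray(rates, dtype=float))
        if rates.shape != self.branch_lengths.shape:
            raise ValueError("rates do not match branch count")
        if not np.any(rates > 0):
            raise ValueError("all rates are zero: degenerate rescaling")
        scaled = self.branch_lengths * rates
        floor = floor_frac * scaled[scaled > 0].mean()
        scaled = np.maximum(scaled, floor)
        if preserve == "sum":
            const = self.branch_lengths.sum() / scaled.sum()
        elif preserve == "height":
            tmp = self.with_branch_lengths(scaled)
            const = self.height / tmp.height
        else:
            raise ValueError("preserve must be 'sum' or 'height'")
        return self.with_branch_lengths(scaled * const)

    def keep_tips(self, tips) -> "Phylogeny":
        """Prune the tree down to the given tip labels."""
        keep = set(tips)
        missing = sorted(keep - set(self.tip_labels))
        if missing:
            raise KeyError(f"tips not in tree: {missing}")
        if keep == set(self.tip_labels):
            return self
        clone = dendropy.Tree(self._dtree)
        clone.retain_taxa_with_labels(sorted(keep))
        clone.seed_node.edge.length = None
        return Phylogeny(clone, _validated=True)

    # -- IO ----------------------------------------------------------------

    def to_newick(self) -> str:
        s = self._dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        )
        return s.strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self) -> str:
        return (
            f"Phylogeny(n_tips={self.n_tips}, height={self.height:.4g}, "
            f"fossil_tips={len(self.fossil_tips())})"
        )


def _validate(dtree: dendropy.Tree) -> None:
    labels = [lf.taxon.label if lf.taxon else "" for lf in dtree.leaf_node_iter()]
    if any(not lab for lab in labels):
        raise NewickError("tree contains unlabeled or empty-label tips")
    dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
    if dupes:
        raise NewickError(f"duplicate tip labels: {dupes}")
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        if nd.edge.length is None:
            who = nd.taxon.label if nd.taxon else (nd.label or "an internal node")
            raise NewickError(
                f"missing branch length above {who!r}; branch lengths are mandatory"
            )
        bl = float(nd.edge.length)
        if not np.isfinite(bl) or bl < 0:
            raise NewickError(f"invalid branch length {bl!r}")


def _subtree_key(nd) -> tuple[int, str]:
    tips = [lf.taxon.label for lf in nd.leaf_iter()]
    return (len(tips), min(tips))


def _resolve_polytomies(dtree: dendropy.Tree) -> None:
    """Resolve multifurcations deterministically (ladderized by subtree size,
    ties by smallest tip label) with zero-length internal branches.

    Zero-length branches leave the Brownian covariance unchanged, so the
    resolution is statistically neutral.
    """
    for nd in list(dtree.preorder_node_iter()):
        children = nd.child_nodes()
        while len(children) > 2:
            children.sort(key=_subtree_key)
            a, b = children[0], children[1]
            for ch in (a, b):
                nd.remove_child(ch)
            joint = dendropy.Node()
            joint.edge.length = 0.0
            joint.add_child(a)
            joint.add_child(b)
            nd.add_child(joint)
            children = nd.child_nodes()


def parse_newick(newick: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`."""
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    return Phylogeny(dtree)


def read_newick(path) -> Phylogeny:
    """Read a strict Newick file (branch lengths mandatory, unique tips)."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Phylogeny, path) -> None:
    tree.write_newick(path)
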