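"""Rooted time trees with node ages in Ma.

The container is a flat array representation (parent pointers + ages) that the
MCMC can update in place; conversion to and from :mod:`dendropy` handles all
Newick/NEXUS serialization.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

from ._errors import ConstraintMappingError, InvalidTreeError

__all__ = ["TimeTree"]

_ULTRAMETRIC_TOL = 1e-6


class TimeTree:
    """A rooted, binary, ultrametric tree with tips at age 0.

    Nodes are indexed ``0 .. n_nodes-1`` with tips first (in the order of
    ``tip_names``) followed by internal nodes in postorder; the root is the
    last index.  Ages are in Ma; the branch above node ``i`` has duration
    ``age[parent[i]] - age[i]`` Myr.
    """

    def __init__(self, tip_names, parent, ages):
        self.tip_names = list(tip_names)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.ages = np.asarray(ages, dtype=float).copy()
        self.n_tips = len(self.tip_names)
        self.n_nodes = len(self.parent)
        if len(set(self.tip_names)) != self.n_tips:
            raise InvalidTreeError("duplicate tip names")
        self.children = [[] for _ in range(self.n_nodes)]
        root = None
        for i, p in enumerate(self.parent):
            if p < 0:
                if root is not None:
                    raise InvalidTreeError("tree has more than one root")
                root = i
            else:
                self.children[p].append(i)
        if root is None:
            raise InvalidTreeError("tree has no root")
        self.root = root
        for i in range(self.n_tips, self.n_nodes):
            if len(self.children[i]) != 2:
                raise InvalidTreeError(
                    f"internal node {i} has {len(self.children[i])} children; "
                    "only rooted binary trees are supported"
                )
        self.postorder = self._compute_postorder()
        self.validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TimeTree":
        tree = tree.clone(depth=1)
        # ages from root distances; ultrametricity is checked by validate()
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                nd._depth = 0.0
            else:
                nd._depth = nd.parent_node._depth + (nd.edge.length or 0.0)
        height = max(lf._depth for lf in tree.leaf_node_iter())
        for nd in tree.preorder_node_iter():
            nd.age = height - nd._depth
        leaves = [lf for lf in tree.leaf_node_iter()]
        tip_names = [lf.taxon.label for lf in leaves]
        internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
        for nd in internals:
            if len(nd.child_nodes()) != 2:
                raise InvalidTreeError(
                    "unsupported tree: polytomy at node with children "
                    f"{sorted(lf.taxon.label for lf in nd.leaf_iter())}"
                )
        index = {}
        for i, lf in enumerate(leaves):
            index[lf] = i
        for j, nd in enumerate(internals):
            index[nd] = len(leaves) + j
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=np.int64)
        ages = np.zeros(n)
        for nd, i in index.items():
            ages[i] = nd.age
            if nd.parent_node is not None:
                parent[i] = index[nd.parent_node]
        return cls(tip_names, parent, ages)

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
        return cls.from_dendropy(tree)

    # -- serialization -----------------------------------------------------

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.tip_names)
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = {}
        for i in range(self.n_nodes):
            nd = dendropy.Node()
            if i < self.n_tips:
                nd.taxon = taxa.get_taxon(self.tip_names[i])
            nodes[i] = nd
        for i, p in enumerate(self.parent):
            if p >= 0:
                nodes[p].add_child(nodes[i])
                nodes[i].edge.length = float(self.ages[p] - self.ages[i])
        tree.seed_node = nodes[self.root]
        tree.is_rooted = True
        return tree

    def to_newick(self) -> str:
        s = io.StringIO()
        self.to_dendropy().write(file=s, schema="newick", suppress_rooting=True)
        return s.getvalue().strip()

    # -- structure queries -------------------------------------------------

    def _compute_postorder(self):
        order, stack = [], [self.root]
        visited = set()
        while stack:
            nd = stack[-1]
            if nd in visited or nd < self.n_tips:
                order.append(stack.pop())
                continue
            visited.add(nd)
            stack.extend(self.children[nd])
        return [nd for nd in order]

    @property
    def internal_nodes(self):
        return list(range(self.n_tips, self.n_nodes))

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def tip_index(self, name: str) -> int:
        try:
            return self.tip_names.index(name)
        except ValueError:
            raise ConstraintMappingError(f"unknown tip name {name!r}") from None

    def clade_tips(self, node: int):
        """Names of the tips descending from ``node``."""
        out, stack = [], [node]
        while stack:
            nd = stack.pop()
            if nd < self.n_tips:
                out.append(self.tip_names[nd])
            else:
                stack.extend(self.children[nd])
        return out

    def mrca(self, tip_names) -> int:
        """Most recent common ancestor of a set of tip names."""
        tips = {self.tip_index(nm) for nm in tip_names}
        if not tips:
            raise ConstraintMappingError("empty tip set")
        if len(tips) == 1:
            return next(iter(tips))
        # intersect root paths
        paths = []
        for t in tips:
            path, nd = [], t
            while nd >= 0:
                path.append(nd)
                nd = self.parent[nd]
            paths.append(path)
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common ancestor = first common node on any root path
        for nd in paths[0]:
            if nd in common:
                return nd
        raise ConstraintMappingError("disconnected tips")  # pragma: no cover

    def monophyletic_mrca(self, tip_names) -> int:
        """MRCA whose clade is exactly ``tip_names``; error otherwise."""
        node = self.mrca(tip_names)
        clade = set(self.clade_tips(node))
        if clade != set(tip_names):
            raise ConstraintMappingError(
                f"tip set {sorted(tip_names)} is not monophyletic; its MRCA "
                f"also contains {sorted(clade - set(tip_names))}"
            )
        return node

    # -- validation and editing --------------------------------------------

    def validate(self):
        ages = self.ages
        for i in range(self.n_tips):
            if abs(ages[i]) > _ULTRAMETRIC_TOL * max(1.0, self.root_age):
                raise InvalidTreeError(
                    f"tip {self.tip_names[i]!r} has age {ages[i]:g}; time trees "
                    "must be ultrametric with all tips at age 0"
                )
        for i, p in enumerate(self.parent):
            if p >= 0 and ages[p] <= ages[i]:
                raise InvalidTreeError(
                    f"node {i} (age {ages[i]:g}) is not younger than its "
                    f"parent {p} (age {ages[p]:g})"
                )

    def ages_valid(self, ages=None) -> bool:
        """Parent-older-than-child check without raising (MCMC hot path)."""
        a = self.ages if ages is None else ages
        for i, p in enumerate(self.parent):
            if p >= 0 and a[p] <= a[i]:
                return False
        return True

    def subtree_internal_nodes(self, node: int):
        """Internal nodes within the subtree rooted at ``node`` (inclusive)."""
        out, stack = [], [node]
        while stack:
            nd = stack.pop()
            if nd >= self.n_tips:
                out.append(nd)
                stack.extend(self.children[nd])
        return out

    def copy(self) -> "TimeTree":
        return TimeTree(self.tip_names, self.parent.copy(), self.ages.copy())

    def __repr__(self):  # pragma: no cover
        return (
            f"TimeTree(n_tips={self.n_tips}, root_age={self.root_age:.3f} Ma)"
        )
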