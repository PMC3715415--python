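"""Rooted species tree with stable branch identifiers.

Each node owns the branch directly above it; the root's branch is the
origin branch on which a gene family can first appear.  Branch IDs are
therefore node IDs, assigned in preorder, so a tree with M nodes exposes
M branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


@dataclass
class SpeciesTree:
    """Rooted tree over a fixed, ordered leaf set.

    Attributes
    ----------
    parent : list[int]
        ``parent[i]`` is the parent node ID of node ``i``; the root has
        parent ``-1``.  Node 0 is always the root.
    children : list[list[int]]
        Child node IDs per node.
    leaf_name : dict[int, str]
        Node ID -> leaf label, for leaves only.
    """

    parent: list[int]
    children: list[list[int]]
    leaf_name: dict[int, str]
    rooted_by: str = "input"
    _leaf_order: list[str] = field(default_factory=list)
    _masks: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self._leaf_order:
            self._leaf_order = sorted(self.leaf_name.values())
        for node, kids in enumerate(self.children):
            if kids and len(kids) < 2:
                raise TreeError(f"internal node {node} has a single child")
        names = list(self.leaf_name.values())
        if len(set(names)) != len(names):
            raise TreeError("duplicate leaf labels")

    # -- basic structure -------------------------------------------------

    @property
    def root(self) -> int:
        return 0

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_branches(self) -> int:
        """One branch per node, the root's origin branch included."""
        return len(self.parent)

    @property
    def leaves(self) -> list[str]:
        """Leaf labels in panel order."""
        return list(self._leaf_order)

    @property
    def leaf_nodes(self) -> list[int]:
        name_to_node = {v: k for k, v in self.leaf_name.items()}
        return [name_to_node[n] for n in self._leaf_order]

    def set_leaf_order(self, order: Sequence[str]) -> None:
        if set(order) != set(self.leaf_name.values()):
            raise TreeError("leaf order does not match tree leaf set")
        self._leaf_order = list(order)
        self._masks = None

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    # -- leaf masks and LCA ----------------------------------------------

    def subtree_leaf_masks(self) -> np.ndarray:
        """Boolean array (n_nodes, n_leaves): leaves under each node.

        Leaf columns follow panel order (``self.leaves``).
        """
        if self._masks is None:
            n_leaves = len(self._leaf_order)
            masks = np.zeros((self.n_nodes, n_leaves), dtype=bool)
            col = {name: i for i, name in enumerate(self._leaf_order)}
            for node in self.postorder():
                if self.is_leaf(node):
                    masks[node, col[self.leaf_name[node]]] = True
                else:
                    for child in self.children[node]:
                        masks[node] |= masks[child]
            self._masks = masks
        return self._masks

    def lca(self, presence: np.ndarray) -> int:
        """Lowest node whose subtree contains every present leaf.

        ``presence`` is a boolean vector in panel leaf order with at
        least one True entry.
        """
        presence = np.asarray(presence, dtype=bool)
        if not presence.any():
            raise TreeError("LCA of an empty leaf set is undefined")
        masks = self.subtree_leaf_masks()
        node = self.root
        n_present = int(presence.sum())
        while True:
            for child in self.children[node]:
                if int((masks[child] & presence).sum()) == n_present:
                    node = child
                    break
            else:
                return node

    def is_ancestor(self, anc: int, node: int) -> bool:
        """True iff ``anc`` lies on the path from ``node`` to the root
        (a node is its own ancestor)."""
        while node != -1:
            if node == anc:
                return True
            node = self.parent[node]
        return False

    # -- I/O --------------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str, rooted_by: str = "input") -> "SpeciesTree":
        """Parse a Newick string (or text of one tree) into a SpeciesTree."""
        try:
            dtree = dendropy.Tree.get(
                data=source,
                schema="newick",
                rooting="force-rooted",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"malformed Newick: {exc}") from exc
        return cls._from_dendropy(dtree, rooted_by=rooted_by)

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree, rooted_by: str = "input") -> "SpeciesTree":
        dnodes = list(dtree.preorder_node_iter())
        index = {id(dn): i for i, dn in enumerate(dnodes)}
        parent = [-1] * len(dnodes)
        children: list[list[int]] = [[] for _ in dnodes]
        leaf_name: dict[int, str] = {}
        for i, dn in enumerate(dnodes):
            if dn.parent_node is not None:
                p = index[id(dn.parent_node)]
                parent[i] = p
                children[p].append(i)
            if dn.is_leaf():
                if dn.taxon is None or not dn.taxon.label:
                    raise TreeError("unlabelled leaf in Newick input")
                label = dn.taxon.label.replace(" ", "_")
                if label in leaf_name.values():
                    raise TreeError(f"duplicate leaf label {label!r}")
                leaf_name[i] = label
        return cls(parent=parent, children=children, leaf_name=leaf_name,
                   rooted_by=rooted_by)

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if self.is_leaf(node):
                return self.leaf_name[node]
            inner = ",".join(render(c) for c in self.children[node])
            return f"({inner})"

        return render(self.root) + ";"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpeciesTree):
            return NotImplemented
        return self.to_newick() == other.to_newick()
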