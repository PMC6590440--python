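"""Minimal rooted-tree structure shared by the parsimony and rate modules.

Newick parsing/writing delegates to dendropy; internally a plain Node
tree keeps the dynamic programs simple.  Polytomies are allowed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy

__all__ = ["Node", "parse_newick", "to_newick"]


@dataclass
class Node:
    label: str
    children: list["Node"] = field(default_factory=list)
    length: float | None = None
    parent: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find(self, label: str) -> "Node":
        for n in self.postorder():
            if n.label == label:
                return n
        raise KeyError(label)

    def branches(self) -> list["Node"]:
        """All non-root nodes; each identifies the branch to its parent."""
        return [n for n in self.postorder() if n.parent is not None]

    def copy(self) -> "Node":
        node = Node(self.label, length=self.length)
        for c in self.children:
            cc = c.copy()
            cc.parent = node
            node.children.append(cc)
        return node


def _convert(dnode, counter) -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label.replace(" ", "_") if dnode.taxon else dnode.label or f"t{next(counter)}"
    else:
        label = (dnode.label or f"N{next(counter)}").replace(" ", "_")
    node = Node(label=label, length=dnode.edge.length)
    for child in dnode.child_nodes():
        cn = _convert(child, counter)
        cn.parent = node
        node.children.append(cn)
    return node


def parse_newick(newick: str) -> Node:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    counter = itertools.count(1)
    return _convert(tree.seed_node, counter)


def to_newick(root: Node, lengths: dict[str, float] | None = None, digits: int = 6) -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = node.label
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.parent is not None:
                s += node.label
        bl = lengths.get(node.label) if lengths is not None else node.length
        if bl is not None and node.parent is not None:
            s += f":{bl:.{digits}f}"
        return s

    return fmt(root) + ";"
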