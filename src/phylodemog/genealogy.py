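"""Rooted ultrametric genealogies with branch lengths in generations.

A thin tree container used both by the coalescent simulator and by the
minimum-sorting-events test. Newick round-tripping goes through dendropy.
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy

__all__ = ["GNode", "Genealogy"]


class GNode:
    __slots__ = ("children", "parent", "time", "label")

    def __init__(
        self,
        time: float = 0.0,
        label: Optional[str] = None,
        children: Optional[list["GNode"]] = None,
    ):
        self.children: list[GNode] = children or []
        self.parent: Optional[GNode] = None
        self.time = float(time)  # generations before present
        self.label = label
        for c in self.children:
            c.parent = self

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "GNode") -> None:
        child.parent = self
        self.children.append(child)


class Genealogy:
    """Rooted binary genealogy; tips at time 0, node times in generations."""

    def __init__(self, root: GNode):
        self.root = root

    # -- traversal --------------------------------------------------------
    def postorder(self) -> Iterator[GNode]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def tips(self) -> list[GNode]:
        return [n for n in self.postorder() if n.is_tip]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    def tmrca(self) -> float:
        return self.root.time

    def branch_length(self, node: GNode) -> float:
        if node.parent is None:
            return 0.0
        return node.parent.time - node.time

    def total_length(self) -> float:
        return sum(self.branch_length(n) for n in self.postorder())

    def validate(self) -> None:
        for node in self.postorder():
            for c in node.children:
                if c.time > node.time + 1e-9:
                    raise ValueError("child older than parent")
        tips = self.tips()
        internal = sum(1 for n in self.postorder() if not n.is_tip)
        if any(len(n.children) not in (0, 2) for n in self.postorder()):
            raise ValueError("genealogy must be binary")
        if internal != len(tips) - 1:
            raise ValueError("rooted binary tree needs n-1 internal nodes")

    # -- newick -----------------------------------------------------------
    def _newick_of(self, node: GNode) -> str:
        if node.is_tip:
            core = node.label or ""
        else:
            core = "(" + ",".join(self._newick_of(c) for c in node.children) + ")"
        if node.parent is None:
            return core
        return f"{core}:{self.branch_length(node):.8g}"

    def to_newick(self) -> str:
        return self._newick_of(self.root) + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, source: str, is_path: bool = False) -> "Genealogy":
        kwargs = {"path": source} if is_path else {"data": source}
        tree = dendropy.Tree.get(schema="newick", **kwargs)
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Genealogy":
        # node depths -> times before present, deepest tip at 0
        depth: dict = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                depth[node] = 0.0
            else:
                depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        max_depth = max(depth.values())

        def build(node) -> GNode:
            label = None
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                if label is not None:
                    label = label.replace(" ", "_")
            g = GNode(time=max_depth - depth[node], label=label)
            for c in node.child_nodes():
                g.add_child(build(c))
            return g

        return cls(build(tree.seed_node))

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick")
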