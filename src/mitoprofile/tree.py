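"""A small mutable unrooted-tree structure with Newick I/O.

The tree is stored rooted at an arbitrary node purely for traversal; for an
unrooted binary tree of n taxa the root is a trifurcation and there are 2n−3
branches. Newick text is parsed with dendropy and converted; writing is done
directly. Internal-node labels hold split support values when present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # -- traversal -----------------------------------------------------
    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        out.reverse()
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def taxa(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def n_branches(self) -> int:
        return len(self.postorder()) - 1

    def copy(self) -> "Tree":
        def clone(n: Node) -> Node:
            c = Node(n.name, n.length, n.support)
            for ch in n.children:
                c.add(clone(ch))
            return c

        return Tree(clone(self.root))

    # -- splits --------------------------------------------------------
    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-side frozenset of
        taxon names (canonicalized by min taxon on ties)."""
        all_taxa = frozenset(self.taxa())
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.name])
            else:
                below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
            if n is self.root or n.is_leaf:
                continue
            side = below[id(n)]
            other = all_taxa - side
            if len(side) < 2 or len(other) < 2:
                continue
            out.add(_canon(side, other))
        return out

    def suppress_unifurcations(self) -> None:
        for n in self.postorder():
            if n is self.root or len(n.children) != 1:
                continue
            child = n.children[0]
            child.length += n.length
            p = n.parent
            p.children[p.children.index(n)] = child
            child.parent = p
        while len(self.root.children) == 1:
            self.root = self.root.children[0]
            self.root.parent = None
            self.root.length = 0.0

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({to_newick(self)})"


def collapse_short_branches(tree: Tree, eps: float = 1e-6) -> Tree:
    """Collapse internal branches of length <= eps into multifurcations
    (used to flag star-like, unresolved results)."""
    changed = True
    while changed:
        changed = False
        for n in tree.postorder():
            if n.is_leaf or n is tree.root or n.length > eps:
                continue
            p = n.parent
            idx = p.children.index(n)
            p.children[idx : idx + 1] = n.children
            for c in n.children:
                c.parent = p
            changed = True
            break
    return tree


def _canon(a: frozenset, b: frozenset) -> frozenset:
    if len(a) != len(b):
        return a if len(a) < len(b) else b
    return a if min(a) < min(b) else b


def to_newick(tree: Tree, support: bool = False) -> str:
    def fmt(n: Node, top: bool) -> str:
        if n.is_leaf:
            body = n.name or ""
        else:
            inner = ",".join(fmt(c, False) for c in n.children)
            label = ""
            if support and n.support is not None:
                label = f"{n.support:g}"
            body = f"({inner}){label}"
        if top:
            return body
        return f"{body}:{n.length:.10g}"

    return fmt(tree.root, True) + ";"


def from_newick(text: str) -> Tree:
    dt = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

    def conv(dn) -> Node:
        name = dn.taxon.label if dn.taxon is not None else (dn.label or None)
        node = Node(
            name=name if dn.is_leaf() else None,
            length=dn.edge.length or 0.0,
        )
        if not dn.is_leaf() and name is not None:
            try:
                node.support = float(name)
            except ValueError:
                node.name = name
        for c in dn.child_nodes():
            node.add(conv(c))
        return node

    return Tree(conv(dt.seed_node))


def write_newick(tree: Tree, path, support: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, support=support) + "\n")


def read_newick(path) -> Tree:
    with open(path) as fh:
        return from_newick(fh.read())


def random_bifurcating(taxa: list[str], rng, min_bl: float = 0.02, max_bl: float = 0.3) -> Tree:
    """Uniform-ish random unrooted binary tree via sequential addition."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    rng.shuffle(taxa)
    root = Node()
    for t in taxa[:3]:
        root.add(Node(t, float(rng.uniform(min_bl, max_bl))))
    tree = Tree(root)
    for t in taxa[3:]:
        edges = [n for n in tree.postorder() if n is not tree.root]
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = Node(length=float(rng.uniform(min_bl, max_bl)))
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        target.length = float(rng.uniform(min_bl, max_bl))
        mid.add(Node(t, float(rng.uniform(min_bl, max_bl))))
    return tree
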