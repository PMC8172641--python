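"""Rooted phylogenetic trees: parsing, canonical writing, and traversal.

Species trees carry node identities at which duplications are counted and
WGDs are placed; gene trees use ``SPECIES|gene`` leaf labels.  Parsing is
delegated to dendropy; the canonical writer (children ordered by smallest
descendant leaf label, branch lengths at 10 significant digits) is local so
that output is byte-stable across runs.
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy

#: reserved separator between species and gene identifiers in gene-tree leaves
LEAF_SEP = "|"


class NewickError(ValueError):
    """Malformed newick input or invalid tree structure."""


class Node:
    """A node of a rooted tree.

    ``depth`` is the time from the root (filled in by :meth:`Tree.set_depths`
    or directly by the simulators); ``id`` is a deterministic post-order
    index assigned by :class:`Tree`.
    """

    __slots__ = ("label", "length", "children", "parent", "id", "depth")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.id: Optional[int] = None
        self.depth: Optional[float] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> Iterator["Node"]:
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label!r} id={self.id}>"


class Tree:
    """A rooted tree with deterministic post-order node ids."""

    def __init__(self, root: Node):
        self.root = root
        self.assign_ids()

    # ------------------------------------------------------------------ ids
    def assign_ids(self) -> None:
        for i, node in enumerate(self.root.postorder()):
            node.id = i

    # ------------------------------------------------------------- traversal
    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> list[Node]:
        return list(self.root.leaves())

    def leaf_labels(self) -> list[str]:
        return [lf.label for lf in self.root.leaves()]

    def find(self, label: str) -> Optional[Node]:
        for node in self.root.preorder():
            if node.label == label:
                return node
        return None

    # ------------------------------------------------------------ geometry
    def set_depths(self) -> None:
        """Fill ``node.depth`` = summed branch length from the root."""
        self.root.depth = 0.0
        for node in self.root.preorder():
            if node.parent is not None:
                node.depth = node.parent.depth + (node.length or 0.0)

    def height(self) -> float:
        self.set_depths()
        return max(lf.depth for lf in self.root.leaves())

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        self.set_depths()
        depths = [lf.depth for lf in self.root.leaves()]
        return max(depths) - min(depths) < tol

    def is_ladder(self) -> bool:
        """True if every internal node has at most one non-leaf child."""
        for node in self.root.preorder():
            if not node.is_leaf:
                internal_children = sum(1 for c in node.children if not c.is_leaf)
                if internal_children > 1:
                    return False
        return True

    def mrca(self, labels: set[str]) -> Node:
        """Most recent common ancestor of the named leaves."""
        want = set(labels)
        for node in self.root.postorder():
            have = {lf.label for lf in node.leaves()}
            if want <= have:
                return node
        raise KeyError(f"labels not all present in tree: {sorted(want)}")

    # ---------------------------------------------------------------- copy
    def copy(self) -> "Tree":
        def _cp(n: Node) -> Node:
            m = Node(n.label, n.length)
            m.depth = n.depth
            for c in n.children:
                m.add_child(_cp(c))
            return m

        return Tree(_cp(self.root))

    # ------------------------------------------------------------- rerooting
    def rerooted_at_leaf(self, leaf_label: str) -> "Tree":
        """Return a copy rooted on the edge above the named leaf.

        The new root is a bifurcation with the named leaf on one side (its
        branch split in half) and the rest of the tree on the other.
        Unifurcations created at the old root are suppressed.
        """
        work = self.copy()
        leaf = work.find(leaf_label)
        if leaf is None or not leaf.is_leaf:
            raise KeyError(f"no leaf labelled {leaf_label!r}")
        if leaf.parent is None:
            raise NewickError("cannot reroot a single-node tree")

        half = (leaf.length / 2.0) if leaf.length is not None else None
        new_root = Node()
        old_parent = leaf.parent
        old_parent.children.remove(leaf)
        leaf.length = half
        new_root.add_child(leaf)

        # invert the path from old_parent up to the old root
        prev, carry_len = new_root, half
        node = old_parent
        while node is not None:
            up = node.parent
            up_len = node.length
            if up is not None:
                up.children.remove(node)
            node.parent = None
            node.length = carry_len
            prev.add_child(node)
            prev, carry_len, node = node, up_len, up

        # suppress any unifurcation left at the old root position
        for n in list(new_root.preorder()):
            if len(n.children) == 1 and n.parent is not None:
                (only,) = n.children
                only.length = (n.length or 0.0) + (only.length or 0.0)
                p = n.parent
                i = p.children.index(n)
                p.children[i] = only
                only.parent = p
        return Tree(new_root)

    # -------------------------------------------------------------- newick
    @classmethod
    def from_newick(cls, text: str, rooted_required: bool = False) -> "Tree":
        return read_newick(text, rooted_required=rooted_required)

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree {len(self.leaves())} leaves>"


# --------------------------------------------------------------------------
# newick I/O
# --------------------------------------------------------------------------

def read_newick(text: str, rooted_required: bool = False) -> Tree:
    """Parse a single newick statement into a :class:`Tree`.

    Raises :class:`NewickError` on malformed input, duplicate leaf labels or
    negative branch lengths.  Node ids are assigned in post-order, so trees
    parsed from the same text always carry the same ids.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError("newick statement must end with ';'")
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse error: {exc}") from exc

    def _convert(dnode) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        if node.length is not None and node.length < 0:
            raise NewickError(
                f"negative branch length {node.length} at {label or '<internal>'}"
            )
        for child in dnode.child_nodes():
            node.add_child(_convert(child))
        return node

    root = _convert(dt.seed_node)
    tree = Tree(root)
    labels = tree.leaf_labels()
    if any(lb is None for lb in labels):
        raise NewickError("unlabelled leaf in newick input")
    dupes = {lb for lb in labels if labels.count(lb) > 1}
    if dupes:
        raise NewickError(f"duplicate leaf labels: {sorted(dupes)}")
    if rooted_required and len(root.children) > 2:
        raise NewickError("tree is unrooted (root has more than two children)")
    return tree


def _min_leaf_label(node: Node) -> str:
    return min(lf.label for lf in node.leaves())


def write_newick(tree: Tree) -> str:
    """Canonical newick: children ordered by smallest descendant leaf label,
    branch lengths printed with 10 significant digits."""

    def _fmt(node: Node) -> str:
        if node.is_leaf:
            core = node.label or ""
        else:
            kids = sorted(node.children, key=_min_leaf_label)
            core = "(" + ",".join(_fmt(c) for c in kids) + ")"
            if node.label:
                core += node.label
        if node.length is not None:
            core += f":{node.length:.10g}"
        return core

    return _fmt(tree.root) + ";"


# --------------------------------------------------------------------------
# gene-tree leaf labels
# --------------------------------------------------------------------------

def make_leaf_label(species: str, gene: str) -> str:
    if LEAF_SEP in species or LEAF_SEP in gene:
        raise ValueError(f"{LEAF_SEP!r} is reserved in species/gene identifiers")
    return f"{species}{LEAF_SEP}{gene}"


def split_leaf_label(label: str) -> tuple[str, str]:
    """Split ``SPECIES|gene`` into its parts."""
    if LEAF_SEP not in label:
        raise ValueError(f"gene-tree leaf label {label!r} lacks {LEAF_SEP!r}")
    species, gene = label.split(LEAF_SEP, 1)
    return species, gene


def leaf_species(tree: Tree) -> set[str]:
    return {split_leaf_label(lf.label)[0] for lf in tree.leaves()}
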