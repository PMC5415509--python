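"""Rooted phylogenies: a lightweight node/tree container plus Newick IO.

The tree is always treated as rooted.  Polytomies are allowed, branch
lengths are optional (but must be non-negative where present), and tip
labels must be unique and non-empty.  Newick parsing is delegated to
dendropy; the in-memory representation here is the container every other
module (parsimony, signal estimation, PGLS) operates on.
"""

from __future__ import annotations

import io
from typing import Callable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "Node",
    "Phylogeny",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "make_ultrametric",
]


class NewickParseError(ValueError):
    """Malformed Newick input; message names the offending character offset."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (duplicate tips, negative lengths, ...)."""


class Node:
    __slots__ = ("id", "label", "length", "parent", "children")

    def __init__(self, id: int, label: Optional[str] = None,
                 length: Optional[float] = None):
        self.id = id
        self.label = label
        self.length = length
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.id}, {self.label!r})"


class Phylogeny:
    """A rooted tree with optional branch lengths and possible polytomies."""

    def __init__(self, root: Node):
        self.root = root
        self._index()
        self.validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    def _index(self) -> None:
        self.nodes: list[Node] = list(self.preorder())
        for i, nd in enumerate(self.nodes):
            nd.id = i
        self._tips = [nd for nd in self.nodes if nd.is_leaf]
        self._label_to_tip = {}
        for nd in self._tips:
            self._label_to_tip[nd.label] = nd

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return iter(reversed(out))

    # -- basic queries -----------------------------------------------------

    @property
    def tips(self) -> list[Node]:
        return list(self._tips)

    @property
    def tip_labels(self) -> list[str]:
        return [nd.label for nd in self._tips]

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def tip(self, label: str) -> Node:
        try:
            return self._label_to_tip[label]
        except KeyError:
            raise KeyError(f"no tip labelled {label!r}") from None

    def has_branch_lengths(self) -> bool:
        return all(nd.length is not None for nd in self.nodes
                   if nd is not self.root)

    def depths(self) -> dict[int, float]:
        """Root-to-node path lengths; requires branch lengths everywhere."""
        out = {self.root.id: 0.0}
        for nd in self.preorder():
            if nd is self.root:
                continue
            if nd.length is None:
                raise TreeValidationError(
                    f"missing branch length on the branch above node "
                    f"{nd.label or nd.id}")
            out[nd.id] = out[nd.parent.id] + nd.length
        return out

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths()
        tip_depths = [d[t.id] for t in self._tips]
        span = max(tip_depths) - min(tip_depths)
        return span <= rel_tol * max(max(tip_depths), 1e-300)

    def mrca(self, labels: Sequence[str]) -> Node:
        """Most recent common ancestor of the given tip labels."""
        if not labels:
            raise ValueError("mrca() of an empty label set")
        paths = []
        for lab in labels:
            nd = self.tip(lab)
            path = []
            while nd is not None:
                path.append(nd)
                nd = nd.parent
            paths.append(list(reversed(path)))
        mrca = self.root
        for level in zip(*paths):
            first = level[0]
            if all(nd is first for nd in level):
                mrca = first
            else:
                break
        return mrca

    def clade_tip_labels(self, node: Node) -> set[str]:
        out = set()
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                out.add(nd.label)
            else:
                stack.extend(nd.children)
        return out

    def clades(self) -> set[frozenset[str]]:
        """The set of tip-label sets of all internal nodes (for isomorphism
        comparisons)."""
        return {frozenset(self.clade_tip_labels(nd))
                for nd in self.nodes if not nd.is_leaf}

    def induced(self, labels: Iterable[str]) -> "Phylogeny":
        """The subtree induced by the given tip labels, with degree-one
        internal nodes suppressed (their branch lengths summed)."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        if not keep:
            raise ValueError("cannot induce an empty subtree")

        def build(nd: Node) -> Optional[Node]:
            if nd.is_leaf:
                if nd.label not in keep:
                    return None
                return Node(0, label=nd.label, length=nd.length)
            kids = [k for k in (build(c) for c in nd.children)
                    if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                if child.length is not None and nd.length is not None:
                    child.length += nd.length
                elif nd.length is not None and child.length is None:
                    child.length = nd.length
                return child
            new = Node(0, label=nd.label, length=nd.length)
            for k in kids:
                new.add_child(k)
            return new

        root = build(self.root)
        root.length = None
        return Phylogeny(root)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        seen: set[str] = set()
        for nd in self._tips:
            if not nd.label:
                raise TreeValidationError("tip with empty label")
            if nd.label in seen:
                raise TreeValidationError(f"duplicate tip label {nd.label!r}")
            seen.add(nd.label)
        for nd in self.nodes:
            if nd.length is not None and nd.length < 0:
                raise TreeValidationError(
                    f"negative branch length {nd.length} above node "
                    f"{nd.label or nd.id}")
            if nd is not self.root and nd.parent is None:
                raise TreeValidationError(f"non-root node {nd.id} has no parent")

    # -- serialisation -----------------------------------------------------

    def to_newick(self) -> str:
        return write_newick(self)

    def copy(self) -> "Phylogeny":
        return parse_newick(self.to_newick())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips>"


# -- Newick IO -------------------------------------------------------------

def parse_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick string into a :class:`Phylogeny`.

    Underscores in unquoted labels are preserved verbatim (no conversion to
    spaces).  Malformed input raises :class:`NewickParseError` naming the
    character offset; duplicate tip labels raise
    :class:`TreeValidationError`.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty Newick string (at character 0)")
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"Newick string must end with ';' (at character {len(text) - 1})")
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' (at character {i})")
    if depth != 0:
        raise NewickParseError(
            f"unbalanced '(' (at character {text.rindex('(')})")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate taxon" in str(exc) or "Multiple occurrences" in str(exc):
            raise TreeValidationError(
                f"duplicate tip labels in Newick input: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        nd = Node(0, label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            nd.add_child(convert(child))
        return nd

    root = convert(dtree.seed_node)
    return Phylogeny(root)


def _format_label(label: str) -> str:
    specials = set("()[]{}:;, \t\n'\"")
    if any(ch in specials for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _node_newick(nd: Node) -> str:
    if nd.is_leaf:
        s = _format_label(nd.label)
    else:
        s = "(" + ",".join(_node_newick(c) for c in nd.children) + ")"
        if nd.label:
            s += _format_label(nd.label)
    if nd.length is not None:
        s += f":{nd.length:.12g}"
    return s


def write_newick(tree: Phylogeny) -> str:
    """Serialise; a single-tip tree is written as ``A;``."""
    root = tree.root
    if root.is_leaf:
        s = _format_label(root.label)
        if root.length is not None:
            s += f":{root.length:.12g}"
        return s + ";"
    return _node_newick(root) + ";"


def make_ultrametric(tree: Phylogeny, depth: float = 1.0) -> Phylogeny:
    """Equal-steps chronogram: assign branch lengths so every tip sits at
    the same distance ``depth`` from the root.

    Node heights are spaced evenly along each root-to-tip path (each
    internal node at height proportional to its maximum number of nodes to
    a descendant tip).  Used to obtain a crude time-calibrated version of a
    topology-only tree for demonstration runs; it is not an inference
    method.
    """
    out = tree.copy()
    levels: dict[int, int] = {}
    for nd in out.postorder():
        levels[nd.id] = 0 if nd.is_leaf else 1 + max(levels[c.id]
                                                     for c in nd.children)
    height: dict[int, float] = {}
    root_levels = levels[out.root.id]
    height[out.root.id] = float(root_levels)
    for nd in out.preorder():
        if nd is out.root:
            continue
        height[nd.id] = float(levels[nd.id])
        nd.length = (height[nd.parent.id] - height[nd.id]) * depth / root_levels
    return out
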