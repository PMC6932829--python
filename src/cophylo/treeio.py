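"""Trees, associations, and the surgery the reconciliation pipeline needs.

The central container is :class:`PhyloTree`, a lightweight rooted/unrooted
tree over uniquely labeled tips.  Newick reading goes through dendropy (so
quoted labels, bracket comments and RAxML/MrBayes output styles are
tolerated); writing is a plain serializer that round-trips topology.

Rootedness follows the usual convention: a basal trifurcation (or higher
polytomy at the base) marks an unrooted tree, a basal bifurcation a rooted
one.  Branch lengths are parsed and carried along but every downstream
operation in this package treats trees as cladograms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy

from .errors import (
    DuplicateLabelError,
    NewickParseError,
    ValidationError,
)

__all__ = [
    "Node",
    "PhyloTree",
    "TreeSet",
    "AssociationTable",
    "parse_newick",
    "write_newick",
    "read_newick",
    "enumerate_rootings",
    "augment_host_tree",
    "read_associations",
    "parse_associations",
    "resolve_polytomies",
]

_NEEDS_QUOTE = set(" ()[]{}:;,'\"\t\n=")


class Node:
    """One tree node: a label (tips), children, parent and optional length."""

    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label: str | None = None, length: float | None = None,
                 children: Iterable["Node"] | None = None):
        self.label = label
        self.length = length
        self.parent: Node | None = None
        self.children: list[Node] = []
        if children is not None:
            for c in children:
                self.add_child(c)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, {len(self.children)} children)"


def _copy_subtree(node: Node) -> Node:
    new = Node(node.label, node.length)
    for c in node.children:
        new.add_child(_copy_subtree(c))
    return new


def _suppress_unifurcations(root: Node) -> Node:
    """Splice out internal nodes with exactly one child; may return new root."""
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    stack = [root]
    while stack:
        node = stack.pop()
        new_children = []
        for c in node.children:
            while len(c.children) == 1:
                c = c.children[0]
            c.parent = node
            new_children.append(c)
            stack.append(c)
        node.children = new_children
    return root


class PhyloTree:
    """Rooted or unrooted phylogenetic tree with uniquely labeled tips."""

    def __init__(self, root: Node, rooted: bool | None = None):
        self.root = root
        self._relink()
        if rooted is None:
            rooted = len(root.children) < 3
        self.rooted = bool(rooted)
        self._check_labels()

    # -- construction ----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def _relink(self) -> None:
        self.root.parent = None
        for node in self.preorder():
            for c in node.children:
                c.parent = node

    def _check_labels(self) -> None:
        seen: set[str] = set()
        for tip in self.tips():
            if tip.label is None or tip.label == "":
                raise ValidationError("every tip must carry a label")
            if tip.label in seen:
                raise DuplicateLabelError(
                    f"duplicate tip label {tip.label!r}")
            seen.add(tip.label)

    # -- traversal -------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def tips(self) -> Iterator[Node]:
        return (n for n in self.preorder() if n.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def label_set(self) -> frozenset:
        return frozenset(self.tip_labels)

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    def find_tip(self, label: str) -> Node:
        for t in self.tips():
            if t.label == label:
                return t
        raise ValidationError(f"tip {label!r} not found in tree")

    def mrca(self, labels: Sequence[str]) -> Node:
        want = set(labels)
        missing = want - self.label_set
        if missing:
            raise ValidationError(
                f"unknown attachment clade label(s): {sorted(missing)}")
        best = None
        for node in self.postorder():
            if best is not None:
                continue
            below = {t.label for t in _subtree_tips(node)}
            if want <= below:
                best = node
        return best if best is not None else self.root

    # -- structure checks ------------------------------------------------
    def is_binary(self) -> bool:
        for node in self.preorder():
            if node.is_tip:
                continue
            if node is self.root:
                expect = 2 if self.rooted else 3
                if len(node.children) != expect:
                    return False
            elif len(node.children) != 2:
                return False
        return True

    def validate(self, require_binary: bool = False) -> None:
        self._check_labels()
        if require_binary and not self.is_binary():
            raise ValidationError("tree is not binary")

    # -- transforms ------------------------------------------------------
    def copy(self) -> "PhyloTree":
        return PhyloTree(_copy_subtree(self.root), rooted=self.rooted)

    def unroot(self) -> "PhyloTree":
        """Return an unrooted copy (basal trifurcation) of a rooted tree."""
        if not self.rooted:
            return self.copy()
        if self.n_tips < 3:
            raise ValidationError("cannot unroot a tree with fewer than 3 tips")
        root = _copy_subtree(self.root)
        # merge one internal child of the root into the root
        internal = next((c for c in root.children if c.children), None)
        if internal is None:  # pragma: no cover - needs >=3 tips, so exists
            raise ValidationError("cannot unroot: no internal root child")
        root.children.remove(internal)
        for gc in internal.children:
            root.add_child(gc)
        return PhyloTree(root, rooted=False)

    # -- comparisons -----------------------------------------------------
    def rooted_clades(self) -> frozenset:
        """Non-trivial clades (tip-label sets below each internal node)."""
        clades = set()
        for node in self.preorder():
            if node.is_tip or node is self.root:
                continue
            clades.add(frozenset(t.label for t in _subtree_tips(node)))
        return frozenset(c for c in clades if len(c) > 1)

    def bipartitions(self) -> frozenset:
        """Non-trivial splits of the tip set, for unrooted comparison."""
        all_tips = self.label_set
        n = len(all_tips)
        splits = set()
        for node in self.preorder():
            if node is self.root or node.is_tip:
                continue
            side = frozenset(t.label for t in _subtree_tips(node))
            if len(side) < 2 or len(side) > n - 2:
                continue
            other = frozenset(all_tips - side)
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return frozenset(splits)

    # -- serialization ---------------------------------------------------
    def newick(self, lengths: bool = True) -> str:
        return _serialize(self.root, lengths) + ";"

    def write(self, path) -> None:
        Path(path).write_text(self.newick() + "\n")


def _subtree_tips(node: Node) -> Iterator[Node]:
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.is_tip:
            yield cur
        else:
            stack.extend(cur.children)


def _format_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _serialize(node: Node, lengths: bool) -> str:
    if node.is_tip:
        out = _format_label(node.label)
    else:
        out = "(" + ",".join(_serialize(c, lengths) for c in node.children) + ")"
    if lengths and node.length is not None:
        out += f":{node.length:g}"
    return out


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse one Newick string into a :class:`PhyloTree`.

    Quoted labels and bracket comments are accepted; internal node labels
    are parsed but ignored downstream.  A basal polytomy marks the tree as
    unrooted.  Duplicate tip labels raise :class:`DuplicateLabelError`.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from None
    root = _from_dendropy(dtree.seed_node)
    return PhyloTree(root)


def _from_dendropy(dnode) -> Node:
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = Node(label, dnode.edge.length)
    for c in dnode.child_nodes():
        node.add_child(_from_dendropy(c))
    return node


def write_newick(tree: PhyloTree, path=None) -> str:
    text = tree.newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(path) -> PhyloTree:
    return parse_newick(Path(path).read_text())


# ---------------------------------------------------------------------------
# TreeSet
# ---------------------------------------------------------------------------

class TreeSet(Sequence):
    """Ordered collection of trees over one shared tip-label set."""

    def __init__(self, trees: Iterable[PhyloTree]):
        self._trees = list(trees)
        if not self._trees:
            raise ValidationError("a TreeSet must contain at least one tree")
        ref = self._trees[0].label_set
        for i, t in enumerate(self._trees[1:], start=1):
            if t.label_set != ref:
                raise ValidationError(
                    f"tree {i} has a different tip-label set than tree 0")

    def __len__(self) -> int:
        return len(self._trees)

    def __getitem__(self, i):
        return self._trees[i]

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self._trees)

    @property
    def label_set(self) -> frozenset:
        return self._trees[0].label_set

    @classmethod
    def read(cls, path) -> "TreeSet":
        lines = [ln for ln in Path(path).read_text().splitlines()
                 if ln.strip()]
        return cls(parse_newick(ln) for ln in lines)

    def write(self, path) -> None:
        Path(path).write_text(
            "".join(t.newick() + "\n" for t in self._trees))


# ---------------------------------------------------------------------------
# Rooting enumeration
# ---------------------------------------------------------------------------

def enumerate_rootings(tree: PhyloTree) -> TreeSet:
    """All rooted versions of an unrooted tree, one per edge.

    The new root bisects the chosen edge; for a binary unrooted tree on n
    tips this yields exactly 2n-3 rooted binary trees.
    """
    if tree.rooted:
        raise ValidationError("enumerate_rootings requires an unrooted tree")
    if tree.n_tips < 3:
        raise ValidationError("need at least 3 tips to enumerate rootings")
    n_edges = sum(1 for _ in tree.preorder()) - 1
    out = []
    for i in range(n_edges):
        c = _copy_subtree(tree.root)
        nodes = _preorder_nodes(c)[1:]
        out.append(_root_at_edge(nodes[i]))
    return TreeSet(out)


def _preorder_nodes(root: Node) -> list[Node]:
    # stand-alone preorder (parent links may be stale during surgery)
    order, stack = [], [root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(node.children))
    return order


def _root_at_edge(v: Node) -> PhyloTree:
    u = v.parent
    u.children.remove(v)
    new_root = Node()
    new_root.add_child(v)
    new_root.add_child(_invert(u))
    root = _suppress_unifurcations(new_root)
    return PhyloTree(root, rooted=True)


def _invert(node: Node) -> Node:
    """Re-hang ``node`` so its former parent becomes one of its children."""
    parent = node.parent
    if parent is not None:
        parent.children.remove(node)
        node.add_child(_invert(parent))
    node.length = None
    return node


# ---------------------------------------------------------------------------
# Host-tree augmentation (placeholder outlier branches)
# ---------------------------------------------------------------------------

def augment_host_tree(host: PhyloTree, placeholders: Sequence[str],
                      attachments: dict | None = None) -> PhyloTree:
    """Attach placeholder tips (e.g. "unidentified insect") to a host tree.

    Each placeholder becomes the sister of an attachment clade: by default
    the whole tree (basal attachment); ``attachments`` may map a placeholder
    label to a tip label or list of tip labels whose MRCA is used instead.
    The output stays binary (one new tip + one new internal node each).
    """
    attachments = attachments or {}
    tree = host.copy()
    for label in placeholders:
        if label in tree.label_set:
            raise DuplicateLabelError(
                f"placeholder {label!r} collides with an existing tip")
        spec = attachments.get(label)
        if spec is None:
            target = tree.root
        else:
            labels = [spec] if isinstance(spec, str) else list(spec)
            target = tree.mrca(labels)
        tree = _attach_sister(tree, target, label)
    return tree


def _attach_sister(tree: PhyloTree, target: Node, label: str) -> PhyloTree:
    new_internal = Node()
    tip = Node(label)
    parent = target.parent
    if parent is None:
        new_internal.add_child(target)
        new_internal.add_child(tip)
        return PhyloTree(new_internal, rooted=tree.rooted)
    idx = parent.children.index(target)
    parent.children[idx] = new_internal
    new_internal.parent = parent
    new_internal.add_child(target)
    new_internal.add_child(tip)
    return PhyloTree(tree.root, rooted=tree.rooted)


# ---------------------------------------------------------------------------
# Associations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationTable:
    """Many-to-one mapping from dependent-tree tips to independent-tree tips.

    ``independent_labels`` records the full tip-label universe of the
    independent tree (needed by host-tip-renaming randomization, which must
    permute over all host tips, not only the ones in use).
    """

    pairs: tuple
    independent_labels: tuple = None
    missing_dependents: tuple = ()

    def __post_init__(self):
        if not self.pairs:
            raise ValidationError("association table must contain >=1 pair")
        seen = set()
        for dep, ind in self.pairs:
            if dep in seen:
                raise ValidationError(
                    f"dependent tip {dep!r} listed more than once")
            seen.add(dep)

    @property
    def mapping(self) -> dict:
        return dict(self.pairs)

    @property
    def dependents(self) -> tuple:
        return tuple(d for d, _ in self.pairs)

    @property
    def targets(self) -> tuple:
        return tuple(i for _, i in self.pairs)

    @classmethod
    def from_pairs(cls, pairs, dep_tree: PhyloTree | None = None,
                   ind_tree: PhyloTree | None = None,
                   allow_missing: bool = False) -> "AssociationTable":
        pairs = tuple((str(d), str(i)) for d, i in pairs)
        if not pairs:
            raise ValidationError("association table must contain >=1 pair")
        ind_labels = None
        missing: tuple = ()
        if ind_tree is not None:
            ind_labels = tuple(ind_tree.tip_labels)
            unknown = [i for _, i in pairs if i not in set(ind_labels)]
            if unknown:
                raise ValidationError(
                    f"independent label(s) not in tree: {sorted(set(unknown))}")
        if dep_tree is not None:
            dep_tips = dep_tree.label_set
            unknown = [d for d, _ in pairs if d not in dep_tips]
            if unknown:
                raise ValidationError(
                    f"dependent label(s) not in tree: {sorted(set(unknown))}")
            missing = tuple(sorted(dep_tips - {d for d, _ in pairs}))
            if missing and not allow_missing:
                raise ValidationError(
                    "dependent tips without an association entry: "
                    f"{list(missing)}")
        return cls(pairs=pairs, independent_labels=ind_labels,
                   missing_dependents=missing)

    @classmethod
    def identity(cls, labels: Iterable[str],
                 ind_tree: PhyloTree | None = None) -> "AssociationTable":
        labels = list(labels)
        return cls(pairs=tuple((l, l) for l in labels),
                   independent_labels=(tuple(ind_tree.tip_labels)
                                       if ind_tree else tuple(labels)))

    def to_tsv(self, path) -> None:
        Path(path).write_text(
            "".join(f"{d}\t{i}\n" for d, i in self.pairs))


def parse_associations(text: str, dep_tree: PhyloTree | None = None,
                       ind_tree: PhyloTree | None = None,
                       allow_missing: bool = False) -> AssociationTable:
    """Parse two-column tab-separated associations (dependent first).

    Lines starting with '#' and blank lines are ignored.
    """
    pairs = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) != 2:
            raise ValidationError(
                f"line {lineno}: expected 2 tab-separated columns, "
                f"got {len(cols)}")
        pairs.append((cols[0], cols[1]))
    if not pairs:
        raise ValidationError("association file contains no pairs")
    return AssociationTable.from_pairs(
        pairs, dep_tree=dep_tree, ind_tree=ind_tree,
        allow_missing=allow_missing)


def read_associations(path, dep_tree: PhyloTree | None = None,
                      ind_tree: PhyloTree | None = None,
                      allow_missing: bool = False) -> AssociationTable:
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"association file not found: {p}")
    return parse_associations(p.read_text(), dep_tree=dep_tree,
                              ind_tree=ind_tree, allow_missing=allow_missing)


# ---------------------------------------------------------------------------
# Polytomy resolution
# ---------------------------------------------------------------------------

def resolve_polytomies(tree: PhyloTree, seed: int = 0) -> PhyloTree:
    """Binarize a rooted tree, replacing each k-tomy by a random caterpillar.

    New internal edges get length 0; deterministic for a fixed seed; a
    k-furcation gains exactly k-2 internal nodes.  Existing bipartitions are
    preserved (the caterpillar only adds clades nested inside the polytomy).
    """
    if not tree.rooted:
        raise ValidationError("resolve_polytomies requires a rooted tree")
    out = tree.copy()
    rng = random.Random(seed)
    for node in list(out.postorder()):
        if len(node.children) <= 2:
            continue
        kids = list(node.children)
        rng.shuffle(kids)
        left = kids[0]
        for nxt in kids[1:-1]:
            combined = Node(length=0.0)
            combined.add_child(left)
            combined.add_child(nxt)
            left = combined
        node.children = []
        node.add_child(left)
        node.add_child(kids[-1])
    return PhyloTree(out.root, rooted=True)
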