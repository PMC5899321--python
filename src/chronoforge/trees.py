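"""Rooted phylogenetic trees: Newick I/O, consensus, support comparison, branch statistics.

Two tree flavours are used throughout the package:

* :class:`Phylogram` — branch lengths in expected substitutions per site;
* :class:`Chronogram` — node ages in million years (Mya), tips at age 0.

Both are rooted; polytomies are allowed. Clades are represented as frozensets
of taxon names so that support bookkeeping is invariant to node numbering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Node",
    "Phylogram",
    "Chronogram",
    "NewickError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "chronogram_from_newick",
    "majority_rule_consensus",
    "max_clade_support_diff",
    "node_to_tip_distances",
    "PathStats",
]


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class TreeValidationError(ValueError):
    pass


class Node:
    """A node of a rooted tree.

    ``length`` is the branch above the node (None for the root or when the
    tree carries no lengths).  ``support`` is a clade frequency in [0, 1].
    ``age`` is used by chronograms (Mya before present).
    """

    __slots__ = ("name", "length", "support", "age", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.support: Optional[float] = None
        self.age: Optional[float] = None
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> List["Node"]:
        return [n for n in self.postorder() if n.is_leaf]


class RootedTree:
    """Shared machinery for phylograms and chronograms."""

    def __init__(self, root: Node):
        self.root = root

    # -- iteration ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> List[Node]:
        return self.root.leaves()

    @property
    def taxa(self) -> FrozenSet[str]:
        return frozenset(leaf.name for leaf in self.leaves())

    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- clades ------------------------------------------------------------
    def clade_map(self) -> Dict[Node, FrozenSet[str]]:
        """Map every node to the frozenset of its descendant taxon names."""
        out: Dict[Node, FrozenSet[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[node] = frozenset([node.name])
            else:
                acc: set = set()
                for child in node.children:
                    acc.update(out[child])
                out[node] = frozenset(acc)
        return out

    def nontrivial_clades(self) -> List[FrozenSet[str]]:
        """Internal clades excluding the root clade and singletons."""
        full = self.taxa
        cm = self.clade_map()
        return [
            c
            for node, c in cm.items()
            if not node.is_leaf and 1 < len(c) < len(full)
        ]

    def mrca(self, taxa: Iterable[str]) -> Node:
        wanted = frozenset(taxa)
        missing = wanted - self.taxa
        if missing:
            raise TreeValidationError(f"taxa absent from tree: {sorted(missing)}")
        cm = self.clade_map()
        best: Optional[Node] = None
        best_size = math.inf
        for node, clade in cm.items():
            if wanted <= clade and len(clade) < best_size:
                best, best_size = node, len(clade)
        assert best is not None
        return best

    def copy(self):
        return parse_newick(write_newick(self)) if isinstance(self, Phylogram) else _copy_tree(self)

    def validate(self) -> None:
        names = [leaf.name for leaf in self.leaves()]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreeValidationError(f"duplicate leaf names: {dupes}")
        if any(n is None or n == "" for n in names):
            raise TreeValidationError("every leaf must be named")


def _copy_tree(tree: "RootedTree"):
    def rec(node: Node) -> Node:
        new = Node(node.name, node.length)
        new.support = node.support
        new.age = node.age
        for c in node.children:
            new.add_child(rec(c))
        return new

    cls = type(tree)
    return cls(rec(tree.root))


class Phylogram(RootedTree):
    """Rooted tree with branch lengths in substitutions/site."""

    def validate(self) -> None:
        super().validate()
        for node in self.postorder():
            if node is self.root:
                continue
            if node.length is not None and node.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.length} above {node.name or 'internal node'}"
                )
            if node.support is not None and not (0.0 <= node.support <= 1.0):
                raise TreeValidationError(f"support {node.support} outside [0, 1]")

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)


class Chronogram(RootedTree):
    """Rooted ultrametric tree with node ages in Mya; tips at age 0."""

    def validate(self) -> None:
        super().validate()
        for node in self.postorder():
            if node.age is None:
                raise TreeValidationError("every node of a chronogram needs an age")
            if node.is_leaf and abs(node.age) > 1e-9:
                raise TreeValidationError(f"tip {node.name} has nonzero age {node.age}")
            for child in node.children:
                if child.age is None or not node.age > child.age:
                    raise TreeValidationError(
                        f"parent age {node.age} not older than child age {child.age}"
                    )

    @property
    def root_age(self) -> float:
        return float(self.root.age)

    def internal_nodes(self) -> List[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def branch_durations(self) -> Dict[Node, float]:
        """Time spanned by the branch above each non-root node (Mya)."""
        return {
            n: float(n.parent.age - n.age)
            for n in self.postorder()
            if n.parent is not None
        }

    def to_phylogram(self, branch_lengths: Dict[Node, float]) -> Phylogram:
        def rec(node: Node) -> Node:
            new = Node(node.name, branch_lengths.get(node))
            for c in node.children:
                new.add_child(rec(c))
            return new

        return Phylogram(rec(self.root))


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_LABEL_FORBIDDEN = set("(),:;[] \t\n'\"")


def parse_newick(text: str) -> Phylogram:
    """Parse a Newick string into a rooted :class:`Phylogram`.

    Numeric internal-node labels are interpreted as clade supports; values
    above 1 are taken as percentages and divided by 100.  Errors report the
    0-based character offset of the offending token.
    """
    s = text.strip()
    if not s:
        raise NewickError("empty Newick string", 0)
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(msg, pos)

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in _LABEL_FORBIDDEN:
            pos += 1
        return s[start:pos]

    def parse_number(context: str) -> float:
        nonlocal pos
        start = pos
        while pos < len(s) and (s[pos].isdigit() or s[pos] in "+-.eE"):
            pos += 1
        token = s[start:pos]
        try:
            return float(token)
        except ValueError:
            raise NewickError(f"expected a number for {context}, got {token!r}", start)

    def parse_clade() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_clade())
                if pos >= len(s):
                    raise error("unterminated clade: missing ')'")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r} inside clade")
            label = parse_label()
            if label:
                try:
                    support = float(label)
                except ValueError:
                    node.name = label
                else:
                    node.support = support / 100.0 if support > 1.0 else support
        else:
            label = parse_label()
            if not label:
                raise error("expected a taxon label")
            node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            node.length = parse_number("branch length")
        return node

    root = parse_clade()
    if pos >= len(s) or s[pos] != ";":
        raise error("expected ';' at end of tree")
    pos += 1
    if s[pos:].strip():
        raise error("trailing characters after ';'")
    tree = Phylogram(root)
    tree.validate()
    return tree


def _fmt_length(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: RootedTree, *, supports: bool = True, lengths: bool = True) -> str:
    """Serialize a rooted tree to Newick.

    Supports are written as numeric internal-node labels with 4 decimals;
    branch lengths with 10 significant digits.
    """

    def rec(node: Node) -> str:
        if node.is_leaf:
            out = node.name or ""
        else:
            out = "(" + ",".join(rec(c) for c in node.children) + ")"
            if supports and node.support is not None:
                out += f"{node.support:.4f}"
            elif node.name:
                out += node.name
        if lengths and node.length is not None and node.parent is not None:
            out += f":{_fmt_length(node.length)}"
        return out

    return rec(tree.root) + ";"


def chronogram_from_newick(text: str, *, tol: float = 1e-6) -> Chronogram:
    """Read a chronogram whose branch lengths are time durations (Mya).

    Node ages are reconstructed from root-to-tip depths; the tree must be
    ultrametric within ``tol`` relative to the root age.
    """
    phylo = parse_newick(text)
    depth: Dict[Node, float] = {phylo.root: 0.0}
    for node in phylo.preorder():
        if node is phylo.root:
            continue
        depth[node] = depth[node.parent] + (node.length or 0.0)
    height = max(depth[leaf] for leaf in phylo.leaves())
    for leaf in phylo.leaves():
        if abs(depth[leaf] - height) > tol * max(height, 1.0):
            raise TreeValidationError(
                f"tree is not ultrametric: tip {leaf.name} depth {depth[leaf]} vs {height}"
            )
    chrono = Chronogram(phylo.root)
    for node in chrono.postorder():
        node.age = 0.0 if node.is_leaf else height - depth[node]
    chrono.validate()
    return chrono


def chronogram_to_newick(chrono: Chronogram) -> str:
    for node in chrono.postorder():
        if node.parent is not None:
            node.length = node.parent.age - node.age
    return write_newick(chrono)


# ---------------------------------------------------------------------------
# Consensus and support comparison
# ---------------------------------------------------------------------------


def _clade_frequencies(trees: Sequence[RootedTree]) -> Dict[FrozenSet[str], float]:
    counts: Dict[FrozenSet[str], int] = {}
    for t in trees:
        for clade in set(t.nontrivial_clades()):
            counts[clade] = counts.get(clade, 0) + 1
    n = len(trees)
    return {c: k / n for c, k in counts.items()}


def _check_common_leafset(trees: Sequence[RootedTree]) -> FrozenSet[str]:
    if not trees:
        raise TreeValidationError("need at least one tree")
    taxa = trees[0].taxa
    for i, t in enumerate(trees[1:], start=2):
        if t.taxa != taxa:
            raise TreeValidationError(f"tree {i} has a different leaf set")
    return taxa


def majority_rule_consensus(
    trees: Sequence[RootedTree], min_freq: float = 0.5
) -> Phylogram:
    """Majority-rule consensus of rooted tree samples.

    Returns the tree containing exactly the non-trivial clades whose
    frequency is strictly greater than ``min_freq`` (ties at the threshold
    are excluded), each annotated with its frequency as support.  For
    ``min_freq >= 0.5`` the retained clades are pairwise compatible by
    construction.
    """
    taxa = _check_common_leafset(trees)
    freqs = _clade_frequencies(trees)
    kept = [(c, f) for c, f in freqs.items() if f > min_freq]
    # Insert large clades first; skip any that would conflict (only possible
    # for min_freq < 0.5).
    kept.sort(key=lambda cf: (-len(cf[0]), sorted(cf[0])))

    root = Node()
    root.support = 1.0
    accepted: List[Tuple[FrozenSet[str], float, Node]] = []
    for clade, f in kept:
        host = root
        host_clade = taxa
        compatible = True
        for c2, _, n2 in accepted:
            if clade <= c2 and len(c2) < len(host_clade):
                host, host_clade = n2, c2
            elif clade & c2 and not (clade <= c2 or c2 <= clade):
                compatible = False
                break
        if not compatible:
            continue
        node = Node()
        node.support = f
        host.add_child(node)
        accepted.append((clade, f, node))

    # attach leaves to the smallest accepted clade containing them
    for taxon in sorted(taxa):
        host = root
        host_size = len(taxa)
        for clade, _, node in accepted:
            if taxon in clade and len(clade) < host_size:
                host, host_size = node, len(clade)
        host.add_child(Node(taxon))

    tree = Phylogram(root)
    tree.validate()
    return tree


def max_clade_support_diff(
    sample_a: Sequence[RootedTree], sample_b: Sequence[RootedTree]
) -> float:
    """Maximum absolute clade-frequency difference between two tree samples.

    This is the two-chain convergence heuristic (threshold 0.3 in practice):
    0 means identical clade frequency spectra, 1 means some clade is fixed in
    one sample and absent from the other.
    """
    if not sample_a or not sample_b:
        raise TreeValidationError("both samples must be non-empty")
    taxa = _check_common_leafset(list(sample_a) + list(sample_b))
    del taxa
    fa = _clade_frequencies(sample_a)
    fb = _clade_frequencies(sample_b)
    diffs = [abs(fa.get(c, 0.0) - fb.get(c, 0.0)) for c in set(fa) | set(fb)]
    return max(diffs, default=0.0)


# ---------------------------------------------------------------------------
# Branch-length statistics
# ---------------------------------------------------------------------------


@dataclass
class PathStats:
    """Node-to-tip path-length statistics from a given ancestral node."""

    distances: Dict[str, float]
    median: float = field(init=False)
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        values = np.array(list(self.distances.values()), dtype=float)
        self.median = float(np.median(values))
        self.mean = float(values.mean())
        self.sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0


def node_to_tip_distances(
    tree: Phylogram,
    ancestor_taxa: Iterable[str],
    tips: Iterable[str],
    *,
    mode: str = "path",
) -> PathStats:
    """Sum of branch lengths from the MRCA of ``ancestor_taxa`` to each tip.

    ``mode='path'`` (default) returns root-to-tip path lengths measured from
    the MRCA; ``mode='branch'`` instead collects the individual branch
    lengths of the subtree below the MRCA (one value per branch).  Branches
    above the MRCA are never included.
    """
    tips = list(tips)
    mrca = tree.mrca(ancestor_taxa)
    cm = tree.clade_map()
    descendants = cm[mrca]
    offenders = [t for t in tips if t not in descendants]
    if offenders:
        raise TreeValidationError(
            f"tips not descendants of the requested ancestor: {sorted(offenders)}"
        )
    if mode == "branch":
        wanted = set(tips)
        lengths = {}
        idx = 0
        for node in mrca.postorder():
            if node is mrca:
                continue
            if cm[node] & wanted:
                key = node.name if node.is_leaf else f"branch_{idx}"
                lengths[key] = float(node.length or 0.0)
                idx += 1
        return PathStats(lengths)
    if mode != "path":
        raise ValueError("mode must be 'path' or 'branch'")

    dist: Dict[Node, float] = {mrca: 0.0}
    out: Dict[str, float] = {}
    stack = [mrca]
    while stack:
        node = stack.pop()
        for child in node.children:
            dist[child] = dist[node] + (child.length or 0.0)
            if child.is_leaf:
                if child.name in tips:
                    out[child.name] = dist[child]
            else:
                stack.append(child)
        if node.is_leaf and node.name in tips:
            out[node.name] = dist[node]
    return PathStats(out)
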