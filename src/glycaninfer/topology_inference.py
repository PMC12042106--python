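"""From fragment annotations to residue adjacency and candidate glycan trees.

A glycan is a rooted tree whose root is the reducing-end residue.  A single
glycosidic cleavage splits it into a root-side component (observed as a Y
ion or, for a terminal residue, a neutral loss) and a leaf-side subtree
(observed as a B ion).  Two same-series fragments whose compositions differ
by exactly one residue ``x``, where the smaller fragment is homogeneous in
one chemical class ``c``, imply that ``x`` is bonded to a residue of class
``c``: root-side components are closed under taking parents and subtrees
are closed under taking children, so the extra residue's tree neighbor
within the larger fragment must belong to class ``c``.

Candidate tree enumeration is exhaustive up to label-preserving isomorphism
(canonical form by sorted recursive labeling) and is practical because the
glycans considered here have at most ~8 residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

from .fragment_annotator import FragmentAnnotation
from .glycan_mass import GlycanComposition, ResidueRegistry, default_registry

__all__ = [
    "GlycanTopology",
    "AdjacencyHypothesis",
    "infer_adjacencies",
    "enumerate_topologies",
    "consistent_topologies",
    "TopologySizeError",
]

# Nested-tuple tree form used internally: (code, (child, child, ...)) with
# children sorted, so structural equality is isomorphism equality.
_Tree = Tuple[str, tuple]


class TopologySizeError(ValueError):
    """Raised when a composition is too large for exhaustive enumeration."""


@dataclass(frozen=True)
class GlycanTopology:
    """A rooted residue tree; node 0 is the reducing-end root.

    ``parents[i]`` is the parent index of node ``i`` (`None` for the root).
    """

    nodes: Tuple[str, ...]
    parents: Tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if n == 0:
            raise ValueError("topology must have at least one residue")
        if len(self.parents) != n:
            raise ValueError("nodes and parents must have equal length")
        roots = [i for i, p in enumerate(self.parents) if p is None]
        if roots != [0]:
            raise ValueError("node 0 must be the unique root")
        for i, p in enumerate(self.parents):
            if p is not None and not (0 <= p < n and p != i):
                raise ValueError(f"invalid parent {p} for node {i}")
        # reachability from the root proves connectedness + acyclicity
        seen = {0}
        changed = True
        while changed:
            changed = False
            for i, p in enumerate(self.parents):
                if i not in seen and p in seen:
                    seen.add(i)
                    changed = True
        if len(seen) != n:
            raise ValueError("parent links do not form a single rooted tree")

    @property
    def root(self) -> str:
        return self.nodes[0]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def composition(self) -> GlycanComposition:
        counts: Dict[str, int] = {}
        for code in self.nodes:
            counts[code] = counts.get(code, 0) + 1
        return GlycanComposition(counts)

    def edges(self) -> List[Tuple[int, int]]:
        """(parent, child) index pairs."""
        return [(p, i) for i, p in enumerate(self.parents) if p is not None]

    def children(self, i: int) -> List[int]:
        return [j for j, p in enumerate(self.parents) if p == i]

    def subtree_nodes(self, i: int) -> List[int]:
        out = [i]
        stack = [i]
        while stack:
            v = stack.pop()
            for c in self.children(v):
                out.append(c)
                stack.append(c)
        return out

    def subtree_composition(self, i: int) -> GlycanComposition:
        counts: Dict[str, int] = {}
        for v in self.subtree_nodes(i):
            counts[self.nodes[v]] = counts.get(self.nodes[v], 0) + 1
        return GlycanComposition(counts)

    def _as_tuple_tree(self, i: int = 0) -> _Tree:
        kids = tuple(sorted(self._as_tuple_tree(c) for c in self.children(i)))
        return (self.nodes[i], kids)

    def canonical(self) -> str:
        """Canonical string; equal iff topologies are isomorphic as rooted
        labeled trees."""
        return _tree_to_text(self._as_tuple_tree())

    def isomorphic_to(self, other: "GlycanTopology") -> bool:
        return self.canonical() == other.canonical()

    def to_text(self) -> str:
        """Parenthesized one-line form, e.g. ``HexNAc(HexNAc(QuiS(Hex(...))))``."""
        return self.canonical()

    @classmethod
    def from_text(cls, text: str) -> "GlycanTopology":
        """Parse the parenthesized one-line form."""
        tree, rest = _parse_tree_text(text.strip())
        if rest:
            raise ValueError(f"trailing text after tree: {rest!r}")
        return _tuple_tree_to_topology(tree)

    @classmethod
    def from_edges(
        cls, nodes: Sequence[str], edges: Sequence[Tuple[int, int]]
    ) -> "GlycanTopology":
        parents: List[Optional[int]] = [None] * len(nodes)
        for p, c in edges:
            if parents[c] is not None:
                raise ValueError(f"node {c} has two parents")
            parents[c] = p
        return cls(tuple(nodes), tuple(parents))


def _tree_to_text(t: _Tree) -> str:
    code, kids = t
    if not kids:
        return code
    return code + "(" + ",".join(_tree_to_text(k) for k in kids) + ")"


def _parse_tree_text(text: str) -> Tuple[_Tree, str]:
    i = 0
    while i < len(text) and text[i] not in "(),":
        i += 1
    code, rest = text[:i], text[i:]
    if not code:
        raise ValueError(f"expected residue code at {text[:20]!r}")
    kids: List[_Tree] = []
    if rest.startswith("("):
        rest = rest[1:]
        while True:
            child, rest = _parse_tree_text(rest)
            kids.append(child)
            if rest.startswith(","):
                rest = rest[1:]
                continue
            if rest.startswith(")"):
                rest = rest[1:]
                break
            raise ValueError(f"unbalanced parentheses near {rest[:20]!r}")
    return (code, tuple(sorted(kids))), rest


def _tuple_tree_to_topology(t: _Tree) -> GlycanTopology:
    nodes: List[str] = []
    parents: List[Optional[int]] = []

    def add(node: _Tree, parent: Optional[int]) -> None:
        idx = len(nodes)
        nodes.append(node[0])
        parents.append(parent)
        for child in node[1]:
            add(child, idx)

    add(t, None)
    return GlycanTopology(tuple(nodes), tuple(parents))


@dataclass
class AdjacencyHypothesis:
    """A claim that residues of class ``attached`` are bonded to class
    ``anchor``, with its fragment-pair evidence."""

    attached: str
    anchor: str
    support: List[Tuple[GlycanComposition, GlycanComposition]] = field(
        default_factory=list
    )

    @property
    def support_count(self) -> int:
        return len(self.support)


def _y_equivalent_compositions(
    annotations: Sequence[FragmentAnnotation],
) -> Tuple[List[GlycanComposition], List[GlycanComposition]]:
    """Normalize annotations into root-side (Y-like) and leaf-side (B)
    composition sets.  Neutral losses become the complementary root-side
    composition; the precursor counts as the full root-side fragment."""
    full: Optional[GlycanComposition] = None
    for a in annotations:
        if a.series == "precursor":
            full = a.subcomp
    y_side: List[GlycanComposition] = []
    b_side: List[GlycanComposition] = []
    seen_y, seen_b = set(), set()
    for a in annotations:
        if a.series in ("precursor", "Y"):
            comp = a.subcomp
        elif a.series == "neutral-loss":
            if full is None or not full.contains(a.subcomp):
                continue  # cannot resolve the complement without a precursor
            comp = full.subtract(a.subcomp)
        elif a.series == "B":
            if a.subcomp not in seen_b:
                seen_b.add(a.subcomp)
                b_side.append(a.subcomp)
            continue
        else:
            continue
        if comp and comp not in seen_y:
            seen_y.add(comp)
            y_side.append(comp)
    return y_side, b_side


def _single_class(comp: GlycanComposition, registry: ResidueRegistry) -> Optional[str]:
    classes = {registry.class_of(code) for code in comp.counts}
    return classes.pop() if len(classes) == 1 else None


def infer_adjacencies(
    annotations: Sequence[FragmentAnnotation],
    registry: Optional[ResidueRegistry] = None,
) -> List[AdjacencyHypothesis]:
    """Class-level adjacency hypotheses from same-series fragment pairs.

    For every same-series pair (S1, S2) with S2 = S1 plus exactly one
    residue ``x``, where S1 is homogeneous in class ``c``, emit or
    strengthen the hypothesis "class(x) attached to c".  Sorted by support
    count descending (ties by class names).
    """
    registry = registry or default_registry()
    hypotheses: Dict[Tuple[str, str], AdjacencyHypothesis] = {}
    for group in _y_equivalent_compositions(annotations):
        for s1 in group:
            c = _single_class(s1, registry)
            if c is None:
                continue
            for s2 in group:
                if s2.total != s1.total + 1 or not s2.contains(s1):
                    continue
                diff = s2.subtract(s1)
                (x_code,) = diff.counts
                key = (registry.class_of(x_code), c)
                hyp = hypotheses.setdefault(key, AdjacencyHypothesis(*key))
                hyp.support.append((s1, s2))
    out = sorted(
        hypotheses.values(),
        key=lambda h: (-h.support_count, h.attached, h.anchor),
    )
    return out


# ---------------------------------------------------------------------------
# Exhaustive rooted-tree enumeration over a label multiset
# ---------------------------------------------------------------------------


def _remove_one(labels: Tuple[str, ...], x: str) -> Tuple[str, ...]:
    out = list(labels)
    out.remove(x)
    return tuple(out)


@lru_cache(maxsize=None)
def _all_trees(labels: Tuple[str, ...], max_children: int) -> Tuple[_Tree, ...]:
    """All rooted trees (nested-tuple form, children sorted) whose node
    label multiset equals ``labels``, up to isomorphism."""
    if not labels:
        return ()
    out = set()
    for r in sorted(set(labels)):
        rest = _remove_one(labels, r)
        for forest in _forests(rest, max_children, max_children):
            out.add((r, forest))
    return tuple(sorted(out))


@lru_cache(maxsize=None)
def _forests(
    labels: Tuple[str, ...], max_trees: int, max_children: int
) -> Tuple[tuple, ...]:
    """All unordered forests (sorted tuples of trees) covering ``labels``
    with at most ``max_trees`` trees."""
    if not labels:
        return ((),)
    if max_trees == 0:
        return ()
    out = set()
    first = labels[0]
    rest = labels[1:]
    # The first label goes into one tree; choose that tree's label set as a
    # sub-multiset of the rest, build its trees, recurse on the remainder.
    for part_rest in _sub_multisets(rest):
        part = tuple(sorted((first,) + part_rest))
        remainder = _multiset_difference(rest, part_rest)
        for tree in _all_trees(part, max_children):
            for tail in _forests(remainder, max_trees - 1, max_children):
                out.add(tuple(sorted((tree,) + tail)))
    return tuple(sorted(out))


@lru_cache(maxsize=None)
def _sub_multisets(labels: Tuple[str, ...]) -> Tuple[Tuple[str, ...], ...]:
    if not labels:
        return ((),)
    counts: Dict[str, int] = {}
    for x in labels:
        counts[x] = counts.get(x, 0) + 1
    codes = sorted(counts)

    def rec(i: int) -> Iterator[Tuple[str, ...]]:
        if i == len(codes):
            yield ()
            return
        for tail in rec(i + 1):
            for n in range(counts[codes[i]] + 1):
                yield (codes[i],) * n + tail

    return tuple(sorted(set(tuple(sorted(t)) for t in rec(0))))


def _multiset_difference(a: Tuple[str, ...], b: Tuple[str, ...]) -> Tuple[str, ...]:
    out = list(a)
    for x in b:
        out.remove(x)
    return tuple(sorted(out))


def enumerate_topologies(
    comp: GlycanComposition,
    max_nodes: int = 8,
    max_children: int = 4,
) -> List[GlycanTopology]:
    """Every rooted tree on the composition's residue multiset, up to
    label-preserving isomorphism.  Branching is capped at ``max_children``
    children per node (ring-hydroxyl valence)."""
    if comp.total > max_nodes:
        raise TopologySizeError(
            f"composition has {comp.total} residues (> max_nodes={max_nodes}); "
            "exhaustive enumeration is disabled at this size — raise max_nodes "
            "or work with adjacency constraints only"
        )
    labels = tuple(
        sorted(code for code, n in comp.counts.items() for _ in range(n))
    )
    # max_children is part of the memo key through the cached helpers
    trees = _all_trees(labels, max_children)
    # children caps inside forests: _forests caps forest width at the same
    # max_children used for every node's child list
    return [_tuple_tree_to_topology(t) for t in trees]


def _comp_key(comp: GlycanComposition) -> Tuple[Tuple[str, int], ...]:
    return tuple(sorted(comp.counts.items()))


def _tree_evidence(
    t: _Tree, class_of: Dict[str, str]
) -> Tuple[Dict[str, int], set, set]:
    """Walk a nested-tuple tree once, collecting (full counts, the set of
    subtree composition keys, the set of class-pair edge keys)."""
    subtree_keys: set = set()
    edge_classes: set = set()

    def walk(node: _Tree) -> Dict[str, int]:
        code, kids = node
        counts = {code: 1}
        for child in kids:
            child_counts = walk(child)
            subtree_keys.add(tuple(sorted(child_counts.items())))
            edge_classes.add(frozenset((class_of[code], class_of[child[0]])))
            for k, v in child_counts.items():
                counts[k] = counts.get(k, 0) + v
        return counts

    full = walk(t)
    return full, subtree_keys, edge_classes


def consistent_topologies(
    comp: GlycanComposition,
    hypotheses: Sequence[AdjacencyHypothesis] = (),
    annotations: Sequence[FragmentAnnotation] = (),
    registry: Optional[ResidueRegistry] = None,
    max_nodes: int = 8,
    max_children: int = 4,
) -> List[GlycanTopology]:
    """Rooted trees on ``comp`` consistent with the fragment evidence.

    A tree is retained iff (i) every annotated Y sub-composition is
    realizable as the root-containing component of a single glycosidic cut
    and every annotated B composition as a leaf-side subtree; and (ii) every
    adjacency hypothesis holds as a tree edge between the stated classes.

    Neutral-loss annotations are deliberately *not* treated as cut evidence:
    a precursor-minus-one-residue peak can arise from in-source loss of an
    internal residue, so it constrains composition (and, via adjacency
    inference, class bonding) but not tree shape.
    """
    registry = registry or default_registry()
    if comp.total > max_nodes:
        raise TopologySizeError(
            f"composition has {comp.total} residues (> max_nodes={max_nodes}); "
            "exhaustive enumeration is disabled at this size — raise max_nodes "
            "or work with adjacency constraints only"
        )
    y_evidence = {
        _comp_key(a.subcomp)
        for a in annotations
        if a.series == "Y" and a.subcomp and a.subcomp != comp
    }
    b_evidence = {
        _comp_key(a.subcomp) for a in annotations if a.series == "B" and a.subcomp
    }
    hypothesis_keys = [frozenset((h.attached, h.anchor)) for h in hypotheses]

    labels = tuple(sorted(code for code, n in comp.counts.items() for _ in range(n)))
    class_of = {code: registry.class_of(code) for code in comp.counts}
    full_key = _comp_key(comp)

    kept: List[GlycanTopology] = []
    for t in _all_trees(labels, max_children):
        full, subtree_keys, edge_classes = _tree_evidence(t, class_of)
        # root-side composition of an edge cut = full minus the subtree cut off
        root_keys = {
            tuple(
                sorted(
                    (k, n - dict(sub).get(k, 0))
                    for k, n in full.items()
                    if n - dict(sub).get(k, 0) > 0
                )
            )
            for sub in subtree_keys
        }
        root_keys.add(full_key)
        if not y_evidence <= root_keys:
            continue
        if not b_evidence <= subtree_keys:
            continue
        if any(h not in edge_classes for h in hypothesis_keys):
            continue
        kept.append(_tuple_tree_to_topology(t))
    return kept
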