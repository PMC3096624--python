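"""Ultrametric tree model, newick I/O, branching times and LTT curves.

Trees are rooted, strictly binary, with node heights measured from the
tips (height 0) toward the root, in the units of the input branch
lengths (typically substitutions/site).  Newick parsing/writing is
delegated to :mod:`dendropy`; validation, normalization and de-tying of
node heights are performed here because the downstream likelihood
requires strictly positive inter-event intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

from .errors import UltrametricityError, ValidationError

#: tips are snapped to height 0 when |height| <= TIP_TOLERANCE * root height
TIP_TOLERANCE = 1e-6

#: tied node heights are separated by multiples of DETIE_EPS * root height
DETIE_EPS = 1e-9


@dataclass
class Node:
    """A node of an :class:`UltrametricTree`.

    ``height`` is the distance from the contemporaneous tip level (0)
    to this node.  Tips carry a ``label``; internal nodes have exactly
    two ``children``.
    """

    label: Optional[str] = None
    height: float = 0.0
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None
    #: preorder index, assigned by UltrametricTree
    index: int = -1

    @property
    def is_tip(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            nd = stack.pop()
            yield nd
            # reversed so the first child is visited first
            stack.extend(reversed(nd.children))

    def tips(self) -> list["Node"]:
        return [nd for nd in self.preorder() if nd.is_tip]


class UltrametricTree:
    """Rooted binary ultrametric tree with tip height 0.

    Parameters
    ----------
    root:
        Root node of a fully built :class:`Node` structure whose
        heights are already measured from the tip level.
    normalize:
        Snap tips within tolerance to 0 and de-tie equal internal node
        heights (deterministically, by preorder index).
    """

    def __init__(self, root: Node, normalize: bool = True):
        self.root = root
        self._index_nodes()
        if normalize:
            self._normalize()
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _index_nodes(self) -> None:
        self.nodes: list[Node] = list(self.root.preorder())
        for i, nd in enumerate(self.nodes):
            nd.index = i
        self.tips: list[Node] = [nd for nd in self.nodes if nd.is_tip]
        self.internal_nodes: list[Node] = [nd for nd in self.nodes if not nd.is_tip]

    def _normalize(self) -> None:
        h_root = self.root.height
        if h_root <= 0:
            raise ValidationError("tree has zero depth (root height must be > 0)")
        tol = TIP_TOLERANCE * h_root
        worst = None
        for tip in self.tips:
            if abs(tip.height) > tol:
                if worst is None or abs(tip.height) > abs(worst.height):
                    worst = tip
        if worst is not None:
            raise UltrametricityError(
                f"tree is not ultrametric: tip {worst.label!r} sits at height "
                f"{worst.height:.6g} (tolerance {tol:.3g}, root height {h_root:.6g})"
            )
        for tip in self.tips:
            tip.height = 0.0
        self._detie()

    def _detie(self) -> None:
        eps = DETIE_EPS * self.root.height
        by_height: dict[float, list[Node]] = {}
        for nd in self.internal_nodes:
            by_height.setdefault(nd.height, []).append(nd)
        for h, group in by_height.items():
            if len(group) < 2:
                continue
            group.sort(key=lambda nd: nd.index)
            for i, nd in enumerate(group):
                nd.height = h - i * eps

    def _validate(self) -> None:
        labels = set()
        for tip in self.tips:
            if not tip.label:
                raise ValidationError("unlabeled tip encountered")
            if tip.label in labels:
                raise ValidationError(f"duplicate tip label {tip.label!r}")
            labels.add(tip.label)
        for nd in self.internal_nodes:
            if len(nd.children) != 2:
                raise ValidationError(
                    f"polytomy (or unifurcation) at internal node with "
                    f"{len(nd.children)} children; resolve it explicitly before analysis"
                )
            for ch in nd.children:
                if not nd.height > ch.height:
                    raise ValidationError(
                        f"internal node at height {nd.height:.6g} does not strictly "
                        f"exceed child height {ch.height:.6g} (zero-length branch "
                        f"that could not be de-tied)"
                    )
        if len(self.internal_nodes) != len(self.tips) - 1:
            raise ValidationError(
                f"tree is not binary: {len(self.tips)} tips but "
                f"{len(self.internal_nodes)} internal nodes"
            )

    # -- basic queries --------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def root_height(self) -> float:
        return self.root.height

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips]

    def subtree_tip_labels(self, node: Node) -> list[str]:
        return [t.label for t in node.tips()]

    # -- I/O ------------------------------------------------------------------

    def to_newick(self) -> str:
        """Serialize with branch lengths at 10 significant digits."""
        parts: list[str] = []

        def fmt(nd: Node) -> str:
            if nd.is_tip:
                body = _quote_label(nd.label)
            else:
                body = "(" + ",".join(fmt(ch) for ch in nd.children) + ")"
            if nd.parent is not None:
                body += ":" + format(nd.parent.height - nd.height, ".10g")
            return body

        parts.append(fmt(self.root))
        return "".join(parts) + ";"


_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,'\"=]")


def _quote_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(text: str) -> UltrametricTree:
    """Parse a newick string into a validated :class:`UltrametricTree`.

    Branch lengths are required on all non-root edges; node heights are
    computed as distance to the tip level.  Non-ultrametric trees
    (beyond tolerance), polytomies and duplicate tip labels are
    rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"malformed newick: {exc}") from exc

    droot = dtree.seed_node
    # depth from root, iterative to cope with deep trees
    depth: dict[int, float] = {id(droot): 0.0}
    order = []
    stack = [droot]
    while stack:
        dnd = stack.pop()
        order.append(dnd)
        for ch in dnd.child_nodes():
            if ch.edge.length is None:
                raise ValidationError(
                    "branch lengths are required on all edges "
                    f"(missing above node {ch.taxon.label if ch.taxon else '?'})"
                )
            depth[id(ch)] = depth[id(dnd)] + ch.edge.length
            stack.append(ch)

    tip_depths = [depth[id(d)] for d in order if not d.child_nodes()]
    if len(tip_depths) < 2:
        raise ValidationError("tree must have at least 2 tips")
    h_root = max(tip_depths)

    # convert to Node structure with heights = h_root - depth
    mapping: dict[int, Node] = {}
    for dnd in order:
        label = None
        if not dnd.child_nodes():
            label = dnd.taxon.label if dnd.taxon is not None else dnd.label
        nd = Node(label=label, height=h_root - depth[id(dnd)])
        mapping[id(dnd)] = nd
    for dnd in order:
        nd = mapping[id(dnd)]
        for ch in dnd.child_nodes():
            cnd = mapping[id(ch)]
            cnd.parent = nd
            nd.children.append(cnd)

    return UltrametricTree(mapping[id(droot)])


def read_newick(path) -> UltrametricTree:
    with open(path) as fh:
        return parse_newick(fh.read())


@dataclass(frozen=True)
class BranchingTimes:
    """Internal node heights sorted descending from the root."""

    times: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self):
        return iter(self.times)

    def __getitem__(self, i):
        return self.times[i]


def branching_times(tree: UltrametricTree) -> BranchingTimes:
    """Descending heights of all internal nodes (ties already broken)."""
    return BranchingTimes(tuple(sorted((nd.height for nd in tree.internal_nodes), reverse=True)))


@dataclass(frozen=True)
class LttCurve:
    """Lineage-through-time step function: (event height, count just below)."""

    heights: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.heights) != len(self.counts):
            raise ValidationError("LTT heights and counts differ in length")


def compute_ltt(tree: UltrametricTree) -> LttCurve:
    """Lineage count as a function of height, stepping +1 at each node.

    The first entry is (root height, 2); the last is (shallowest node
    height, n).
    """
    bt = branching_times(tree)
    counts = tuple(range(2, len(bt) + 2))
    return LttCurve(heights=tuple(bt), counts=counts)
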