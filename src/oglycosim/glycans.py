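"""Rooted-tree representation of mucin-type O-glycans.

Structures are read and written in the condensed-IUPAC dialect used in CHO
O-glycomics, e.g. ``NeuAcα2-3Galβ1-3(NeuAcα2-6)GalNAcol``.  The root of every
tree is the reducing-end GalNAc: released-glycan MS profiles report it as the
reduced alditol ``GalNAcol``, while pathway texts write the peptide-linked
``GalNAcα1-``.  Both spellings are accepted on input and denote the same
species; serialization always emits ``GalNAcol``.

A 6-O-sulfate ester (placed on GlcNAc by the sulfotransferase CHST4) is
modelled as a leaf node with residue ``Sulfate`` and written as the branch
token ``6S``, e.g. ``Galβ1-4(6S)GlcNAcβ1-3GalNAcol``.

Canonical form
--------------
Two trees are equal iff their canonical strings are equal.  The canonical
serialization is deterministic and independent of the order in which branches
were attached: at every node the main chain continues through the child with
the deepest subtree (ties broken in favour of backbone sugars over
Fuc/NeuAc/NeuGc/Sulfate decorations, then by lowest attachment position); the
remaining children are parenthesized in ascending attachment position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional

__all__ = [
    "MonosaccharideNode",
    "GlycanTree",
    "GlycanParseError",
    "parse_structure",
    "serialize",
    "charge_count",
    "residue_count",
    "substituent_count",
]

#: residues carrying (or representing) a negative charge in MS profiles
CHARGED_RESIDUES = frozenset({"NeuAc", "NeuGc", "Sulfate"})

#: carbon position on the donor sugar that forms the glycosidic bond
DONOR_POSITION = {
    "GalNAc": 1,
    "GlcNAc": 1,
    "Gal": 1,
    "Fuc": 1,
    "NeuAc": 2,
    "NeuGc": 2,
}

MONOSACCHARIDES = frozenset(DONOR_POSITION)
RESIDUES = MONOSACCHARIDES | {"Sulfate"}

_GREEK = {"a": "α", "b": "β"}

# longest names first so "GalNAc" is not eaten by "Gal"
_TOKEN_RE = re.compile(r"(NeuAc|NeuGc|GalNAc|GlcNAc|Gal|Fuc)([ab])(\d)-(\d)$")

_ROOT_OL = "GalNAcol"
_ROOT_PEPTIDE = "GalNAca1-"


class GlycanParseError(ValueError):
    """Malformed condensed-IUPAC structure string."""

    def __init__(self, message: str, text: str, offset: int):
        super().__init__(f"{message} (at offset {offset} in {text!r})")
        self.text = text
        self.offset = offset


@dataclass
class MonosaccharideNode:
    """One residue of a glycan tree.

    ``children`` is keyed by the carbon position on this residue to which the
    child is attached, so no two children can share an attachment position.
    """

    residue: str
    anomer: Optional[str] = None  # "a" | "b" | None (root, Sulfate)
    parent_position: Optional[int] = None  # None for the root
    children: Dict[int, "MonosaccharideNode"] = field(default_factory=dict)

    @property
    def donor_position(self) -> Optional[int]:
        if self.parent_position is None or self.residue == "Sulfate":
            return None
        return DONOR_POSITION[self.residue]

    def is_terminal(self) -> bool:
        """True if the node carries no monosaccharide child (sulfate ignored)."""
        return all(c.residue == "Sulfate" for c in self.children.values())

    def add_child(self, child: "MonosaccharideNode") -> None:
        pos = child.parent_position
        if pos is None:
            raise ValueError("child node must carry a parent_position")
        if pos in self.children:
            raise ValueError(f"position {pos} on {self.residue} already occupied")
        if self.residue == "Sulfate":
            raise ValueError("Sulfate nodes are leaves")
        self.children[pos] = child

    def copy(self) -> "MonosaccharideNode":
        return MonosaccharideNode(
            self.residue,
            self.anomer,
            self.parent_position,
            {p: c.copy() for p, c in self.children.items()},
        )

    def walk(self) -> Iterator["MonosaccharideNode"]:
        """Pre-order traversal, children in ascending attachment position."""
        yield self
        for pos in sorted(self.children):
            yield from self.children[pos].walk()


class GlycanTree:
    """A rooted O-glycan; identity is the canonical condensed-IUPAC string."""

    __slots__ = ("root", "_canonical")

    def __init__(self, root: MonosaccharideNode):
        if root.residue != "GalNAc":
            raise ValueError("root residue must be GalNAc")
        self.root = root
        self._canonical: Optional[str] = None

    @property
    def canonical_string(self) -> str:
        if self._canonical is None:
            self._canonical = _serialize_node(self.root, is_root=True)
        return self._canonical

    def copy(self) -> "GlycanTree":
        return GlycanTree(self.root.copy())

    def walk(self) -> Iterator[MonosaccharideNode]:
        return self.root.walk()

    def node_at(self, path: tuple) -> MonosaccharideNode:
        """Resolve a path of attachment positions from the root."""
        node = self.root
        for pos in path:
            node = node.children[pos]
        return node

    def __eq__(self, other) -> bool:
        if not isinstance(other, GlycanTree):
            return NotImplemented
        return self.canonical_string == other.canonical_string

    def __hash__(self) -> int:
        return hash(self.canonical_string)

    def __repr__(self) -> str:
        return f"GlycanTree({self.canonical_string!r})"

    def __str__(self) -> str:
        return self.canonical_string


# ---------------------------------------------------------------------------
# parsing


def parse_structure(text: str) -> GlycanTree:
    """Parse a condensed-IUPAC string into a :class:`GlycanTree`.

    Accepts Greek (``α``/``β``) or ASCII (``a``/``b``) anomer letters and
    either root spelling (``GalNAcol`` / ``GalNAcα1-``).
    """
    s = text.strip().replace("α", "a").replace("β", "b")
    if not s:
        raise GlycanParseError("empty structure string", text, 0)
    if s.endswith(_ROOT_OL):
        prefix = s[: -len(_ROOT_OL)]
    elif s.endswith(_ROOT_PEPTIDE):
        prefix = s[: -len(_ROOT_PEPTIDE)]
    else:
        raise GlycanParseError(
            "structure must end in 'GalNAcol' or 'GalNAcα1-'", s, max(0, len(s) - 8)
        )
    root = MonosaccharideNode("GalNAc")
    _attach_children(s, prefix, 0, root)
    return GlycanTree(root)


def _attach_children(full: str, seg: str, start: int, parent: MonosaccharideNode) -> None:
    """Attach the residues encoded in ``seg`` (= full[start:start+len(seg)])."""
    end = len(seg)
    while end > 0:
        if seg[end - 1] == ")":
            depth = 1
            i = end - 2
            while i >= 0:
                if seg[i] == ")":
                    depth += 1
                elif seg[i] == "(":
                    depth -= 1
                    if depth == 0:
                        break
                i -= 1
            if depth != 0:
                raise GlycanParseError("unbalanced parenthesis", full, start + end - 1)
            inner = seg[i + 1 : end - 1]
            child = _parse_chain(full, inner, start + i + 1)
            _attach(full, start + i + 1, parent, child)
            end = i
        elif seg[end - 1] == "(":
            raise GlycanParseError("unbalanced parenthesis", full, start + end - 1)
        else:
            # everything left of the branches is the main chain
            child = _parse_chain(full, seg[:end], start)
            _attach(full, start, parent, child)
            end = 0


def _parse_chain(full: str, seg: str, start: int) -> MonosaccharideNode:
    if not seg:
        raise GlycanParseError("empty branch", full, start)
    if seg == "6S":
        return MonosaccharideNode("Sulfate", anomer=None, parent_position=6)
    m = _TOKEN_RE.search(seg)
    if m is None:
        raise GlycanParseError(f"unrecognized residue token {seg!r}", full, start)
    residue, anomer, donor_pos, parent_pos = (
        m.group(1),
        m.group(2),
        int(m.group(3)),
        int(m.group(4)),
    )
    if donor_pos != DONOR_POSITION[residue]:
        raise GlycanParseError(
            f"{residue} links through carbon {DONOR_POSITION[residue]}, not {donor_pos}",
            full,
            start + m.start(),
        )
    if not 2 <= parent_pos <= 6:
        raise GlycanParseError(
            f"acceptor position {parent_pos} outside 2-6", full, start + m.start()
        )
    node = MonosaccharideNode(residue, anomer, parent_pos)
    _attach_children(full, seg[: m.start()], start, node)
    return node


def _attach(full: str, offset: int, parent: MonosaccharideNode, child: MonosaccharideNode) -> None:
    try:
        parent.add_child(child)
    except ValueError as exc:
        raise GlycanParseError(str(exc), full, offset) from exc


# ---------------------------------------------------------------------------
# serialization

#: residues that decorate rather than continue a chain; never chosen as the
#: main chain when a backbone sugar of equal depth is available
_BRANCH_RESIDUES = frozenset({"Fuc", "NeuAc", "NeuGc", "Sulfate"})


def _depth(node: MonosaccharideNode) -> int:
    return 1 + max((_depth(c) for c in node.children.values()), default=0)


def _token(node: MonosaccharideNode, is_root: bool) -> str:
    if is_root:
        return _ROOT_OL
    if node.residue == "Sulfate":
        return "6S"
    return (
        f"{node.residue}{_GREEK[node.anomer]}"
        f"{DONOR_POSITION[node.residue]}-{node.parent_position}"
    )


def _serialize_node(node: MonosaccharideNode, is_root: bool = False) -> str:
    parts = []
    if node.children:
        kids = sorted(
            node.children.values(),
            key=lambda c: (-_depth(c), c.residue in _BRANCH_RESIDUES, c.parent_position),
        )
        main, rest = kids[0], sorted(kids[1:], key=lambda c: c.parent_position)
        parts.append(_serialize_node(main))
        parts.extend(f"({_serialize_node(b)})" for b in rest)
    parts.append(_token(node, is_root))
    return "".join(parts)


def serialize(tree: GlycanTree) -> str:
    """Canonical condensed-IUPAC string of ``tree`` (root printed ``GalNAcol``)."""
    return tree.canonical_string


# ---------------------------------------------------------------------------
# simple observables


def charge_count(tree: GlycanTree) -> int:
    """Number of negatively charged residues (NeuAc + NeuGc + sulfate)."""
    return sum(1 for n in tree.walk() if n.residue in CHARGED_RESIDUES)


def residue_count(tree: GlycanTree) -> int:
    """Number of monosaccharide nodes (sulfate esters not counted)."""
    return sum(1 for n in tree.walk() if n.residue != "Sulfate")


def substituent_count(tree: GlycanTree) -> int:
    """Number of sulfate substituents."""
    return sum(1 for n in tree.walk() if n.residue == "Sulfate")
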