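"""Glycosyltransferase reaction rules.

A rule couples an enzyme and its nucleotide-sugar donor to an *acceptor
pattern* — a structural predicate on a node of a glycan tree — and an
*attachment action* (residue, anomer, acceptor carbon).  Enzymes that act on
more than one substrate carry several rules distinguished by an ``_a/_b/...``
suffix on the rule id; all suffixed rules of one enzyme share the enzyme's
kinetic donor affinity and its Golgi localization.

The bundled default rule set (``data/rules.json``) covers the mucin-type
pathway of CHO transfection panels: the four cores, chain extension (type 1,
type 2, poly-LacNAc, LacdiNAc), fucosylation, sialylation, alpha-Gal /
alpha-GlcNAc capping and GlcNAc 6-O-sulfation — 20 enzymes, 30 rules, 12 of
which correspond to transfectable enzymes.  Enzyme families catalysing one
reaction (B3GNT, B4GALT, ST3GAL, ST6GALNAC) are collapsed into single model
enzymes.  The rule table is data, not code: corrections are one-line edits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Tuple

from .glycans import GlycanTree, MonosaccharideNode

__all__ = [
    "NodePattern",
    "ChildPattern",
    "ReactionRule",
    "EnzymeRecord",
    "RuleSet",
    "load_ruleset",
    "match_sites",
    "apply_rule",
]

DONORS = frozenset(
    {"UDP_Gal", "UDP_GlcNAc", "UDP_GalNAc", "GDP_Fuc", "CMP_NeuAc", "CMP_NeuGc", "PAP_S"}
)


@dataclass(frozen=True)
class ChildPattern:
    """Requirement on a child attached at a fixed position of the acceptor."""

    position: int
    residue: Optional[str] = None
    anomer: Optional[str] = None
    required_children: Tuple["ChildPattern", ...] = ()
    forbidden_child_positions: Tuple[int, ...] = ()

    def matches(self, node: MonosaccharideNode) -> bool:
        child = node.children.get(self.position)
        if child is None:
            return False
        if self.residue is not None and child.residue != self.residue:
            return False
        if self.anomer is not None and child.anomer != self.anomer:
            return False
        for sub in self.required_children:
            if not sub.matches(child):
                return False
        return not any(p in child.children for p in self.forbidden_child_positions)


@dataclass(frozen=True)
class NodePattern:
    """Predicate on an acceptor node, evaluated in its tree context.

    ``linkage_anomer``/``linkage_position`` constrain the node's own bond to
    its parent (e.g. "a Gal attached β1-4"); ``parent`` constrains the parent
    node itself (used by rules that read the core context of the root).
    """

    residue: str
    is_root: Optional[bool] = None
    terminal: Optional[bool] = None
    linkage_anomer: Optional[str] = None
    linkage_position: Optional[int] = None
    parent_residue: Optional[str] = None
    parent: Optional["NodePattern"] = None
    required_children: Tuple[ChildPattern, ...] = ()
    forbidden_child_positions: Tuple[int, ...] = ()

    def matches(
        self,
        node: MonosaccharideNode,
        parent: Optional[MonosaccharideNode],
        grandparent: Optional[MonosaccharideNode] = None,
    ) -> bool:
        if node.residue != self.residue:
            return False
        if self.is_root is not None and (parent is None) != self.is_root:
            return False
        if self.terminal is not None and node.is_terminal() != self.terminal:
            return False
        if self.linkage_anomer is not None and node.anomer != self.linkage_anomer:
            return False
        if self.linkage_position is not None and node.parent_position != self.linkage_position:
            return False
        if self.parent_residue is not None and (
            parent is None or parent.residue != self.parent_residue
        ):
            return False
        if self.parent is not None:
            # one level of parent context; a parent pattern may itself not
            # nest another parent pattern
            if parent is None or not self.parent.matches(parent, grandparent):
                return False
        for sub in self.required_children:
            if not sub.matches(node):
                return False
        return not any(p in node.children for p in self.forbidden_child_positions)


@dataclass(frozen=True)
class Attachment:
    residue: str
    anomer: Optional[str]  # None for Sulfate
    position: int


@dataclass(frozen=True)
class ReactionRule:
    rule_id: str
    enzyme: str
    donor: str
    attach: Attachment
    pattern: NodePattern

    def __post_init__(self):
        if self.donor not in DONORS:
            raise ValueError(f"unknown donor {self.donor!r} in rule {self.rule_id}")


@dataclass(frozen=True)
class EnzymeRecord:
    abbreviation: str
    name: str
    ec: str
    transfected: bool


@dataclass
class RuleSet:
    rules: Dict[str, ReactionRule]
    enzymes: Dict[str, EnzymeRecord]
    aliases: Dict[str, str] = field(default_factory=dict)

    def rule(self, rule_id: str) -> ReactionRule:
        return self.rules[rule_id]

    def rules_of(self, enzyme: str) -> List[ReactionRule]:
        return [r for r in self.rules.values() if r.enzyme == enzyme]

    def resolve_enzyme(self, name: str) -> str:
        """Map a transfection-table spelling to the model enzyme abbreviation."""
        key = name.strip().upper()
        key = self.aliases.get(key, key)
        if key not in self.enzymes:
            raise KeyError(f"unknown enzyme {name!r}")
        return key


# ---------------------------------------------------------------------------
# loading


def _parse_child_pattern(obj: dict) -> ChildPattern:
    return ChildPattern(
        position=obj["position"],
        residue=obj.get("residue"),
        anomer=obj.get("anomer"),
        required_children=tuple(
            _parse_child_pattern(c) for c in obj.get("required_children", [])
        ),
        forbidden_child_positions=tuple(obj.get("forbidden_child_positions", [])),
    )


def _parse_pattern(obj: dict) -> NodePattern:
    return NodePattern(
        residue=obj["residue"],
        is_root=obj.get("is_root"),
        terminal=obj.get("terminal"),
        linkage_anomer=obj.get("linkage_anomer"),
        linkage_position=obj.get("linkage_position"),
        parent_residue=obj.get("parent_residue"),
        parent=_parse_pattern(obj["parent"]) if obj.get("parent") else None,
        required_children=tuple(
            _parse_child_pattern(c) for c in obj.get("required_children", [])
        ),
        forbidden_child_positions=tuple(obj.get("forbidden_child_positions", [])),
    )


def load_ruleset(path: Optional[str] = None) -> RuleSet:
    """Load a rule file (default: the bundled 20-enzyme / 30-rule set)."""
    if path is None:
        text = resources.files("oglycosim.data").joinpath("rules.json").read_text("utf-8")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    doc = json.loads(text)
    enzymes = {
        e["abbreviation"]: EnzymeRecord(
            e["abbreviation"], e.get("name", ""), e.get("ec", ""), bool(e["transfected"])
        )
        for e in doc["enzymes"]
    }
    rules: Dict[str, ReactionRule] = {}
    for r in doc["rules"]:
        if r["rule_id"] in rules:
            raise ValueError(f"duplicate rule_id {r['rule_id']}")
        if r["enzyme"] not in enzymes:
            raise ValueError(f"rule {r['rule_id']} references unknown enzyme {r['enzyme']}")
        rules[r["rule_id"]] = ReactionRule(
            rule_id=r["rule_id"],
            enzyme=r["enzyme"],
            donor=r["donor"],
            attach=Attachment(
                r["attach"]["residue"], r["attach"].get("anomer"), r["attach"]["position"]
            ),
            pattern=_parse_pattern(r["pattern"]),
        )
    return RuleSet(rules=rules, enzymes=enzymes, aliases=dict(doc.get("aliases", {})))


# ---------------------------------------------------------------------------
# rule application


def match_sites(rule: ReactionRule, tree: GlycanTree) -> List[tuple]:
    """All acceptor sites of ``rule`` on ``tree``.

    A site is returned as a path of attachment positions from the root (the
    empty tuple is the root itself).  Sites are listed in pre-order, so the
    result is deterministic.  A node only matches if, additionally, the
    attachment position of the rule is unoccupied.
    """
    sites: List[tuple] = []

    def visit(node, parent, grandparent, path: tuple):
        if rule.attach.position not in node.children and rule.pattern.matches(
            node, parent, grandparent
        ):
            sites.append(path)
        for pos in sorted(node.children):
            visit(node.children[pos], node, parent, path + (pos,))

    visit(tree.root, None, None, ())
    return sites


def apply_rule(rule: ReactionRule, tree: GlycanTree, site: tuple) -> GlycanTree:
    """Return a new tree with the rule's residue attached at ``site``.

    ``site`` must come from :func:`match_sites`; the input tree is unmodified.
    """
    if site not in match_sites(rule, tree):
        raise ValueError(f"site {site} does not match rule {rule.rule_id}")
    new = tree.copy()
    node = new.node_at(site)
    node.add_child(
        MonosaccharideNode(
            rule.attach.residue, rule.attach.anomer, rule.attach.position
        )
    )
    return GlycanTree(new.root)
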