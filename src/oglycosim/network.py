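"""Per-experiment reaction network generation.

Starting from the Tn antigen (``GalNAcol``), the closure under a set of
active reaction rules is enumerated breadth-first: every active rule is
applied at every matching site of every species, products are canonicalized
and de-duplicated, and species that have reached ``max_residues``
monosaccharides are not expanded further.  Because rule application is a pure
function of the substrate, the closure is independent of expansion order.

The residue cutoff exists because poly-LacNAc elongation rules make the
closure infinite; the default of 10 residues covers every structure observed
in the CHO transfection panel with headroom.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx
import pandas as pd

from .glycans import GlycanTree, parse_structure, residue_count
from .rules import ReactionRule, RuleSet, apply_rule, match_sites

__all__ = ["Reaction", "ReactionNetwork", "build_network", "reachability_report"]

ROOT_STRUCTURE = "GalNAcol"

DEFAULT_MAX_RESIDUES = 10


@dataclass(frozen=True)
class Reaction:
    substrate: str
    product: str
    rule_id: str


@dataclass
class ReactionNetwork:
    """Species/reaction graph closed under a set of active rules."""

    species: Dict[str, GlycanTree]
    reactions: List[Reaction]
    root_species: str
    active_rule_ids: Tuple[str, ...]
    max_residues: int

    @property
    def n_species(self) -> int:
        return len(self.species)

    def rules_used(self) -> Tuple[str, ...]:
        return tuple(sorted({r.rule_id for r in self.reactions}))

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.species)
        for r in self.reactions:
            g.add_edge(r.substrate, r.product, rule_id=r.rule_id)
        return g

    def to_frame(self) -> pd.DataFrame:
        """Edge list as a tidy frame (substrate, product, rule_id)."""
        return pd.DataFrame(
            [(r.substrate, r.product, r.rule_id) for r in self.reactions],
            columns=["substrate", "product", "rule_id"],
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def build_network(
    ruleset: RuleSet,
    active_rule_ids: Iterable[str],
    max_residues: int = DEFAULT_MAX_RESIDUES,
) -> ReactionNetwork:
    """Breadth-first closure of the active rules from the Tn antigen.

    An empty active set yields the one-species network of the root alone.
    """
    active = sorted(set(active_rule_ids))
    unknown = [rid for rid in active if rid not in ruleset.rules]
    if unknown:
        raise KeyError(f"unknown rule ids: {unknown}")
    if max_residues < 1:
        raise ValueError("max_residues must be >= 1")

    rules: List[ReactionRule] = [ruleset.rules[rid] for rid in active]
    root = parse_structure(ROOT_STRUCTURE)
    species: Dict[str, GlycanTree] = {root.canonical_string: root}
    reactions: List[Reaction] = []
    seen_reactions = set()
    queue = deque([root.canonical_string])

    while queue:
        name = queue.popleft()
        tree = species[name]
        if residue_count(tree) >= max_residues:
            continue  # grown out: do not expand further
        for rule in rules:
            for site in match_sites(rule, tree):
                product = apply_rule(rule, tree, site)
                pname = product.canonical_string
                key = (name, pname, rule.rule_id)
                if key not in seen_reactions:
                    seen_reactions.add(key)
                    reactions.append(Reaction(name, pname, rule.rule_id))
                if pname not in species:
                    species[pname] = product
                    queue.append(pname)

    return ReactionNetwork(
        species=species,
        reactions=reactions,
        root_species=root.canonical_string,
        active_rule_ids=tuple(active),
        max_residues=max_residues,
    )


@dataclass
class ReachabilityEntry:
    structure: str
    reachable: bool
    path: Optional[List[str]] = None  # rule ids of one shortest synthesis route

    @property
    def n_steps(self) -> Optional[int]:
        return None if self.path is None else len(self.path)


def reachability_report(
    network: ReactionNetwork, observed: Iterable[GlycanTree | str]
) -> Dict[str, ReachabilityEntry]:
    """For each observed structure: is it a species, and one shortest route.

    Structures may be given as trees or condensed-IUPAC strings; keys of the
    returned mapping are canonical strings.
    """
    # breadth-first search over reactions from the root
    preds: Dict[str, Tuple[str, str]] = {}  # product -> (substrate, rule_id)
    dist = {network.root_species: 0}
    adj: Dict[str, List[Reaction]] = {}
    for r in network.reactions:
        adj.setdefault(r.substrate, []).append(r)
    queue = deque([network.root_species])
    while queue:
        name = queue.popleft()
        for r in adj.get(name, []):
            if r.product not in dist:
                dist[r.product] = dist[name] + 1
                preds[r.product] = (name, r.rule_id)
                queue.append(r.product)

    report: Dict[str, ReachabilityEntry] = {}
    for obs in observed:
        tree = parse_structure(obs) if isinstance(obs, str) else obs
        name = tree.canonical_string
        if name not in dist:
            report[name] = ReachabilityEntry(name, False, None)
            continue
        path: List[str] = []
        cur = name
        while cur != network.root_species:
            cur, rid = preds[cur]
            path.append(rid)
        report[name] = ReachabilityEntry(name, True, list(reversed(path)))
    return report
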