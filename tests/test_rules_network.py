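"""Rule matching/application and reaction-network generation."""

import random

import pytest

from oglycosim import (
    apply_rule,
    build_network,
    match_sites,
    parse_structure,
    reachability_report,
    residue_count,
    substituent_count,
)
from oglycosim.experiments import load_experiments

from conftest import CHO_WT_RULES

CHO_WT_OBSERVED = [
    "Galβ1-3(NeuAcα2-6)GalNAcol",
    "NeuAcα2-3Galβ1-3GalNAcol",
    "NeuAcα2-3Galβ1-3(NeuAcα2-6)GalNAcol",
]


class TestInventory:
    def test_bundled_counts(self, ruleset):
        assert len(ruleset.enzymes) == 20
        assert len(ruleset.rules) == 30
        assert sum(e.transfected for e in ruleset.enzymes.values()) == 12

    def test_suffixed_rules_share_their_enzyme(self, ruleset):
        for rid, rule in ruleset.rules.items():
            base = rid.rsplit("_", 1)[0] if rid[-2:] in ("_a", "_b", "_c", "_d") else rid
            assert rule.enzyme == base

    def test_multi_substrate_enzymes(self, ruleset):
        multi = {
            e
            for e in ruleset.enzymes
            if len([r for r in ruleset.rules.values() if r.enzyme == e]) > 1
        }
        assert multi == {"B3GNT", "B3GNT3", "CHST4", "GCNT1", "ST3GAL", "ST6GALNAC"}


class TestMatching:
    def test_core1_enzyme_matches_bare_root(self, ruleset):
        rule = ruleset.rules["C1GALT1"]
        assert match_sites(rule, parse_structure("GalNAcol")) == [()]

    def test_occupied_position_blocks(self, ruleset):
        rule = ruleset.rules["C1GALT1"]
        assert match_sites(rule, parse_structure("Galβ1-3GalNAcol")) == []

    def test_core3_enzyme_competes_for_the_same_site(self, ruleset):
        # B3GNT6 acts on the same acceptor position of the Tn antigen
        assert match_sites(ruleset.rules["B3GNT6"], parse_structure("GalNAcol")) == [()]

    def test_sialyl_lewis_x_fucosylation_requires_sialylated_lacnac(self, ruleset):
        fut7 = ruleset.rules["FUT7"]
        sialylated = parse_structure("NeuAcα2-3Galβ1-4GlcNAcβ1-3GalNAcol")
        neutral = parse_structure("Galβ1-4GlcNAcβ1-3GalNAcol")
        assert len(match_sites(fut7, sialylated)) == 1
        assert match_sites(fut7, neutral) == []


class TestApplication:
    @pytest.mark.parametrize(
        "rule_id, substrate, product",
        [
            ("C1GALT1", "GalNAcol", "Galβ1-3GalNAcol"),
            ("GCNT1_a", "Galβ1-3GalNAcol", "Galβ1-3(GlcNAcβ1-6)GalNAcol"),
            ("ST6GALNAC_b", "Galβ1-3GalNAcol", "Galβ1-3(NeuAcα2-6)GalNAcol"),
            ("B3GNT6", "GalNAcol", "GlcNAcβ1-3GalNAcol"),
        ],
    )
    def test_products(self, ruleset, rule_id, substrate, product):
        rule = ruleset.rules[rule_id]
        tree = parse_structure(substrate)
        sites = match_sites(rule, tree)
        assert sites
        assert apply_rule(rule, tree, sites[0]).canonical_string == product

    def test_substrate_not_modified(self, ruleset):
        rule = ruleset.rules["C1GALT1"]
        tree = parse_structure("GalNAcol")
        apply_rule(rule, tree, ())
        assert tree.canonical_string == "GalNAcol"

    def test_nonmatching_site_rejected(self, ruleset):
        rule = ruleset.rules["C1GALT1"]
        with pytest.raises(ValueError):
            apply_rule(rule, parse_structure("Galβ1-3GalNAcol"), ())


class TestNetwork:
    def test_empty_active_set_gives_root_only(self, ruleset):
        net = build_network(ruleset, [])
        assert set(net.species) == {"GalNAcol"}
        assert net.reactions == []

    def test_single_rule_closure(self, ruleset):
        net = build_network(ruleset, ["C1GALT1"])
        assert set(net.species) == {"GalNAcol", "Galβ1-3GalNAcol"}
        assert len(net.reactions) == 1

    def test_cho_wt_contains_the_observed_structures(self, cho_wt_network):
        for s in CHO_WT_OBSERVED:
            assert s in cho_wt_network.species

    def test_every_reaction_adds_one_unit(self, ruleset, cho_wt_network):
        nets = [cho_wt_network, build_network(ruleset, ["B3GNT6", "B4GALT", "CHST4_b"])]
        for net in nets:
            for r in net.reactions:
                sub, prod = net.species[r.substrate], net.species[r.product]
                grew = residue_count(prod) - residue_count(sub)
                sulfated = substituent_count(prod) - substituent_count(sub)
                assert (grew, sulfated) in {(1, 0), (0, 1)}

    def test_residue_cutoff_bounds_growth(self, ruleset):
        # poly-LacNAc loop is infinite without the cutoff
        net = build_network(ruleset, ["B3GNT6", "B4GALT", "B3GNT_a"], max_residues=6)
        assert all(residue_count(t) <= 6 for t in net.species.values())
        bigger = build_network(ruleset, ["B3GNT6", "B4GALT", "B3GNT_a"], max_residues=8)
        assert bigger.n_species > net.n_species

    def test_closure_independent_of_application_order(self, ruleset):
        """Shuffled rule application reaches exactly the same species set."""
        active = [ruleset.rules[r] for r in CHO_WT_RULES]
        reference = set(build_network(ruleset, CHO_WT_RULES).species)
        rng = random.Random(7)
        for _ in range(5):
            species = {parse_structure("GalNAcol").canonical_string}
            trees = {"GalNAcol": parse_structure("GalNAcol")}
            frontier = ["GalNAcol"]
            while frontier:
                rng.shuffle(frontier)
                name = frontier.pop()
                rules = active[:]
                rng.shuffle(rules)
                for rule in rules:
                    tree = trees[name]
                    sites = match_sites(rule, tree)
                    rng.shuffle(sites)
                    for site in sites:
                        prod = apply_rule(rule, tree, site)
                        if prod.canonical_string not in species:
                            species.add(prod.canonical_string)
                            trees[prod.canonical_string] = prod
                            frontier.append(prod.canonical_string)
            assert species == reference


class TestReachability:
    def test_cho_wt_profile_fully_reachable(self, cho_wt_network):
        report = reachability_report(cho_wt_network, CHO_WT_OBSERVED)
        assert all(e.reachable for e in report.values())

    def test_core2_unreachable_without_branching_enzyme(self, cho_wt_network):
        report = reachability_report(cho_wt_network, ["Galβ1-3(GlcNAcβ1-6)GalNAcol"])
        (entry,) = report.values()
        assert not entry.reachable and entry.path is None

    def test_shortest_path_length(self, cho_wt_network):
        report = reachability_report(
            cho_wt_network, ["NeuAcα2-3Galβ1-3(NeuAcα2-6)GalNAcol"]
        )
        (entry,) = report.values()
        assert entry.n_steps == 3

    def test_every_bundled_fixture_reachable_in_its_network(self, ruleset):
        for cfg in load_experiments(ruleset=ruleset):
            net = cfg.build_network(ruleset)
            report = reachability_report(net, cfg.observed_profile().structures())
            unreachable = [k for k, v in report.items() if not v.reachable]
            assert not unreachable, (cfg.name, unreachable)


def test_network_exports(tmp_path, cho_wt_network):
    csv = tmp_path / "net.csv"
    gml = tmp_path / "net.graphml"
    cho_wt_network.write_csv(csv)
    cho_wt_network.write_graphml(gml)
    frame = __import__("pandas").read_csv(csv)
    assert set(frame.columns) == {"substrate", "product", "rule_id"}
    assert len(frame) == len(cho_wt_network.reactions)
    g = __import__("networkx").read_graphml(gml)
    assert g.number_of_nodes() == cho_wt_network.n_species
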