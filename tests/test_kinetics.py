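"""Rate law, ODE assembly, transport schedule and conservation."""

import numpy as np
import pytest
from scipy.special import lambertw

from oglycosim import (
    GolgiLayout,
    KineticParams,
    assemble_system,
    build_network,
    reaction_rate,
    simulate,
    total_glycan,
)
from oglycosim.kinetics import COMPARTMENTS
from oglycosim.synthetic import _draw_params

ROOT = "GalNAcol"
CORE1 = "Galβ1-3GalNAcol"


@pytest.fixture(scope="module")
def core1_model(ruleset, layout):
    net = build_network(ruleset, ["C1GALT1"])
    params = KineticParams.uniform(net, ruleset, layout, kf=100.0, km=1e3, kmd=10.0, enzyme_uM=5.0)
    return net, params, assemble_system(net, params, layout, ruleset)


class TestRateLaw:
    def test_zero_substrate_zero_rate(self, core1_model):
        net, params, model = core1_model
        v = reaction_rate(model, "C1GALT1", ROOT, 0, {ROOT: 0.0}, params)
        assert v == 0.0

    def test_absent_enzyme_zero_rate(self, core1_model):
        # C1GALT1 is localized in cis only; in the trans compartment its
        # concentration is zero and the rule carries no flux
        net, params, model = core1_model
        assert params.enzyme_uM["C1GALT1"][2] == 0.0
        v = reaction_rate(model, "C1GALT1", ROOT, 2, {ROOT: 500.0}, params)
        assert v == 0.0

    def test_saturating_donor_recovers_michaelis_menten(self, ruleset, layout):
        net = build_network(ruleset, ["C1GALT1"])
        km = 1e3
        kmd = layout.donors["UDP_Gal"][0] / 1e3  # donor >= 1000 * Kmd
        params = KineticParams.uniform(
            net, ruleset, layout, kf=50.0, km=km, kmd=kmd, enzyme_uM=2.0
        )
        model = assemble_system(net, params, layout, ruleset)
        v = reaction_rate(model, "C1GALT1", ROOT, 0, {ROOT: km}, params)
        # at S = Km the classical MM rate is Kf*E/2
        assert v == pytest.approx(50.0 * 2.0 / 2.0, rel=0.01)

    def test_donor_monotonicity(self, ruleset):
        net = build_network(ruleset, ["C1GALT1"])
        rates = []
        for donor in [0.0, 10.0, 100.0, 1e3, 1e5]:
            lay = GolgiLayout.default()
            lay.donors = dict(lay.donors)
            lay.donors["UDP_Gal"] = (donor, 0, 3810, 3810)
            params = KineticParams.uniform(net, ruleset, lay, kf=10, km=100, kmd=50, enzyme_uM=1)
            model = assemble_system(net, params, lay, ruleset)
            rates.append(reaction_rate(model, "C1GALT1", ROOT, 0, {ROOT: 200.0}, params))
        assert rates == sorted(rates)
        assert rates[0] == 0.0 and rates[-1] > 0.0

    def test_negative_concentration_rejected(self, core1_model):
        net, params, model = core1_model
        with pytest.raises(ValueError):
            reaction_rate(model, "C1GALT1", ROOT, 0, {ROOT: -1.0}, params)


class TestAssembly:
    def test_empty_network_zero_rhs(self, ruleset, layout):
        net = build_network(ruleset, [])
        params = KineticParams.uniform(net, ruleset, layout)
        model = assemble_system(net, params, layout, ruleset)
        for c in range(4):
            assert np.allclose(model.rhs(c, params)(0.0, np.array([123.0])), 0.0)

    def test_one_to_one_stoichiometry_sums_to_zero(self, ruleset, layout, cho_wt_network):
        params = KineticParams.uniform(cho_wt_network, ruleset, layout, kf=30, km=500, kmd=20, enzyme_uM=3)
        model = assemble_system(cho_wt_network, params, layout, ruleset)
        rng = np.random.default_rng(0)
        S = rng.uniform(0, 1e4, model.n_species)
        for c in range(4):
            assert abs(model.rhs(c, params)(0.0, S).sum()) < 1e-9 * S.sum()

    def test_competition_splits_root_consumption(self, ruleset, layout):
        # C1GALT1 and B3GNT6 compete for the root in cis
        net = build_network(ruleset, ["C1GALT1", "B3GNT6"])
        params = KineticParams.uniform(net, ruleset, layout, kf=10, km=100, kmd=10, enzyme_uM=1)
        model = assemble_system(net, params, layout, ruleset)
        S = np.zeros(model.n_species)
        S[model.index[ROOT]] = 250.0
        rates = model.instantaneous_rates(0, S, params)
        v1 = rates[("C1GALT1", ROOT)]
        v3 = rates[("B3GNT6", ROOT)]
        dS = model.rhs(0, params)(0.0, S)
        assert dS[model.index[ROOT]] == pytest.approx(-(v1 + v3), rel=1e-12)
        # hand-computed single-substrate rate for each enzyme
        for v, donor, kmd in [(v1, layout.donors["UDP_Gal"][0], 10.0),
                              (v3, layout.donors["UDP_GlcNAc"][0], 10.0)]:
            expected = 10 * 1 * (donor / (kmd + donor)) * (250 / 100) / (1 + 250 / 100)
            assert v == pytest.approx(expected, rel=1e-12)

    def test_analytic_jacobian_matches_finite_differences(self, ruleset, layout, cho_wt_network):
        params = KineticParams.uniform(cho_wt_network, ruleset, layout, kf=30, km=500, kmd=20, enzyme_uM=3)
        model = assemble_system(cho_wt_network, params, layout, ruleset)
        rng = np.random.default_rng(1)
        S = rng.uniform(1.0, 1e4, model.n_species)
        for c in (0, 2):
            f = model.rhs(c, params)
            J = model.jac(c, params)(0.0, S)
            eps = 1e-4
            for j in range(model.n_species):
                dS = np.zeros_like(S)
                dS[j] = eps * max(1.0, S[j])
                fd = (f(0.0, S + dS) - f(0.0, S - dS)) / (2 * dS[j])
                assert np.allclose(J[:, j], fd, rtol=1e-5, atol=1e-8)


class TestSimulate:
    def test_horizon_is_four_residence_times(self, layout):
        assert layout.horizon_min == pytest.approx(22.24)
        assert len(COMPARTMENTS) == 4

    def test_no_enzymes_leaves_everything_as_root(self, ruleset, layout):
        net = build_network(ruleset, [])
        params = KineticParams.uniform(net, ruleset, layout)
        result = simulate(net, params, layout=layout, ruleset=ruleset)
        assert result.tgn_profile == {ROOT: 100.0}
        assert result.times[-1] == pytest.approx(22.24)

    def test_initial_amount_and_conservation(self, ruleset, layout, cho_wt_network):
        params = KineticParams.uniform(cho_wt_network, ruleset, layout, kf=1e4, km=1e3, kmd=100, enzyme_uM=10)
        result = simulate(cho_wt_network, params, layout=layout, ruleset=ruleset)
        start = total_glycan(result, 0.0)
        # 100 umol/uL x 2.5 uL in the cis compartment
        assert start == pytest.approx(100.0 * 2.5, rel=1e-12)
        for t in [3.0, 11.1, 22.24]:
            assert total_glycan(result, t) == pytest.approx(start, rel=1e-6)
        # after the final transfer everything resides in the TGN
        final = result.final_state()
        assert final[:3].sum() == 0.0
        assert final[3].sum() > 0.0

    def test_conservation_and_positivity_over_random_draws(self, ruleset, layout, cho_wt_network):
        from oglycosim.kinetics import SimulationError

        rng = np.random.default_rng(42)
        checked = 0
        attempts = 0
        while checked < 8 and attempts < 40:
            attempts += 1
            params = _draw_params(rng, [cho_wt_network], ruleset, layout)
            try:
                result = simulate(cho_wt_network, params, layout=layout, ruleset=ruleset)
            except SimulationError:
                continue
            start = total_glycan(result, 0.0)
            for t in np.linspace(0, 22.24, 9):
                assert total_glycan(result, t) == pytest.approx(start, rel=1e-6)
            assert result.concentrations.min() >= -1e-9 * layout.initial_root_uM
            checked += 1
        assert checked == 8

    def test_closed_form_batch_oracle(self, ruleset, layout):
        """Single-rule model vs the analytic irreversible-MM solution."""
        net = build_network(ruleset, ["C1GALT1"])
        km = 5e7
        kmd = 1e-3  # saturating donor in cis (3810 uM >> Kmd)
        kf, e_conc = 9e3, 1e3
        params = KineticParams.uniform(net, ruleset, layout, kf=kf, km=km, kmd=kmd, enzyme_uM=e_conc)
        result = simulate(net, params, layout=layout, ruleset=ruleset, rtol=1e-10)
        s0 = layout.initial_root_uM
        d = layout.donors["UDP_Gal"][0]
        vmax = kf * e_conc * d / (kmd + d)
        tau = layout.residence_min  # conversion happens in cis only
        s_exact = km * np.real(lambertw((s0 / km) * np.exp((s0 - vmax * tau) / km)))
        expected_root = 100.0 * s_exact / s0
        assert result.tgn_profile[ROOT] == pytest.approx(expected_root, abs=0.1)
        assert result.tgn_profile[CORE1] == pytest.approx(100 - expected_root, abs=0.1)

    def test_cstr_mode_conserves_and_differs(self, ruleset, layout, cho_wt_network):
        params = KineticParams.uniform(cho_wt_network, ruleset, layout, kf=1e4, km=1e3, kmd=100, enzyme_uM=10)
        batch = simulate(cho_wt_network, params, layout=layout, ruleset=ruleset)
        cstr = simulate(cho_wt_network, params, layout=layout, ruleset=ruleset, mode="cstr")
        assert cstr.mode == "cstr"
        assert total_glycan(cstr, 22.24) == pytest.approx(250.0, rel=1e-6)
        assert batch.tgn_profile != cstr.tgn_profile

    def test_profile_sums_to_100(self, ruleset, layout, cho_wt_network):
        params = KineticParams.uniform(cho_wt_network, ruleset, layout, kf=100, km=1e4, kmd=10, enzyme_uM=1)
        result = simulate(cho_wt_network, params, layout=layout, ruleset=ruleset)
        assert sum(result.tgn_profile.values()) == pytest.approx(100.0, abs=1e-9)


class TestValidation:
    def test_localization_mask_enforced(self, ruleset, layout, cho_wt_network):
        params = KineticParams.uniform(cho_wt_network, ruleset, layout)
        bad = dict(params.enzyme_uM)
        bad["C1GALT1"] = (1.0, 1.0, 0.0, 0.0)  # medial not allowed
        params.enzyme_uM = bad
        with pytest.raises(ValueError):
            assemble_system(cho_wt_network, params, layout, ruleset)

    def test_missing_rule_parameters_detected(self, ruleset, layout, cho_wt_network):
        params = KineticParams.uniform(cho_wt_network, ruleset, layout)
        del params.kf["C1GALT1"]
        with pytest.raises(ValueError):
            assemble_system(cho_wt_network, params, layout, ruleset)
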