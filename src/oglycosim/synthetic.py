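"""Synthetic observed profiles with known ground truth.

The measured glycan abundances of the CHO transfection panel are published
only as figures, so end-to-end testing of the estimation pipeline needs
profiles whose generating parameters are known.  A scenario draws a "true"
kinetic parameter set log-uniformly inside the search bounds, simulates the
experiment's network through the Golgi model, optionally perturbs the TGN
percentages with additive truncated-Gaussian noise, renormalizes and
packages the result in the same profile format the experiment bundle uses.

Draws for which the simulation is uninformative (the root retains more than
99% of the material) are rejected and redrawn, up to a fixed number of
attempts.  Scenario generation is a pure function of (experiment, seed,
noise level).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .estimation import BOUNDS, FitExperiment
from .experiments import ExperimentConfig, GlycanProfile, ProfileEntry, load_experiments
from .kinetics import GolgiLayout, KineticParams, SimulationError, simulate
from .network import ReactionNetwork
from .rules import RuleSet, load_ruleset

__all__ = ["SyntheticScenario", "generate_scenario", "four_experiment_suite"]

#: the four lines with small enough profiles for joint estimation
FOUR_EXPERIMENT_NAMES = (
    "CHO/CHO-WT",
    "Slex on C3",
    "Slex on exC1",
    "A4GlcNAc on C1",
)

_MAX_ROOT_PERCENT = 99.0
_MAX_ATTEMPTS = 500


@dataclass
class SyntheticScenario:
    experiment: str
    seed: int
    sigma_noise: float
    true_params: KineticParams
    profile: GlycanProfile
    network: ReactionNetwork
    layout: GolgiLayout

    def observed_dict(self) -> Dict[str, float]:
        return self.profile.as_dict()

    def as_fit_experiment(self) -> FitExperiment:
        return FitExperiment(
            name=self.experiment,
            network=self.network,
            observed=self.observed_dict(),
            layout=self.layout,
        )


def _draw_params(
    rng: np.random.Generator,
    networks: Sequence[ReactionNetwork],
    ruleset: RuleSet,
    layout: GolgiLayout,
) -> KineticParams:
    lo, hi = np.log10(BOUNDS[0]), np.log10(BOUNDS[1])
    rule_ids = sorted({r for net in networks for r in net.active_rule_ids})
    enzymes = sorted({ruleset.rules[r].enzyme for r in rule_ids})

    def draw() -> float:
        return float(10.0 ** rng.uniform(lo, hi))

    return KineticParams(
        kf={r: draw() for r in rule_ids},
        km={r: draw() for r in rule_ids},
        kmd={e: draw() for e in enzymes},
        enzyme_uM={
            e: tuple(draw() if L else 0.0 for L in layout.localization[e]) for e in enzymes
        },
    )


def _profile_with_noise(
    tgn: Dict[str, float], rng: np.random.Generator, sigma_noise: float
) -> Dict[str, float]:
    values = {s: p for s, p in tgn.items() if p > 0}
    if sigma_noise > 0:
        values = {s: max(0.0, p + rng.normal(0.0, sigma_noise)) for s, p in values.items()}
        values = {s: p for s, p in values.items() if p > 0}
    total = sum(values.values())
    return {s: 100.0 * p / total for s, p in values.items()}


def _config(experiment: str) -> ExperimentConfig:
    for cfg in load_experiments():
        if cfg.name == experiment or cfg.slug == experiment:
            return cfg
    raise KeyError(f"unknown experiment {experiment!r}")


def generate_scenario(
    experiment: str,
    seed: int,
    sigma_noise: float = 0.0,
    ruleset: Optional[RuleSet] = None,
    layout: Optional[GolgiLayout] = None,
    max_residues: int = 10,
) -> SyntheticScenario:
    """Draw a ground-truth parameter set and emulate the observed TGN profile."""
    ruleset = ruleset or load_ruleset()
    layout = layout or GolgiLayout.default()
    cfg = _config(experiment)
    network = cfg.build_network(ruleset, max_residues=max_residues)
    rng = np.random.default_rng([seed, _scenario_salt(cfg.slug)])
    for _ in range(_MAX_ATTEMPTS):
        params = _draw_params(rng, [network], ruleset, layout)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # solver chatter on rejected draws
                result = simulate(network, params, layout=layout, ruleset=ruleset, rtol=1e-8)
        except SimulationError:
            continue  # pathological draw; reject like an uninformative one
        if result.tgn_profile.get(network.root_species, 0.0) <= _MAX_ROOT_PERCENT:
            values = _profile_with_noise(result.tgn_profile, rng, sigma_noise)
            profile = GlycanProfile(
                entries=[
                    ProfileEntry(structure=s, value=v) for s, v in sorted(values.items())
                ],
                kind="adjusted",
                name=f"synthetic:{cfg.slug}",
                synthetic=True,
            )
            return SyntheticScenario(
                experiment=cfg.name,
                seed=seed,
                sigma_noise=sigma_noise,
                true_params=params,
                profile=profile,
                network=network,
                layout=layout,
            )
    raise RuntimeError(
        f"could not draw an informative scenario for {experiment!r} "
        f"in {_MAX_ATTEMPTS} attempts"
    )


def _scenario_salt(slug: str) -> int:
    # stable small integer per experiment so scenarios are independent
    return sum(ord(ch) for ch in slug) % 9973


def four_experiment_suite(
    seed: int,
    sigma_noise: float = 0.0,
    ruleset: Optional[RuleSet] = None,
    layout: Optional[GolgiLayout] = None,
) -> List[SyntheticScenario]:
    """Scenarios for the four jointly modelled lines, sharing one true vector."""
    ruleset = ruleset or load_ruleset()
    layout = layout or GolgiLayout.default()
    configs = [_config(name) for name in FOUR_EXPERIMENT_NAMES]
    networks = [cfg.build_network(ruleset) for cfg in configs]
    rng = np.random.default_rng([seed, 4])
    for _ in range(_MAX_ATTEMPTS):
        params = _draw_params(rng, networks, ruleset, layout)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = [
                    simulate(net, params, layout=layout, ruleset=ruleset, rtol=1e-8)
                    for net in networks
                ]
        except SimulationError:
            continue
        if all(
            r.tgn_profile.get(net.root_species, 0.0) <= _MAX_ROOT_PERCENT
            for r, net in zip(results, networks)
        ):
            scenarios = []
            for cfg, net, res in zip(configs, networks, results):
                values = _profile_with_noise(res.tgn_profile, rng, sigma_noise)
                profile = GlycanProfile(
                    entries=[
                        ProfileEntry(structure=s, value=v)
                        for s, v in sorted(values.items())
                    ],
                    kind="adjusted",
                    name=f"synthetic:{cfg.slug}",
                    synthetic=True,
                )
                scenarios.append(
                    SyntheticScenario(
                        experiment=cfg.name,
                        seed=seed,
                        sigma_noise=sigma_noise,
                        true_params=params,
                        profile=profile,
                        network=net,
                        layout=layout,
                    )
                )
            return scenarios
    raise RuntimeError(
        f"could not draw a jointly informative four-experiment suite in "
        f"{_MAX_ATTEMPTS} attempts"
    )
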