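"""Experiment bundle, glycan profiles and the charge-based intensity adjustment.

The bundle describes the 25 CHO transfection experiments: the enzymes
transiently expressed in each line and the reaction rules active in its
model.  Each experiment references a bundled observed-profile fixture.  The
measured abundances of the original study exist only as figures, so the
bundled profiles are synthetic stand-ins (structure lists follow the pathway
of each line; see :mod:`oglycosim.synthetic`): they exercise every code path
without claiming to be the measured data.

Charge adjustment: negatively charged glycans (NeuAc/NeuGc/sulfate) ionize
more efficiently in MS, so raw intensities are down-weighted by 0.3 for
singly and 0.4 for doubly charged structures before renormalization to
100%.  No factor is defined for higher charges; such entries are rejected.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Dict, List, Literal, Optional

from pydantic import BaseModel, Field, field_validator

from .glycans import charge_count, parse_structure
from .network import ReactionNetwork, build_network
from .rules import RuleSet, load_ruleset

__all__ = [
    "ProfileEntry",
    "GlycanProfile",
    "ExperimentConfig",
    "adjust_profile",
    "load_experiments",
    "load_profile",
    "compare_profiles",
    "ProfileComparison",
]

CHARGE_FACTORS = {0: 1.0, 1: 0.3, 2: 0.4}


class ProfileEntry(BaseModel):
    structure: str
    value: float = Field(ge=0)
    charge: Optional[int] = None

    @field_validator("structure")
    @classmethod
    def _canonical(cls, v: str) -> str:
        return parse_structure(v).canonical_string

    def model_post_init(self, __context) -> None:
        computed = charge_count(parse_structure(self.structure))
        if self.charge is None:
            self.charge = computed
        elif self.charge != computed:
            raise ValueError(
                f"declared charge {self.charge} does not match structure "
                f"{self.structure} (charge {computed})"
            )


class GlycanProfile(BaseModel):
    entries: List[ProfileEntry]
    kind: Literal["raw_intensity", "adjusted"]
    name: Optional[str] = None
    synthetic: bool = False

    def model_post_init(self, __context) -> None:
        if self.kind == "adjusted":
            total = sum(e.value for e in self.entries)
            if abs(total - 100.0) > 1e-6:
                raise ValueError(f"adjusted profile sums to {total}, not 100")

    def as_dict(self) -> Dict[str, float]:
        return {e.structure: e.value for e in self.entries}

    def structures(self) -> List[str]:
        return [e.structure for e in self.entries]


def adjust_profile(raw: GlycanProfile) -> GlycanProfile:
    """Apply the 0.3/0.4 charge factors and renormalize to 100%.

    Only ``raw_intensity`` profiles may be adjusted, so double adjustment is
    impossible by construction.
    """
    if raw.kind != "raw_intensity":
        raise ValueError("profile is already adjusted")
    weights = []
    for e in raw.entries:
        if e.charge not in CHARGE_FACTORS:
            raise ValueError(
                f"no adjustment factor defined for charge {e.charge} "
                f"({e.structure}); factors exist for charges 0-2"
            )
        weights.append(e.value * CHARGE_FACTORS[e.charge])
    total = sum(weights)
    if total <= 0:
        raise ValueError("profile has zero total intensity")
    return GlycanProfile(
        entries=[
            ProfileEntry(structure=e.structure, value=100.0 * w / total, charge=e.charge)
            for e, w in zip(raw.entries, weights)
        ],
        kind="adjusted",
        name=raw.name,
        synthetic=raw.synthetic,
    )


class ExperimentConfig(BaseModel):
    name: str
    slug: str
    transfected_enzymes: List[str]
    active_rule_ids: List[str]
    observed_profile_ref: str

    def build_network(self, ruleset: Optional[RuleSet] = None, max_residues: int = 10) -> ReactionNetwork:
        ruleset = ruleset or load_ruleset()
        return build_network(ruleset, self.active_rule_ids, max_residues=max_residues)

    def observed_profile(self) -> GlycanProfile:
        return load_profile(self.observed_profile_ref)


def _bundle_text(name: str) -> str:
    return resources.files("oglycosim.data").joinpath(name).read_text("utf-8")


def load_experiments(
    path: Optional[str] = None, ruleset: Optional[RuleSet] = None
) -> List[ExperimentConfig]:
    """Load and validate the experiment bundle (default: the 25 bundled configs)."""
    if path is None:
        doc = json.loads(_bundle_text("experiments.json"))
    else:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    ruleset = ruleset or load_ruleset()
    configs: List[ExperimentConfig] = []
    for entry in doc["experiments"]:
        transfected = [ruleset.resolve_enzyme(e) for e in entry["transfected"]]
        for enzyme in transfected:
            if not ruleset.enzymes[enzyme].transfected:
                raise ValueError(
                    f"experiment {entry['name']}: enzyme {enzyme} is not "
                    "flagged transfectable in the enzyme table"
                )
        for rid in entry["active_rules"]:
            if rid not in ruleset.rules:
                raise ValueError(f"experiment {entry['name']}: unknown rule {rid}")
        # every transfected enzyme must contribute at least one active rule
        active_enzymes = {ruleset.rules[r].enzyme for r in entry["active_rules"]}
        missing = [e for e in transfected if e not in active_enzymes]
        if missing:
            raise ValueError(
                f"experiment {entry['name']}: transfected enzymes with no active rule: {missing}"
            )
        configs.append(
            ExperimentConfig(
                name=entry["name"],
                slug=entry["slug"],
                transfected_enzymes=transfected,
                active_rule_ids=list(entry["active_rules"]),
                observed_profile_ref=f"profiles/{entry['slug']}.json",
            )
        )
    return configs


def load_profile(ref: str) -> GlycanProfile:
    """Load a profile fixture, either bundled (``profiles/<slug>.json``) or a path."""
    try:
        text = _bundle_text(ref)
    except FileNotFoundError:
        with open(ref, "r", encoding="utf-8") as fh:
            text = fh.read()
    return GlycanProfile.model_validate_json(text)


# ---------------------------------------------------------------------------
# profile comparison


class ProfileComparison(BaseModel):
    rows: List[dict]  # structure, simulated, observed, residual
    sum_squared_residuals: float
    max_abs_residual: float

    def as_dict(self) -> Dict[str, dict]:
        return {r["structure"]: r for r in self.rows}


def compare_profiles(
    simulated: Dict[str, float] | GlycanProfile,
    observed: Dict[str, float] | GlycanProfile,
) -> ProfileComparison:
    """Per-structure residuals over the union of both structure sets.

    Structures absent from one side count as 0%.  Residual = simulated -
    observed, so the comparison is symmetric up to sign.
    """
    sim = simulated.as_dict() if isinstance(simulated, GlycanProfile) else dict(simulated)
    obs = observed.as_dict() if isinstance(observed, GlycanProfile) else dict(observed)
    rows = []
    for s in sorted(set(sim) | set(obs)):
        sv, ov = sim.get(s, 0.0), obs.get(s, 0.0)
        rows.append(
            {"structure": s, "simulated": sv, "observed": ov, "residual": sv - ov}
        )
    ssr = sum(r["residual"] ** 2 for r in rows)
    mx = max((abs(r["residual"]) for r in rows), default=0.0)
    return ProfileComparison(rows=rows, sum_squared_residuals=ssr, max_abs_residual=mx)
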