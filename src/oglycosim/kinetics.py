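"""Four-compartment Golgi kinetic model.

The Golgi is modelled as four equally sized, well-mixed compartments
(cis, medial, trans, TGN).  The glycoprotein pool enters the cis compartment
as the Tn antigen and spends a fixed residence time tau = 5.56 min in each
compartment, so the simulation spans 4*tau = 22.24 min and the glycan
profile is read from the TGN at the end.

Rate law
--------
Each reaction-rule instance r (enzyme e, donor d, acceptor species j) in
compartment c proceeds at the rapid-equilibrium bi-substrate rate with
competition of all acceptors of the same enzyme:

    v = Kf[r] * E[e,c] * (D[d,c]/Kmd[e]) * (S_j/Km[r])
        / ( (1 + D[d,c]/Kmd[e]) * (1 + sum_k S_k/Km[k]) )

where the sum runs over every (species, rule) pair of enzyme e present in
the compartment.  In the saturating-donor, single-substrate limit this
reduces to classical irreversible Michaelis-Menten kinetics.  Donor
concentrations are clamped at their configured per-compartment values (a
donor set to 0 in a compartment silently disables the rule there), and
enzymes are present only where the binary localization matrix says so.

Transport
---------
The default ``batch`` schedule integrates one compartment at a time over its
residence window and then hands the entire glycan content to the next
compartment (plug flow).  A continuous ``cstr`` mode (compartments in series
with first-order transfer at rate 1/tau, terminal accumulation in the TGN)
is provided as an alternative; the mode used is recorded in the result.

Units: concentrations are handled internally in uM.  The initial glycan
concentration is configured on its conventional scale (umol/uL) and converted
once at the boundary with an explicit factor; glycan profiles are relative
(percent), so the absolute scale cancels there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .network import ReactionNetwork
from .rules import RuleSet

__all__ = [
    "GolgiLayout",
    "KineticParams",
    "GolgiModel",
    "SimulationResult",
    "reaction_rate",
    "assemble_system",
    "simulate",
    "total_glycan",
]

COMPARTMENTS = ("cis", "medial", "trans", "tgn")

#: concentrations below this (uM) are reported as 0% to suppress solver noise
PROFILE_FLOOR_UM = 1e-12


def _load_json(name: str) -> dict:
    return json.loads(resources.files("oglycosim.data").joinpath(name).read_text("utf-8"))


@dataclass
class GolgiLayout:
    """Geometry, donors and enzyme localization of the Golgi model."""

    donors: Dict[str, Tuple[float, float, float, float]]
    localization: Dict[str, Tuple[int, int, int, int]]
    residence_min: float = 5.56
    volume_uL: float = 2.5
    initial_root_umol_per_uL: float = 100.0
    #: 1 umol/uL = 1 mol/L = 1e6 uM
    uM_per_umol_per_uL: float = 1.0e6

    @property
    def compartments(self) -> Tuple[str, ...]:
        return COMPARTMENTS

    @property
    def n_compartments(self) -> int:
        return len(COMPARTMENTS)

    @property
    def horizon_min(self) -> float:
        """End of the simulation: one residence time per compartment."""
        return self.n_compartments * self.residence_min

    @property
    def initial_root_uM(self) -> float:
        return self.initial_root_umol_per_uL * self.uM_per_umol_per_uL

    @classmethod
    def default(cls) -> "GolgiLayout":
        donors_doc = _load_json("donors.json")
        loc_doc = _load_json("localization.json")
        assert tuple(donors_doc["compartments"]) == COMPARTMENTS
        assert tuple(loc_doc["compartments"]) == COMPARTMENTS
        return cls(
            donors={k: tuple(v) for k, v in donors_doc["donors"].items()},
            localization={k: tuple(v) for k, v in loc_doc["localization"].items()},
        )


@dataclass
class KineticParams:
    """Per-rule turnover/affinity and per-enzyme donor affinity & abundance.

    ``kf``: turnover constants (1/min) keyed by rule id; ``km``: acceptor
    half-saturation (uM) keyed by rule id; ``kmd``: donor half-saturation
    (uM) keyed by enzyme; ``enzyme_uM``: enzyme concentration per compartment
    keyed by enzyme, zero wherever the localization matrix is zero.
    """

    kf: Dict[str, float] = field(default_factory=dict)
    km: Dict[str, float] = field(default_factory=dict)
    kmd: Dict[str, float] = field(default_factory=dict)
    enzyme_uM: Dict[str, Tuple[float, float, float, float]] = field(default_factory=dict)

    def validate(self, layout: GolgiLayout) -> None:
        for key, v in self.kf.items():
            if v < 0:
                raise ValueError(f"negative kf for {key}")
        for d in (self.km, self.kmd):
            for key, v in d.items():
                if v <= 0:
                    raise ValueError(f"half-saturation constant for {key} must be > 0")
        for enzyme, conc in self.enzyme_uM.items():
            loc = layout.localization.get(enzyme)
            for c, value in enumerate(conc):
                if value < 0:
                    raise ValueError(f"negative enzyme concentration for {enzyme}")
                if loc is not None and loc[c] == 0 and value != 0:
                    raise ValueError(
                        f"{enzyme} has nonzero concentration in"
                        f" {COMPARTMENTS[c]} where it is not localized"
                    )

    @classmethod
    def uniform(
        cls,
        network: ReactionNetwork,
        ruleset: RuleSet,
        layout: GolgiLayout,
        kf: float = 1.0,
        km: float = 1.0,
        kmd: float = 1.0,
        enzyme_uM: float = 1.0,
    ) -> "KineticParams":
        """Identical values for every rule/enzyme (localization-masked)."""
        rule_ids = network.active_rule_ids
        enzymes = sorted({ruleset.rules[r].enzyme for r in rule_ids})
        return cls(
            kf={r: kf for r in rule_ids},
            km={r: km for r in rule_ids},
            kmd={e: kmd for e in enzymes},
            enzyme_uM={
                e: tuple(enzyme_uM * L for L in layout.localization[e]) for e in enzymes
            },
        )


# ---------------------------------------------------------------------------
# compiled ODE system


@dataclass
class _CompartmentSystem:
    # one reaction instance per (reaction, compartment) with E and D support
    sub: np.ndarray  # substrate index per instance
    prod: np.ndarray  # product index per instance
    enz: np.ndarray  # enzyme-group index per instance
    rule_ids: List[str]
    enzymes: List[str]  # enzyme-group order
    donor_uM: np.ndarray  # donor concentration per instance

    def coefficients(self, params: KineticParams, c: int) -> Tuple[np.ndarray, np.ndarray]:
        """(kf*E*Dterm per instance, 1/Km per instance) for compartment ``c``."""
        kf = np.array([params.kf[r] for r in self.rule_ids])
        km = np.array([params.km[r] for r in self.rule_ids])
        kmd = np.array([params.kmd[e] for e in self.enzymes])
        e_conc = np.array([params.enzyme_uM[e][c] for e in self.enzymes])
        with np.errstate(divide="ignore", invalid="ignore"):
            dterm = np.where(
                self.donor_uM > 0,
                self.donor_uM / (kmd[self.enz] + self.donor_uM),
                0.0,
            )
            inv_km = np.where(km > 0, 1.0 / km, np.inf)
        return kf * e_conc[self.enz] * dterm, inv_km


class GolgiModel:
    """Reaction network + rate law + layout compiled into per-compartment ODEs."""

    def __init__(
        self,
        network: ReactionNetwork,
        ruleset: RuleSet,
        layout: Optional[GolgiLayout] = None,
    ):
        self.network = network
        self.ruleset = ruleset
        self.layout = layout or GolgiLayout.default()
        self.species: List[str] = sorted(network.species)
        self.index = {s: i for i, s in enumerate(self.species)}
        self.root_index = self.index[network.root_species]
        self._systems: List[_CompartmentSystem] = []
        for c in range(self.layout.n_compartments):
            self._systems.append(self._compile_compartment(c))

    def _compile_compartment(self, c: int) -> _CompartmentSystem:
        sub, prod, enz, rule_ids, donors = [], [], [], [], []
        enzymes: List[str] = []
        enzyme_pos: Dict[str, int] = {}
        for r in self.network.reactions:
            rule = self.ruleset.rules[r.rule_id]
            loc = self.layout.localization.get(rule.enzyme)
            if loc is None:
                raise ValueError(f"no localization for enzyme {rule.enzyme}")
            if loc[c] == 0:
                continue
            d = self.layout.donors.get(rule.donor)
            if d is None:
                raise ValueError(f"no donor table entry for {rule.donor}")
            if d[c] <= 0:
                continue  # donor not supplied here: rule silently inactive
            if rule.enzyme not in enzyme_pos:
                enzyme_pos[rule.enzyme] = len(enzymes)
                enzymes.append(rule.enzyme)
            sub.append(self.index[r.substrate])
            prod.append(self.index[r.product])
            enz.append(enzyme_pos[rule.enzyme])
            rule_ids.append(r.rule_id)
            donors.append(d[c])
        return _CompartmentSystem(
            sub=np.asarray(sub, dtype=np.intp),
            prod=np.asarray(prod, dtype=np.intp),
            enz=np.asarray(enz, dtype=np.intp),
            rule_ids=rule_ids,
            enzymes=enzymes,
            donor_uM=np.asarray(donors, dtype=float),
        )

    @property
    def n_species(self) -> int:
        return len(self.species)

    def rhs(self, compartment: int, params: KineticParams):
        """Right-hand side ``f(t, S)`` of compartment ``compartment`` (uM/min)."""
        sys = self._systems[compartment]
        n = self.n_species
        if sys.sub.size == 0:
            return lambda t, S: np.zeros(n)
        coef, inv_km = sys.coefficients(params, compartment)
        n_enz = len(sys.enzymes)
        sub, prod, enz = sys.sub, sys.prod, sys.enz

        def f(t, S):
            u = np.maximum(S[sub], 0.0) * inv_km
            den = 1.0 + np.bincount(enz, weights=u, minlength=n_enz)
            v = coef * u / den[enz]
            return np.bincount(prod, weights=v, minlength=n) - np.bincount(
                sub, weights=v, minlength=n
            )

        return f

    def jac(self, compartment: int, params: KineticParams):
        """Analytic Jacobian of :meth:`rhs` (exact; keeps LSODA stable)."""
        sys = self._systems[compartment]
        n = self.n_species
        if sys.sub.size == 0:
            return lambda t, S: np.zeros((n, n))
        coef, inv_km = sys.coefficients(params, compartment)
        n_enz = len(sys.enzymes)
        sub, prod, enz = sys.sub, sys.prod, sys.enz

        def jac_fn(t, S):
            active = (S[sub] > 0.0).astype(float)
            u = np.maximum(S[sub], 0.0) * inv_km
            den = 1.0 + np.bincount(enz, weights=u, minlength=n_enz)
            # d(den_e)/dS_j summed over the enzyme's instances
            row = np.zeros((n_enz, n))
            np.add.at(row, (enz, sub), inv_km * active)
            dv = -((coef * u / den[enz] ** 2)[:, None]) * row[enz]
            dv[np.arange(sub.size), sub] += coef * inv_km * active / den[enz]
            J = np.zeros((n, n))
            np.add.at(J, prod, dv)
            np.subtract.at(J, sub, dv)
            return J

        return jac_fn

    def instantaneous_rates(
        self, compartment: int, S: np.ndarray, params: KineticParams
    ) -> Dict[Tuple[str, str], float]:
        """Rates of every instance at state ``S``: {(rule_id, substrate): uM/min}."""
        sys = self._systems[compartment]
        out: Dict[Tuple[str, str], float] = {}
        if sys.sub.size == 0:
            return out
        coef, inv_km = sys.coefficients(params, compartment)
        u = np.maximum(S[sys.sub], 0.0) * inv_km
        den = 1.0 + np.bincount(sys.enz, weights=u, minlength=len(sys.enzymes))
        v = coef * u / den[sys.enz]
        for i, rid in enumerate(sys.rule_ids):
            out[(rid, self.species[sys.sub[i]])] = float(v[i])
        return out


def assemble_system(
    network: ReactionNetwork,
    params: KineticParams,
    layout: Optional[GolgiLayout] = None,
    ruleset: Optional[RuleSet] = None,
) -> GolgiModel:
    """Build the compiled ODE system (validates parameters against layout)."""
    from .rules import load_ruleset

    ruleset = ruleset or load_ruleset()
    model = GolgiModel(network, ruleset, layout)
    params.validate(model.layout)
    missing = [
        r.rule_id
        for r in (ruleset.rules[rid] for rid in network.rules_used())
        if r.rule_id not in params.kf or r.rule_id not in params.km
    ]
    if missing:
        raise ValueError(f"missing kinetic parameters for rules: {missing}")
    return model


def reaction_rate(
    model: GolgiModel,
    rule_id: str,
    substrate: str,
    compartment: int,
    concentrations: Dict[str, float],
    params: KineticParams,
) -> float:
    """Instantaneous rate (uM/min) of one rule instance in one compartment.

    ``concentrations`` maps species strings to uM; species omitted are 0.
    Competing substrates of the same enzyme enter the denominator.
    """
    if any(v < 0 for v in concentrations.values()):
        raise ValueError("negative concentration")
    S = np.zeros(model.n_species)
    for name, v in concentrations.items():
        S[model.index[name]] = v
    rates = model.instantaneous_rates(compartment, S, params)
    return rates.get((rule_id, substrate), 0.0)


# ---------------------------------------------------------------------------
# simulation


@dataclass
class SimulationResult:
    species: List[str]
    times: np.ndarray  # global time grid (min)
    concentrations: np.ndarray  # (n_compartments, n_species, n_times), uM
    tgn_profile: Dict[str, float]  # percent at the horizon
    mode: str
    layout: GolgiLayout

    def final_state(self) -> np.ndarray:
        return self.concentrations[:, :, -1]

    def profile_at_end(self) -> Dict[str, float]:
        return dict(self.tgn_profile)


class _BudgetExceeded(Exception):
    pass


def _budgeted(f, budget: int):
    """Wrap an ODE callback with a hard evaluation budget.

    Well-behaved integrations use a few hundred evaluations; a budget in the
    tens of thousands only trips on pathologically stiff parameter draws,
    turning a potentially unbounded solve into a clean failure.
    """
    count = [0]

    def g(t, y):
        count[0] += 1
        if count[0] > budget:
            raise _BudgetExceeded()
        return f(t, y)

    return g


class SimulationError(RuntimeError):
    def __init__(self, message: str, compartment: Optional[str] = None, time: Optional[float] = None):
        super().__init__(message)
        self.compartment = compartment
        self.time = time


def _profile_from_state(species: Sequence[str], y: np.ndarray) -> Dict[str, float]:
    y = np.where(y < PROFILE_FLOOR_UM, 0.0, y)
    total = y.sum()
    if total <= 0:
        return {s: 0.0 for s in species}
    return {s: 100.0 * y[i] / total for i, s in enumerate(species)}


def simulate(
    network: ReactionNetwork,
    params: KineticParams,
    layout: Optional[GolgiLayout] = None,
    ruleset: Optional[RuleSet] = None,
    mode: str = "batch",
    rtol: float = 1e-8,
    points_per_compartment: int = 25,
    max_rhs_evals: int = 50_000,
) -> SimulationResult:
    """Integrate the model over the full Golgi transit and read the TGN profile.

    ``mode='batch'`` (default): sequential plug-flow — each compartment is
    integrated alone over its residence window and its whole content is then
    transferred to the next.  ``mode='cstr'``: continuous stirred tanks in
    series with transfer rate 1/tau and terminal accumulation in the TGN.
    """
    model = assemble_system(network, params, layout, ruleset)
    lay = model.layout
    n, nc = model.n_species, lay.n_compartments
    tau = lay.residence_min
    s0 = lay.initial_root_uM
    atol = s0 * 1e-14

    # a floor on the internal step aborts (rather than grinds through)
    # pathologically stiff corners of the parameter space; such draws are
    # reported as SimulationError and rejected by the callers that search
    min_step = tau * 1e-13

    if mode == "batch":
        times: List[np.ndarray] = []
        conc = []
        y = np.zeros(n)
        y[model.root_index] = s0
        for c in range(nc):
            t0, t1 = c * tau, (c + 1) * tau
            grid = np.linspace(t0, t1, points_per_compartment)
            try:
                sol = solve_ivp(
                    _budgeted(model.rhs(c, params), max_rhs_evals),
                    (t0, t1),
                    y,
                    method="LSODA",
                    rtol=rtol,
                    atol=atol,
                    t_eval=grid,
                    jac=model.jac(c, params),
                    min_step=min_step,
                )
            except _BudgetExceeded:
                raise SimulationError(
                    f"integration exceeded {max_rhs_evals} evaluations",
                    compartment=lay.compartments[c],
                    time=t0,
                ) from None
            if not sol.success:
                raise SimulationError(
                    f"integration failed: {sol.message}",
                    compartment=lay.compartments[c],
                    time=float(sol.t[-1]) if len(sol.t) else t0,
                )
            seg = np.zeros((nc, n, grid.size))
            seg[c] = sol.y
            times.append(grid)
            conc.append(seg)
            y = sol.y[:, -1].copy()  # transfer everything to the next compartment
        all_t = np.concatenate(times)
        all_c = np.concatenate(conc, axis=2)
        profile = _profile_from_state(model.species, y)
    elif mode == "cstr":
        y = np.zeros(nc * n)
        y[model.root_index] = s0
        rhs_c = [model.rhs(c, params) for c in range(nc)]
        jac_c = [model.jac(c, params) for c in range(nc)]

        def f(t, Y):
            Y = Y.reshape(nc, n)
            dY = np.empty_like(Y)
            for c in range(nc):
                dY[c] = rhs_c[c](t, Y[c])
            # first-order transfer down the stack; the TGN accumulates
            for c in range(nc - 1):
                flux = Y[c] / tau
                dY[c] -= flux
                dY[c + 1] += flux
            return dY.ravel()

        eye = np.eye(n) / tau

        def jac(t, Y):
            Y = Y.reshape(nc, n)
            J = np.zeros((nc * n, nc * n))
            for c in range(nc):
                J[c * n : (c + 1) * n, c * n : (c + 1) * n] = jac_c[c](t, Y[c])
            for c in range(nc - 1):
                J[c * n : (c + 1) * n, c * n : (c + 1) * n] -= eye
                J[(c + 1) * n : (c + 2) * n, c * n : (c + 1) * n] += eye
            return J

        grid = np.linspace(0.0, lay.horizon_min, points_per_compartment * nc)
        try:
            sol = solve_ivp(
                _budgeted(f, 4 * max_rhs_evals),
                (0.0, lay.horizon_min),
                y,
                method="LSODA",
                rtol=rtol,
                atol=atol,
                t_eval=grid,
                jac=jac,
                min_step=min_step,
            )
        except _BudgetExceeded:
            raise SimulationError(
                f"integration exceeded {4 * max_rhs_evals} evaluations"
            ) from None
        if not sol.success:
            raise SimulationError(f"integration failed: {sol.message}", time=float(sol.t[-1]))
        all_t = grid
        all_c = sol.y.reshape(nc, n, grid.size)
        profile = _profile_from_state(model.species, all_c[-1, :, -1])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return SimulationResult(
        species=model.species,
        times=all_t,
        concentrations=all_c,
        tgn_profile=profile,
        mode=mode,
        layout=lay,
    )


def total_glycan(result: SimulationResult, time: float) -> float:
    """Total glycan amount (umol) across all compartments at ``time``.

    Constant over the whole simulation to within integrator tolerance: every
    reaction converts one acceptor into one product and transfer is lossless.
    """
    t = result.times
    if not (t[0] <= time <= t[-1]):
        raise ValueError(f"time {time} outside simulated horizon [{t[0]}, {t[-1]}]")
    i = int(np.searchsorted(t, time, side="left"))
    i = min(i, t.size - 1)
    conc_sum = result.concentrations[:, :, i].sum()  # uM summed over compartments
    umol_per_uL = conc_sum / result.layout.uM_per_umol_per_uL
    return umol_per_uL * result.layout.volume_uL
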