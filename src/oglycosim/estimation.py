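"""Evolution-strategy estimation of the kinetic parameters.

The free parameters — per-rule turnover ``Kf`` and acceptor affinity ``Km``,
per-enzyme donor affinity ``Kmd`` and per-compartment enzyme concentrations —
are searched inside the box [1e-6, 1e5] on a log10 scale (kinetic constants
are scale parameters and the box spans eleven decades).  Candidates are
scored by the weighted sum of squared differences between the simulated and
observed TGN profiles (relative abundances, percent); the weight of an
experiment is derived from the standard deviation of its observed values,
mirroring the standard-deviation weighting of common parameter-estimation
tools.  Several experiments can be fitted jointly with one shared parameter
vector; an enzyme absent from an experiment simply has no reactions in that
experiment's network, so its concentration cannot leak into the fit.

The optimizer is a (mu, lambda) evolution strategy with stochastic ranking,
log-uniform initialization, self-adaptive per-coordinate step sizes and
reflection repair at the bounds.  With box constraints handled by repair the
candidates are always feasible, so the stochastic ranking reduces to an
objective sort; the ranking machinery is kept for fidelity to the method.
Runs are deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .kinetics import GolgiLayout, KineticParams, SimulationError, simulate
from .network import ReactionNetwork
from .rules import RuleSet, load_ruleset

__all__ = [
    "BOUNDS",
    "FitExperiment",
    "FitProblem",
    "FitResult",
    "objective",
    "sres_fit",
    "joint_fit",
]

BOUNDS = (1e-6, 1e5)

_FAILURE_SENTINEL = float("inf")


@dataclass
class FitExperiment:
    """One experiment inside a fit: a network plus its observed TGN profile."""

    name: str
    network: ReactionNetwork
    observed: Dict[str, float]  # structure -> percent
    layout: Optional[GolgiLayout] = None
    mode: str = "batch"

    def __post_init__(self):
        if not self.observed:
            raise ValueError(f"experiment {self.name}: no observed structures")
        missing = [s for s in self.observed if s not in self.network.species]
        if missing:
            raise ValueError(
                f"experiment {self.name}: observed structures not in network: {missing}"
            )


@dataclass
class FreeParameter:
    kind: str  # "kf" | "km" | "kmd" | "enzyme"
    key: str  # rule id or enzyme
    compartment: Optional[int] = None  # for kind == "enzyme"

    @property
    def name(self) -> str:
        if self.kind == "enzyme":
            from .kinetics import COMPARTMENTS

            return f"E[{self.key},{COMPARTMENTS[self.compartment]}]"
        return f"{self.kind.capitalize()}[{self.key}]"


class FitProblem:
    """Experiments + shared free-parameter vector + weighting."""

    def __init__(
        self,
        experiments: Sequence[FitExperiment],
        ruleset: Optional[RuleSet] = None,
        free_parameters: Optional[Sequence[FreeParameter]] = None,
        bounds: Tuple[float, float] = BOUNDS,
        weight_mode: str = "sd",
        rtol: float = 1e-7,
    ):
        if not experiments:
            raise ValueError("at least one experiment required")
        self.ruleset = ruleset or load_ruleset()
        self.experiments = list(experiments)
        self.bounds = bounds
        self.weight_mode = weight_mode
        self.rtol = rtol
        self._rule_ids = sorted({r for e in self.experiments for r in e.network.rules_used()})
        self._enzymes = sorted({self.ruleset.rules[r].enzyme for r in self._rule_ids})
        self._layouts = [e.layout or GolgiLayout.default() for e in self.experiments]
        self.free_parameters = (
            list(free_parameters) if free_parameters is not None else self._default_free()
        )
        self.weights = [self._weight(e.observed) for e in self.experiments]

    # -- construction -----------------------------------------------------

    def _default_free(self) -> List[FreeParameter]:
        free: List[FreeParameter] = []
        for r in self._rule_ids:
            free.append(FreeParameter("kf", r))
        for r in self._rule_ids:
            free.append(FreeParameter("km", r))
        for e in self._enzymes:
            free.append(FreeParameter("kmd", e))
        # one concentration per compartment in which the enzyme occurs in
        # any of the experiments' layouts
        for e in self._enzymes:
            loc = None
            for lay in self._layouts:
                l = lay.localization.get(e)
                if l is not None:
                    loc = l if loc is None else tuple(max(a, b) for a, b in zip(loc, l))
            for c, present in enumerate(loc or ()):
                if present:
                    free.append(FreeParameter("enzyme", e, c))
        return free

    def _weight(self, observed: Dict[str, float]) -> float:
        if self.weight_mode == "none":
            return 1.0
        values = np.array(list(observed.values()), dtype=float)
        sd = float(values.std(ddof=0))
        if sd <= 0:
            return 1.0
        return 1.0 / sd**2

    @property
    def n_parameters(self) -> int:
        return len(self.free_parameters)

    # -- vector <-> KineticParams -----------------------------------------

    def params_from_vector(self, x_log10: np.ndarray) -> KineticParams:
        values = 10.0 ** np.asarray(x_log10, dtype=float)
        params = KineticParams(
            kf={r: 1.0 for r in self._rule_ids},
            km={r: 1.0 for r in self._rule_ids},
            kmd={e: 1.0 for e in self._enzymes},
            enzyme_uM={},
        )
        conc = {e: [0.0, 0.0, 0.0, 0.0] for e in self._enzymes}
        for fp, v in zip(self.free_parameters, values):
            if fp.kind == "kf":
                params.kf[fp.key] = v
            elif fp.kind == "km":
                params.km[fp.key] = v
            elif fp.kind == "kmd":
                params.kmd[fp.key] = v
            elif fp.kind == "enzyme":
                conc[fp.key][fp.compartment] = v
            else:
                raise ValueError(f"unknown parameter kind {fp.kind}")
        params.enzyme_uM = {e: tuple(v) for e, v in conc.items()}
        return params

    # -- objective ---------------------------------------------------------

    def simulate_experiment(self, i: int, params: KineticParams):
        e = self.experiments[i]
        return simulate(
            e.network,
            params,
            layout=self._layouts[i],
            ruleset=self.ruleset,
            mode=e.mode,
            rtol=self.rtol,
            points_per_compartment=2,
        )

    def residuals(self, params: KineticParams) -> List[Dict[str, float]]:
        """Per-experiment {structure: simulated% - observed%}."""
        out = []
        for i, e in enumerate(self.experiments):
            profile = self.simulate_experiment(i, params).tgn_profile
            out.append({s: profile.get(s, 0.0) - obs for s, obs in e.observed.items()})
        return out

    def objective(self, params: KineticParams) -> float:
        import warnings

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # solver chatter on doomed candidates
                total = 0.0
                for w, res in zip(self.weights, self.residuals(params)):
                    total += w * sum(r * r for r in res.values())
            return total
        except SimulationError:
            return _FAILURE_SENTINEL

    def objective_vector(self, x_log10: np.ndarray) -> float:
        return self.objective(self.params_from_vector(x_log10))

    def max_abs_residual(self, params: KineticParams) -> float:
        return max(
            (abs(r) for res in self.residuals(params) for r in res.values()), default=0.0
        )


def objective(problem: FitProblem, params: KineticParams) -> float:
    """Weighted sum of squared profile residuals (simulation failure -> inf)."""
    return problem.objective(params)


# ---------------------------------------------------------------------------
# stochastic-ranking evolution strategy


@dataclass
class FitResult:
    best_parameters: KineticParams
    objective: float
    history: List[float]  # best-so-far objective per generation
    seed: int
    simulated_profiles: List[Dict[str, float]]
    residuals: List[Dict[str, float]]
    free_parameter_names: List[str]
    best_vector_log10: np.ndarray
    weights: List[float] = field(default_factory=list)
    generations_run: int = 0


def _stochastic_rank(f: np.ndarray, g: np.ndarray, rng: np.random.Generator, pf: float = 0.45):
    """Stochastic-ranking bubble sort over objective f and constraint violation g."""
    idx = np.arange(f.size)
    for _ in range(f.size):
        swapped = False
        u = rng.random(f.size - 1)
        for j in range(f.size - 1):
            a, b = idx[j], idx[j + 1]
            if (g[a] == 0 and g[b] == 0) or u[j] < pf:
                swap = f[a] > f[b]
            else:
                swap = g[a] > g[b]
            if swap:
                idx[j], idx[j + 1] = b, a
                swapped = True
        if not swapped:
            break
    return idx


def sres_fit(
    problem: FitProblem,
    population: int = 20,
    generations: int = 500,
    seed: int = 0,
    stop_tol: float = 1e-10,
    patience: int = 50,
    target_max_residual: Optional[float] = None,
) -> FitResult:
    """(mu, lambda) evolution strategy with stochastic ranking.

    Stops early when the best objective has improved by less than
    ``stop_tol`` over ``patience`` generations, or (optionally) when the
    best candidate's largest absolute profile residual falls below
    ``target_max_residual`` percent.
    """
    if population < 10:
        raise ValueError("population must be >= 10")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    n = problem.n_parameters
    lo, hi = (math.log10(problem.bounds[0]), math.log10(problem.bounds[1]))
    rng = np.random.default_rng(seed)
    lam = population
    mu = max(2, lam // 7)
    tau = 1.0 / math.sqrt(2.0 * math.sqrt(n))
    tau_prime = 1.0 / math.sqrt(2.0 * n)
    sigma_max = (hi - lo) / 2.0

    x = rng.uniform(lo, hi, size=(lam, n))  # log-uniform in original scale
    sigma = np.full((lam, n), (hi - lo) / math.sqrt(n))
    f = np.array([problem.objective_vector(xi) for xi in x])

    best_i = int(np.argmin(f))
    best_x, best_f = x[best_i].copy(), float(f[best_i])
    history: List[float] = []
    since_improvement = 0
    gens_run = 0

    for gen in range(generations):
        gens_run = gen + 1
        order = _stochastic_rank(f, np.zeros_like(f), rng)
        parents = order[:mu]
        pick = rng.integers(0, mu, size=lam)
        px, ps = x[parents[pick]], sigma[parents[pick]]
        global_step = rng.normal(size=(lam, 1))
        sigma_new = ps * np.exp(tau_prime * global_step + tau * rng.normal(size=(lam, n)))
        np.clip(sigma_new, 1e-8, sigma_max, out=sigma_new)
        x_new = px + sigma_new * rng.normal(size=(lam, n))
        # reflection repair into the box
        span = hi - lo
        x_new = np.abs((x_new - lo) % (2 * span) - span) * -1 + span + lo  # triangle wave
        x, sigma = x_new, sigma_new
        f = np.array([problem.objective_vector(xi) for xi in x])

        gen_best = int(np.argmin(f))
        improved = float(f[gen_best]) < best_f - stop_tol
        if float(f[gen_best]) < best_f:
            best_f = float(f[gen_best])
            best_x = x[gen_best].copy()
        history.append(best_f)
        since_improvement = 0 if improved else since_improvement + 1
        if since_improvement >= patience:
            break
        if target_max_residual is not None and best_f < _FAILURE_SENTINEL:
            params = problem.params_from_vector(best_x)
            if problem.max_abs_residual(params) < target_max_residual:
                break

    best_params = problem.params_from_vector(best_x)
    profiles = [
        problem.simulate_experiment(i, best_params).tgn_profile
        for i in range(len(problem.experiments))
    ]
    residuals = problem.residuals(best_params)
    return FitResult(
        best_parameters=best_params,
        objective=problem.objective(best_params),
        history=history,
        seed=seed,
        simulated_profiles=profiles,
        residuals=residuals,
        free_parameter_names=[fp.name for fp in problem.free_parameters],
        best_vector_log10=best_x,
        weights=list(problem.weights),
        generations_run=gens_run,
    )


def joint_fit(
    experiments: Sequence[FitExperiment],
    ruleset: Optional[RuleSet] = None,
    population: int = 20,
    generations: int = 500,
    seed: int = 0,
    **kwargs,
) -> FitResult:
    """Fit one shared parameter vector across several experiments.

    Parameters are shared through the rule/enzyme vocabulary; an enzyme that
    does not occur in an experiment's network contributes nothing to that
    experiment's simulation regardless of its candidate value.  The result
    carries per-experiment simulated profiles and residuals at the optimum.
    """
    problem = FitProblem(experiments, ruleset=ruleset)
    return sres_fit(
        problem, population=population, generations=generations, seed=seed, **kwargs
    )
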