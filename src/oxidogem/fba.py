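"""Flux balance analysis: LP phenotype simulation and summaries.

FBA solves ``max/min Z = c'v`` subject to ``S v = 0`` and ``l <= v <= u``.
Growth is simulated by maximizing the biomass pseudoreaction under a
:class:`LimitationScenario` that encodes the medium: the limiting exchange
gets a small uptake bound (default 1 mmol·gDW⁻¹·h⁻¹), non-limiting medium
components are free at -1000, and every exchange may secrete up to +1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import DEFAULT_BOUND, MetabolicModel

__all__ = [
    "ObjectiveSpec",
    "LimitationScenario",
    "FluxDistribution",
    "apply_scenario",
    "optimize",
    "uptake_sweep",
    "pathway_flux_summary",
    "chemostat_simulate",
    "FLUX_EPSILON",
]

#: flux magnitude below which a reaction is considered inactive
FLUX_EPSILON = 1e-6


@dataclass(frozen=True)
class ObjectiveSpec:
    """Sparse objective row vector c' with an optimization sense."""

    coefficients: dict[str, float]
    sense: str = "max"

    def __post_init__(self):
        if not any(v != 0 for v in self.coefficients.values()):
            raise ValueError("objective needs at least one nonzero coefficient")
        if self.sense not in {"max", "min"}:
            raise ValueError(f"unknown sense {self.sense!r}")

    def dense(self, model: MetabolicModel) -> np.ndarray:
        c = np.zeros(model.n_reactions)
        idx = model.reaction_index
        for rxn, coeff in self.coefficients.items():
            if rxn not in idx:
                raise KeyError(f"objective references unknown reaction {rxn!r}")
            c[idx[rxn]] = coeff
        return c


@dataclass(frozen=True)
class LimitationScenario:
    """Nutrient-limitation recipe applied to exchange bounds.

    ``limiting_exchange`` receives lower bound ``-limiting_uptake_bound``;
    the carbon source (when not itself limiting) and every exchange in
    ``free_exchanges`` receive -1000; all exchange upper bounds are +1000 and
    all remaining exchange lower bounds 0 (secretion only).
    """

    carbon_exchange: str
    limiting_exchange: str
    limiting_uptake_bound: float = 1.0
    free_exchanges: tuple[str, ...] = ()
    name: str = ""

    @property
    def limiting_element_is_carbon(self) -> bool:
        return self.limiting_exchange == self.carbon_exchange


def apply_scenario(model: MetabolicModel, scenario: LimitationScenario) -> MetabolicModel:
    """Return a copy of the model with exchange bounds set by the scenario."""
    exchanges = model.exchange_reaction_ids
    for rxn in (scenario.carbon_exchange, scenario.limiting_exchange, *scenario.free_exchanges):
        if rxn not in model.reaction_index:
            raise KeyError(f"scenario references unknown exchange {rxn!r}")
    bounds: dict[str, tuple[float, float]] = {}
    for rxn in exchanges:
        bounds[rxn] = (0.0, DEFAULT_BOUND)
    for rxn in scenario.free_exchanges:
        bounds[rxn] = (-DEFAULT_BOUND, DEFAULT_BOUND)
    if scenario.limiting_element_is_carbon:
        bounds[scenario.carbon_exchange] = (-scenario.limiting_uptake_bound, DEFAULT_BOUND)
    else:
        bounds[scenario.carbon_exchange] = (-DEFAULT_BOUND, DEFAULT_BOUND)
        bounds[scenario.limiting_exchange] = (-scenario.limiting_uptake_bound, DEFAULT_BOUND)
    return model.with_bounds(bounds)


@dataclass
class FluxDistribution:
    """One steady-state solution vector v with its objective value."""

    reaction_ids: list[str]
    fluxes: np.ndarray | None
    objective_value: float | None
    status: str
    scenario: LimitationScenario | None = None

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        if self.fluxes is None:
            raise ValueError(f"no fluxes available (status {self.status})")
        return float(self.fluxes[self.reaction_ids.index(reaction_id)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.fluxes, index=self.reaction_ids, name="flux")


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "failed"}


def _solve_lp(
    c: np.ndarray,
    S: sp.csr_matrix,
    lb: np.ndarray,
    ub: np.ndarray,
    sense: str,
) -> tuple[str, np.ndarray | None, float | None]:
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return status, None, None
    return status, res.x, float(sign * res.fun)


def optimize(
    model: MetabolicModel,
    objective: ObjectiveSpec | None = None,
    scenario: LimitationScenario | None = None,
    parsimonious: bool = False,
) -> FluxDistribution:
    """Solve the FBA linear program.

    With no explicit objective the biomass pseudoreaction is maximized.  When
    ``parsimonious`` is set, a secondary LP minimizes total absolute flux at
    the fixed optimal objective value, stabilizing reported flux summaries
    among alternate optima.
    """
    if objective is None:
        if model.biomass_reaction_id is None:
            raise ValueError("model has no biomass reaction and no objective was given")
        objective = ObjectiveSpec({model.biomass_reaction_id: 1.0}, "max")
    scoped = apply_scenario(model, scenario) if scenario is not None else model
    c = objective.dense(scoped)
    S = scoped.stoichiometry.tocsr()
    lb, ub = scoped.lower_bounds, scoped.upper_bounds

    status, v, z = _solve_lp(c, S, lb, ub, objective.sense)
    if status == "optimal" and parsimonious:
        v2 = _parsimonious(S, lb, ub, c, z, weights=_enzyme_weights(scoped))
        if v2 is not None:
            v = v2
    return FluxDistribution(
        reaction_ids=list(scoped.reaction_ids),
        fluxes=v,
        objective_value=z,
        status=status,
        scenario=scenario,
    )


def _enzyme_weights(model: MetabolicModel, background: float = 1e-3) -> np.ndarray:
    """Per-reaction weights for the parsimonious step.

    Parsimony proxies enzyme usage, so gene-associated reactions weigh 1;
    diffusion, exchange and other non-enzymatic pseudo-reactions get only a
    small tie-break weight.
    """
    return np.array([1.0 if rule else background for rule in model.gene_rules])


def _parsimonious(
    S: sp.csr_matrix,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    z_star: float,
    weights: np.ndarray | None = None,
) -> np.ndarray | None:
    """Minimize weighted sum |v| subject to S v = 0, bounds, and c'v = z*."""
    n = S.shape[1]
    # variables [v, t]; minimize w't with -t <= v <= t
    A_eq = sp.hstack([sp.vstack([S, sp.csr_matrix(c)]), sp.csr_matrix((S.shape[0] + 1, n))])
    b_eq = np.zeros(S.shape[0] + 1)
    b_eq[-1] = z_star
    eye = sp.identity(n)
    A_ub = sp.vstack([sp.hstack([eye, -eye]), sp.hstack([-eye, -eye])])
    b_ub = np.zeros(2 * n)
    obj = np.concatenate(
        [np.zeros(n), weights if weights is not None else np.ones(n)]
    )
    big = max(np.abs(lb).max(), np.abs(ub).max())
    var_bounds = np.vstack([np.column_stack([lb, ub]), np.column_stack([np.zeros(n), np.full(n, big)])])
    res = linprog(
        obj, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=var_bounds, method="highs"
    )
    if res.status != 0:
        return None
    return res.x[:n]


def uptake_sweep(
    model: MetabolicModel,
    exchange_id: str,
    lower_bounds: np.ndarray,
    tracked: list[str],
    scenario: LimitationScenario | None = None,
    parsimonious: bool = True,
) -> pd.DataFrame:
    """Maximize growth over a grid of lower bounds on one exchange reaction.

    Returns one row per grid point with the uptake bound, the realized growth
    rate and the flux of every tracked reaction; infeasible points yield NaN.
    """
    if exchange_id not in model.reaction_index:
        raise KeyError(f"unknown exchange {exchange_id!r}")
    base = apply_scenario(model, scenario) if scenario is not None else model
    rows = []
    for bound in np.asarray(lower_bounds, dtype=float):
        step = base.with_bounds({exchange_id: (bound, base.upper_bounds[base.reaction_index[exchange_id]])})
        dist = optimize(step, parsimonious=parsimonious)
        row = {"lower_bound": bound, "growth": np.nan}
        row.update({r: np.nan for r in tracked})
        if dist.is_optimal:
            row["growth"] = dist.objective_value
            for r in tracked:
                row[r] = dist[r]
        rows.append(row)
    return pd.DataFrame(rows)


def pathway_flux_summary(
    dist: FluxDistribution, groups: dict[str, list[str]]
) -> dict[str, float]:
    """Sum of absolute fluxes per named reaction group."""
    if dist.fluxes is None:
        raise ValueError(f"no fluxes available (status {dist.status})")
    index = {r: i for i, r in enumerate(dist.reaction_ids)}
    out = {}
    for name, members in groups.items():
        for r in members:
            if r not in index:
                raise KeyError(f"group {name!r} references unknown reaction {r!r}")
        out[name] = float(sum(abs(dist.fluxes[index[r]]) for r in members))
    return out


def chemostat_simulate(
    model: MetabolicModel,
    dilution_rate: float,
    carbon_exchange: str,
    parsimonious: bool = False,
) -> FluxDistribution:
    """Steady-state chemostat: fix growth to D, minimize carbon uptake.

    In a growth-limited chemostat the specific growth rate equals the imposed
    dilution rate; the cell is assumed to use the carbon source as frugally
    as the network allows, so the simulation objective maximizes the carbon
    exchange flux (uptake is negative, so this minimizes consumption).
    """
    if dilution_rate < 0:
        raise ValueError("dilution rate must be nonnegative")
    if model.biomass_reaction_id is None:
        raise ValueError("model has no biomass reaction")
    fixed = model.with_bounds({model.biomass_reaction_id: (dilution_rate, dilution_rate)})
    return optimize(
        fixed,
        ObjectiveSpec({carbon_exchange: 1.0}, "max"),
        parsimonious=parsimonious,
    )
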