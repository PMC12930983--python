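"""Random-objective exploration of the feasible flux space.

For a limitation scenario, growth is first maximized to obtain the reference
optimum v*growth; the growth pseudoreaction is then floored at
``growth_floor_fraction * v*growth`` (0.5 by default) and a series of FBA
problems is solved, each maximizing a randomly drawn objective vector.  The
collected solutions form an ensemble of attainable metabolic phenotypes at
suboptimal growth — not a uniform sample of the polytope.

Each random objective assigns i.i.d. uniform[-1, 1] coefficients to a random
reaction subset.  The subset is Bernoulli-selected with a configurable
density; the default density targets two reactions per objective, matching
the sparse random objectives of the toolbox routine this procedure follows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fba import FluxDistribution, LimitationScenario, ObjectiveSpec, apply_scenario, optimize
from .model import MetabolicModel

__all__ = ["SamplingConfig", "SamplingResult", "ScenarioError", "draw_objective", "sample"]


class ScenarioError(RuntimeError):
    """Raised when the growth reference of a scenario cannot be computed."""


@dataclass(frozen=True)
class SamplingConfig:
    """Settings of one random-sampling run.

    ``objective_density`` is the Bernoulli inclusion probability per
    reaction; ``None`` selects the default of two expected reactions.
    With ``parsimonious`` each accepted solution is post-processed by a
    total-|v| minimization at the fixed random-objective optimum, so that
    arbitrary alternate-optimum vertices do not contaminate secretion
    statistics with fluxes the objective never rewarded.
    """

    n_samples: int = 10_000
    growth_floor_fraction: float = 0.5
    seed: int = 0
    objective_density: float | None = None
    parsimonious: bool = True
    max_retries: int = 50

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (0 < self.growth_floor_fraction <= 1):
            raise ValueError("growth_floor_fraction must lie in (0, 1]")
        if self.objective_density is not None and not (0 < self.objective_density <= 1):
            raise ValueError("objective_density must lie in (0, 1]")

    def density_for(self, model: MetabolicModel) -> float:
        if self.objective_density is not None:
            return self.objective_density
        return min(1.0, 2.0 / max(model.n_reactions, 1))


@dataclass
class SamplingResult:
    """Flux matrix (reactions x n_samples) plus run metadata."""

    reaction_ids: list[str]
    flux_matrix: np.ndarray
    v_growth_star: float
    scenario: LimitationScenario
    config: SamplingConfig
    statuses: list[str]
    n_retries: int = 0

    @property
    def n_samples(self) -> int:
        return self.flux_matrix.shape[1]

    def flux_of(self, reaction_id: str) -> np.ndarray:
        """Row of the flux matrix for one reaction, over all samples."""
        return self.flux_matrix[self.reaction_ids.index(reaction_id), :]


def draw_objective(
    model: MetabolicModel, rng: np.random.Generator, density: float
) -> ObjectiveSpec:
    """Draw a random maximization objective.

    Reactions enter the support with probability ``density`` (at least one is
    guaranteed by redrawing); coefficients are uniform on [-1, 1].  Exchange
    reactions are eligible like any other.
    """
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    n = model.n_reactions
    while True:
        mask = rng.random(n) < density
        if mask.any():
            break
    coeffs = rng.uniform(-1.0, 1.0, size=int(mask.sum()))
    selected = np.flatnonzero(mask)
    return ObjectiveSpec(
        {model.reaction_ids[j]: float(c) for j, c in zip(selected, coeffs)},
        sense="max",
    )


def sample(
    model: MetabolicModel,
    scenario: LimitationScenario,
    config: SamplingConfig = SamplingConfig(),
) -> SamplingResult:
    """Run the randomized-objective FBA ensemble for one scenario.

    Reproducible for a fixed (model, scenario, config) triple: all
    randomness flows through one generator seeded from ``config.seed`` and
    samples are ordered by draw index.
    """
    if model.biomass_reaction_id is None:
        raise ScenarioError("model has no biomass reaction")
    scoped = apply_scenario(model, scenario)
    reference = optimize(scoped)
    if not reference.is_optimal or reference.objective_value is None:
        raise ScenarioError(
            f"growth maximization failed under scenario {scenario.name or scenario} "
            f"(status {reference.status})"
        )
    v_star = reference.objective_value
    if v_star <= 0:
        raise ScenarioError("optimal growth is zero; sampling floor undefined")

    floored = scoped.with_bounds(
        {model.biomass_reaction_id: (
            config.growth_floor_fraction * v_star,
            scoped.upper_bounds[scoped.reaction_index[model.biomass_reaction_id]],
        )}
    )
    rng = np.random.default_rng(config.seed)
    density = config.density_for(model)

    flux = np.empty((model.n_reactions, config.n_samples))
    statuses: list[str] = []
    retries = 0
    for k in range(config.n_samples):
        dist: FluxDistribution | None = None
        for _ in range(config.max_retries + 1):
            objective = draw_objective(floored, rng, density)
            dist = optimize(floored, objective, parsimonious=config.parsimonious)
            if dist.is_optimal:
                break
            retries += 1
        if dist is None or not dist.is_optimal:
            raise ScenarioError(
                f"sample {k} failed after {config.max_retries} retries "
                f"(last status {dist.status if dist else 'none'})"
            )
        flux[:, k] = dist.fluxes
        statuses.append(dist.status)

    return SamplingResult(
        reaction_ids=list(model.reaction_ids),
        flux_matrix=flux,
        v_growth_star=v_star,
        scenario=scenario,
        config=config,
        statuses=statuses,
        n_retries=retries,
    )
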