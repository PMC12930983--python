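"""FBA engine: oracle agreement, scenario recipes, sweeps, chemostats."""

import numpy as np
import pandas as pd
import pytest

from oxidogem.curation import delete_genes
from oxidogem.fba import (
    LimitationScenario,
    ObjectiveSpec,
    apply_scenario,
    chemostat_simulate,
    optimize,
    pathway_flux_summary,
    uptake_sweep,
)
from oxidogem.io import write_model
from oxidogem.model import parse_formula
from oxidogem.synth import GAL_CLUSTER, ToyModelSpec, build_toy_model, toy_pathway_groups, toy_scenario


def cobra_growth(model, scoped, tmp_path, objective="GROWTH"):
    """Independent oracle: same LP through cobrapy's SBML reader and GLPK."""
    import cobra

    path = tmp_path / "oracle.xml"
    write_model(model, path)
    cm = cobra.io.read_sbml_model(str(path))
    for rxn, lb, ub in zip(scoped.reaction_ids, scoped.lower_bounds, scoped.upper_bounds):
        r = cm.reactions.get_by_id(rxn)
        r.lower_bound, r.upper_bound = float(lb), float(ub)
    cm.objective = objective
    return cm.optimize().objective_value


@pytest.mark.parametrize(
    "carbon, limitation",
    [("galactose", "carbon"), ("galactose", "oxygen"), ("lactose", "nitrogen"),
     ("glucose", "carbon")],
)
def test_optimum_matches_independent_solver(toy_model, tmp_path, carbon, limitation):
    scenario = toy_scenario(carbon, limitation)
    scoped = apply_scenario(toy_model, scenario)
    mine = optimize(scoped)
    assert mine.is_optimal and mine.objective_value > 0
    oracle = cobra_growth(toy_model, scoped, tmp_path)
    assert mine.objective_value == pytest.approx(oracle, rel=1e-6)


def test_flux_distribution_invariants(toy_model):
    dist = optimize(toy_model, scenario=toy_scenario("galactose", "carbon"))
    scoped = apply_scenario(toy_model, toy_scenario("galactose", "carbon"))
    assert np.abs(scoped.stoichiometry @ dist.fluxes).max() < 1e-6
    assert np.all(dist.fluxes >= scoped.lower_bounds - 1e-7)
    assert np.all(dist.fluxes <= scoped.upper_bounds + 1e-7)


def test_no_carbon_no_growth(toy_model):
    scenario = toy_scenario("galactose", "carbon", uptake_bound=0.0)
    # maintenance ATP cannot be met without carbon: outright infeasible
    assert optimize(toy_model, scenario=scenario).status == "infeasible"
    # without the maintenance demand, starvation yields exactly zero growth
    relaxed = build_toy_model(ToyModelSpec(ngam=0.0))
    dist = optimize(relaxed, scenario=scenario)
    assert dist.is_optimal
    assert dist.objective_value == pytest.approx(0.0, abs=1e-9)


def test_growth_scales_with_limiting_bound():
    """Doubling the limiting uptake doubles optimal growth while no other
    bound binds (LP homogeneity; requires zero fixed-maintenance offset)."""
    model = build_toy_model(ToyModelSpec(ngam=0.0))
    g1 = optimize(model, scenario=toy_scenario("galactose", "carbon", 1.0)).objective_value
    g2 = optimize(model, scenario=toy_scenario("galactose", "carbon", 2.0)).objective_value
    assert g1 > 0
    assert g2 == pytest.approx(2 * g1, rel=1e-6)


def test_relaxing_a_bound_never_hurts(toy_model):
    base = optimize(toy_model, scenario=toy_scenario("galactose", "oxygen", 1.0)).objective_value
    relaxed = optimize(toy_model, scenario=toy_scenario("galactose", "oxygen", 2.0)).objective_value
    assert relaxed >= base - 1e-9


def test_carbon_is_conserved_across_exchanges(toy_model):
    """Carbon entering through uptakes leaves through secretion/CO2 or stays
    in biomass; the per-gDW biomass carbon content is scenario-independent."""
    retained = {}
    for carbon in ("galactose", "lactose"):
        dist = optimize(toy_model, scenario=toy_scenario(carbon, "carbon"))
        imbalance = 0.0
        for ex in toy_model.exchange_reaction_ids:
            met = next(iter(toy_model.reaction_stoichiometry(ex)))
            formula = parse_formula(toy_model.metabolite_formulas.get(met, ""))
            imbalance += dist[ex] * formula.get("C", 0.0)
        retained[carbon] = -imbalance / dist.objective_value  # mmol C per gDW
    assert retained["galactose"] > 0
    assert retained["galactose"] == pytest.approx(retained["lactose"], rel=1e-6)


def test_leloir_block_costs_yield_and_raises_ppp_flux(toy_model):
    """Forcing the oxidoreductive route reduces biomass yield modestly while
    diverting extra flux into the oxidative PPP; blocking the NADH-linked
    reductase on top roughly doubles the diversion again."""
    scenario = toy_scenario("galactose", "carbon")
    groups = toy_pathway_groups()
    opt = optimize(toy_model, scenario=scenario, parsimonious=True)
    leloir_blocked = toy_model.with_bounds({r: (0.0, 0.0) for r in groups["leloir"]})
    forced = optimize(leloir_blocked, scenario=scenario, parsimonious=True)
    nadph_only = leloir_blocked.with_bounds({"XYL1_2_NADH": (0.0, 0.0)})
    forced2 = optimize(nadph_only, scenario=scenario, parsimonious=True)

    drop = 1 - forced.objective_value / opt.objective_value
    assert 0 < drop < 0.10  # a modest single-digit-% yield penalty

    ppp_opt = pathway_flux_summary(opt, groups)["ppp"]
    ppp_forced = pathway_flux_summary(forced, groups)["ppp"]
    ppp_forced2 = pathway_flux_summary(forced2, groups)["ppp"]
    assert ppp_forced > 1.5 * ppp_opt
    assert ppp_forced2 > ppp_forced


def test_pathway_flux_summary_edges(toy_model):
    dist = optimize(toy_model, scenario=toy_scenario("galactose", "carbon"))
    zero = dist
    zero_dist = type(dist)(dist.reaction_ids, np.zeros_like(dist.fluxes), 0.0, "optimal")
    groups = {"a": ["GAL1", "PPP"], "b": ["OXPHOS"]}
    assert pathway_flux_summary(zero_dist, groups) == {"a": 0.0, "b": 0.0}
    with pytest.raises(KeyError):
        pathway_flux_summary(dist, {"bad": ["NOPE"]})


class TestUptakeSweep:
    def test_galactose_sweep_growth_monotone_no_ethanol(self, toy_model):
        table = uptake_sweep(
            toy_model, "EX_gal", np.linspace(-0.5, -5, 6), ["EX_etoh", "EX_gol"],
            scenario=toy_scenario("galactose", "carbon"),
        )
        assert not table["growth"].isna().any()
        growth = table["growth"].to_numpy()
        assert np.all(np.diff(growth) >= -1e-9)  # nondecreasing with uptake
        assert np.all(table["EX_etoh"].to_numpy() < 1e-6)

    def test_infeasible_points_reported_as_gaps(self, toy_model):
        # zero uptake cannot meet the fixed maintenance demand -> NaN row
        table = uptake_sweep(
            toy_model, "EX_gal", np.array([0.0, -1.0]), ["EX_etoh"],
            scenario=toy_scenario("galactose", "carbon"),
        )
        assert np.isnan(table.loc[0, "growth"])
        assert np.isfinite(table.loc[1, "growth"])

    def test_oxygen_sweep_switches_on_fermentation(self, toy_model):
        fixed_carbon = toy_scenario("galactose", "carbon", uptake_bound=1.0)
        table = uptake_sweep(
            toy_model, "EX_o2", np.linspace(-5, 0, 11), ["EX_etoh", "EX_gol"],
            scenario=fixed_carbon,
        )
        etoh = table["EX_etoh"].to_numpy()
        assert etoh[0] < 1e-6  # replete oxygen: fully respiratory
        assert etoh[-2] > 1e-6  # near-anoxia: ethanol overflow switches on

    def test_empty_grid(self, toy_model):
        table = uptake_sweep(toy_model, "EX_gal", np.array([]), ["EX_etoh"])
        assert table.empty


class TestChemostat:
    def test_zero_dilution_zero_maintenance_zero_uptake(self):
        model = build_toy_model(ToyModelSpec(ngam=0.0))
        rich = model.with_bounds(
            {ex: (-1000.0, 1000.0) for ex in ("EX_glc", "EX_o2", "EX_nh4", "EX_pi", "EX_h2o", "EX_h")}
        )
        dist = chemostat_simulate(rich, 0.0, "EX_glc")
        assert dist.is_optimal
        assert -dist["EX_glc"] == pytest.approx(0.0, abs=1e-8)

    def test_uptake_matches_independent_solver(self, toy_model, tmp_path):
        rich = toy_model.with_bounds(
            {ex: (-1000.0, 1000.0) for ex in ("EX_glc", "EX_o2", "EX_nh4", "EX_pi", "EX_h2o", "EX_h")}
        )
        D = 0.05
        dist = chemostat_simulate(rich, D, "EX_glc")
        fixed = rich.with_bounds({"GROWTH": (D, D)})
        oracle = cobra_growth(toy_model, fixed, tmp_path, objective="EX_glc")
        assert dist["EX_glc"] == pytest.approx(oracle, rel=1e-6)

    def test_dilution_beyond_max_growth_is_infeasible(self, toy_model):
        rich = toy_model.with_bounds(
            {ex: (-1000.0, 1000.0) for ex in ("EX_glc", "EX_o2", "EX_nh4", "EX_pi", "EX_h2o", "EX_h")}
        )
        mu_max = optimize(rich).objective_value
        dist = chemostat_simulate(rich, mu_max * 1.5, "EX_glc")
        assert dist.status == "infeasible" and dist.fluxes is None


def test_objective_spec_validation():
    with pytest.raises(ValueError):
        ObjectiveSpec({})
    with pytest.raises(ValueError):
        ObjectiveSpec({"r": 0.0})
    with pytest.raises(ValueError):
        ObjectiveSpec({"r": 1.0}, sense="sideways")


def test_scenario_unknown_exchange_rejected(toy_model):
    bad = LimitationScenario(carbon_exchange="EX_nope", limiting_exchange="EX_nope")
    with pytest.raises(KeyError):
        apply_scenario(toy_model, bad)
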