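"""Synthetic study inputs: toy dual-pathway model, chemostat data, expression.

The toy genome-scale model condenses lactose/galactose catabolism in a
Crabtree-like yeast into ~55 reactions: lactose uptake and hydrolysis, the
Leloir pathway (galactokinase, transferase, epimerase, phosphoglucomutase),
the oxidoreductive route (aldose reductases with NADH- and NADPH-linked
variants, galactitol dehydrogenase, L-xylo-3-hexulose reductase, sorbitol
dehydrogenase), lumped glycolysis, oxidative pentose phosphate pathway, TCA
cycle, oxidative phosphorylation parameterized by the P/O ratio, an ethanol
branch regenerating NAD⁺, maintenance reactions (GAM inside the biomass
pseudoreaction, NGAM as a forced ATP hydrolysis) and exchange reactions for
all external metabolites.  All internal reactions with fully specified
formulas are balanced for C, H, O, N and P.

Galactitol formation is redox-coupled (the NADH-linked reductase consumes
cytosolic NADH), so oxygen or nitrogen limitation elicits galactitol overflow
the way ethanol overflow appears in fermenting yeasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .fba import LimitationScenario, chemostat_simulate
from .model import DEFAULT_BOUND, MetabolicModel

__all__ = [
    "ToyModelSpec",
    "build_toy_model",
    "toy_markers",
    "toy_energetics_map",
    "toy_biomass_map",
    "toy_scenario",
    "toy_pathway_groups",
    "simulate_chemostat_data",
    "simulate_expression",
    "GALACTOSE_EXCHANGE",
    "LACTOSE_EXCHANGE",
    "GAL_CLUSTER",
]

GALACTOSE_EXCHANGE = "EX_gal"
LACTOSE_EXCHANGE = "EX_lac"
#: genes removed as a unit in the Leloir-deficient (galΔ) strain
GAL_CLUSTER = frozenset({"GAL1", "GAL7", "GAL10"})

# molecular formulas (charged species, as in consensus yeast models)
_FORMULAS = {
    "lactose": "C12H22O11",
    "gal": "C6H12O6",
    "glc": "C6H12O6",
    "fru": "C6H12O6",
    "srb": "C6H12O6",
    "xhl": "C6H12O6",
    "gol": "C6H14O6",
    "sbt": "C6H14O6",
    "gal1p": "C6H11O9P",
    "glc1p": "C6H11O9P",
    "g6p": "C6H11O9P",
    "f6p": "C6H11O9P",
    "udpglc": "C15H22N2O17P2",
    "udpgal": "C15H22N2O17P2",
    "pyr": "C3H3O3",
    "t3p": "C3H5O6P",
    "glyc": "C3H8O3",
    "etoh": "C2H6O",
    "atp": "C10H12N5O13P3",
    "adp": "C10H12N5O10P2",
    "pi": "HO4P",
    "h2o": "H2O",
    "h": "H",
    "o2": "O2",
    "co2": "CO2",
    "nh4": "H4N",
    "nad": "C21H26N7O14P2",
    "nadh": "C21H27N7O14P2",
    "nadp": "C21H25N7O17P3",
    "nadph": "C21H26N7O17P3",
    "ala": "C3H7NO2",
    "gly": "C2H5NO2",
    "ser": "C3H7NO3",
}

#: amino-acid residue masses, g/mol (free mass minus one water)
AA_RESIDUE_MW = {"ala": 71.08, "gly": 57.05, "ser": 87.08}
#: default molar amino-acid frequencies of the protein pseudoreaction
AA_FREQUENCIES = {"ala": 0.40, "gly": 0.35, "ser": 0.25}

_LIPID_UNIT_MW = 256.43  # palmitate-equivalent, g/mol
_CARB_UNIT_MW = 162.14  # anhydroglucose residue, g/mol


@dataclass(frozen=True)
class ToyModelSpec:
    """Construction recipe for the toy model.

    Energetic parameters are baked into the stoichiometry: ``gam`` is the ATP
    coefficient of the biomass pseudoreaction (mmol ATP·gDW⁻¹), ``ngam`` the
    forced lower bound of the maintenance hydrolysis (mmol ATP·gDW⁻¹·h⁻¹) and
    ``po_ratio`` the ATP produced per oxygen atom reduced in oxidative
    phosphorylation.
    """

    include_leloir: bool = True
    include_oxidoreductive: bool = True
    gam: float = 60.0
    ngam: float = 1.0
    po_ratio: float = 1.5
    protein_fraction: float = 0.45
    lipid_fraction: float = 0.07
    carbon_sources: tuple[str, ...] = ("lactose", "galactose", "glucose", "galactitol")

    def __post_init__(self):
        if not (self.include_leloir or self.include_oxidoreductive):
            raise ValueError("at least one galactose pathway must be included")
        if not self.carbon_sources:
            raise ValueError("at least one carbon source is required")
        if self.po_ratio < 0 or self.po_ratio > 3:
            raise ValueError("P/O ratio must lie in [0, 3]")


def _protein_coefficients(frequencies: dict[str, float]) -> dict[str, float]:
    """mmol of each amino acid per gram of protein polymer."""
    total = sum(frequencies.values())
    mean_res = sum(frequencies[a] / total * AA_RESIDUE_MW[a] for a in frequencies)
    return {a: 1000.0 * frequencies[a] / total / mean_res for a in frequencies}


def build_toy_model(spec: ToyModelSpec = ToyModelSpec()) -> MetabolicModel:
    """Assemble the toy lactose–galactose network as a MetabolicModel."""
    d = spec.po_ratio

    # reaction table: id -> (stoichiometry, lb, ub, rule, name)
    B = DEFAULT_BOUND
    rxns: dict[str, tuple[dict[str, float], float, float, str, str]] = {}

    def add(rid, stoich, lb, ub, rule="", name=""):
        rxns[rid] = (stoich, lb, ub, rule, name)

    # --- exchanges (one external metabolite each; negative flux = uptake)
    externals = [
        "lactose", "gal", "glc", "gol", "etoh", "glyc", "pyr", "sbt", "srb",
        "o2", "co2", "nh4", "pi", "h2o", "h",
    ]
    ex_id = {
        "lactose": "EX_lac", "gal": "EX_gal", "glc": "EX_glc", "gol": "EX_gol",
        "etoh": "EX_etoh", "glyc": "EX_glyc", "pyr": "EX_pyr",
        "sbt": "EX_sbt", "srb": "EX_srb",
        "o2": "EX_o2", "co2": "EX_co2", "nh4": "EX_nh4", "pi": "EX_pi",
        "h2o": "EX_h2o", "h": "EX_h",
    }
    free_media = {"o2", "nh4", "pi", "h2o", "h"}
    for met in externals:
        lb = -B if met in free_media else 0.0
        add(ex_id[met], {f"{met}[e]": -1.0}, lb, B, "", f"{met} exchange")

    # --- transport
    add("T_lac", {"lactose[e]": -1, "lactose[c]": 1}, 0, B, "LAC12", "lactose permease")
    add("T_gal", {"gal[e]": -1, "gal[c]": 1}, 0, B, "HGT1", "galactose transport")
    add("T_glc", {"glc[e]": -1, "glc[c]": 1}, 0, B, "HGT1", "glucose transport")
    add("T_gol", {"gol[c]": -1, "gol[e]": 1}, -B, B, "", "galactitol transport/diffusion")
    add("T_etoh", {"etoh[c]": -1, "etoh[e]": 1}, 0, B, "", "ethanol diffusion")
    add("T_glyc", {"glyc[c]": -1, "glyc[e]": 1}, 0, B, "", "glycerol export")
    add("T_pyr", {"pyr[c]": -1, "h[c]": -1, "pyr[e]": 1, "h[e]": 1},
        0, B, "", "pyruvate/proton symport (overflow exit)")
    add("T_sbt", {"sbt[c]": -1, "sbt[e]": 1}, -B, B, "SOT1", "D-sorbitol transport")
    add("T_srb", {"srb[c]": -1, "srb[e]": 1}, 0, B, "SOT2", "L-sorbose transport")
    add("T_o2", {"o2[e]": -1, "o2[c]": 1}, 0, B, "", "oxygen diffusion")
    add("T_co2", {"co2[c]": -1, "co2[e]": 1}, 0, B, "", "CO2 diffusion")
    add("T_nh4", {"nh4[e]": -1, "nh4[c]": 1}, 0, B, "MEP1", "ammonium transport")
    add("T_pi", {"pi[e]": -1, "pi[c]": 1}, -B, B, "PHO84", "phosphate transport")
    add("T_h2o", {"h2o[e]": -1, "h2o[c]": 1}, -B, B, "", "water diffusion")
    add("T_h", {"h[e]": -1, "h[c]": 1}, -B, B, "", "proton exchange")

    def c(*pairs):
        return {f"{m}[c]": v for m, v in pairs}

    # --- lactose hydrolysis and hexose activation
    add("LAC4", c(("lactose", -1), ("h2o", -1), ("gal", 1), ("glc", 1)),
        0, B, "LAC4", "beta-galactosidase")
    add("HXK", c(("glc", -1), ("atp", -1), ("g6p", 1), ("adp", 1), ("h", 1)),
        0, B, "HXK1", "hexokinase")
    add("FRK", c(("fru", -1), ("atp", -1), ("f6p", 1), ("adp", 1), ("h", 1)),
        0, B, "HXK1", "fructokinase")
    add("PGI", c(("g6p", -1), ("f6p", 1)), -B, B, "PGI1", "phosphoglucose isomerase")

    # --- Leloir pathway
    if spec.include_leloir:
        add("GAL1", c(("gal", -1), ("atp", -1), ("gal1p", 1), ("adp", 1), ("h", 1)),
            0, B, "GAL1", "galactokinase")
        add("GAL7", c(("gal1p", -1), ("udpglc", -1), ("glc1p", 1), ("udpgal", 1)),
            0, B, "GAL7", "galactose-1-phosphate uridylyltransferase")
        add("GAL10", c(("udpgal", -1), ("udpglc", 1)),
            -B, B, "GAL10", "UDP-glucose 4-epimerase")
        add("PGM", c(("glc1p", -1), ("g6p", 1)), -B, B, "PGM1", "phosphoglucomutase")

    # --- oxidoreductive pathway
    if spec.include_oxidoreductive:
        red = c(("gal", -1), ("gol", 1))
        add("XYL1_2_NADH", {**red, "nadh[c]": -1, "h[c]": -1, "nad[c]": 1},
            0, B, "XYL1_2", "galactose reductase (NADH)")
        add("XYL1_2_NADPH", {**red, "nadph[c]": -1, "h[c]": -1, "nadp[c]": 1},
            0, B, "XYL1_2", "galactose reductase (NADPH)")
        add("XYL1_1", {**red, "nadph[c]": -1, "h[c]": -1, "nadp[c]": 1},
            0, B, "XYL1_1", "aldose reductase (NADPH)")
        add("XYL1_3", {**red, "nadph[c]": -1, "h[c]": -1, "nadp[c]": 1},
            0, B, "XYL1_3", "aldose reductase (NADPH)")
        add("LAD1", c(("gol", -1), ("nad", -1), ("xhl", 1), ("nadh", 1), ("h", 1)),
            0, B, "LAD1", "galactitol dehydrogenase")
        add("LXR4", c(("xhl", -1), ("nadph", -1), ("h", -1), ("sbt", 1), ("nadp", 1)),
            0, B, "LXR4", "L-xylo-3-hexulose reductase")
        add("XYL2", c(("sbt", -1), ("nad", -1), ("fru", 1), ("nadh", 1), ("h", 1)),
            0, B, "XYL2", "D-sorbitol dehydrogenase")
        add("SDH_SRB", c(("sbt", -1), ("nad", -1), ("srb", 1), ("nadh", 1), ("h", 1)),
            0, B, "Seq_5357 or Seq_2923", "sorbitol to L-sorbose")

    # --- lumped central carbon metabolism (C/H/O/N/P balanced)
    add("GLYCO_UPPER",
        c(("f6p", -1), ("atp", -1), ("t3p", 2), ("adp", 1), ("h", 1)),
        0, B, "PFK1", "upper glycolysis, F6P to triose phosphate (lumped)")
    add("GLYCO_LOWER",
        c(("t3p", -1), ("adp", -2), ("pi", -1), ("nad", -1),
          ("pyr", 1), ("atp", 2), ("nadh", 1), ("h2o", 1)),
        0, B, "CDC19", "lower glycolysis, triose phosphate to pyruvate (lumped)")
    add("GLYCEROL_FORM",
        c(("t3p", -1), ("nadh", -1), ("h", -1), ("h2o", -1),
          ("glyc", 1), ("nad", 1), ("pi", 1)),
        0, B, "GPD1", "glycerol formation from triose phosphate (lumped)")
    add("PPP",
        c(("g6p", -1), ("nadp", -12), ("h2o", -7),
          ("co2", 6), ("nadph", 12), ("pi", 1), ("h", 12)),
        0, B, "ZWF1", "oxidative pentose phosphate pathway (lumped)")
    add("TCA",
        c(("pyr", -1), ("nad", -5), ("adp", -1), ("pi", -1), ("h2o", -2),
          ("co2", 3), ("nadh", 5), ("atp", 1), ("h", 3)),
        0, B, "CIT1", "pyruvate oxidation via the TCA cycle (lumped)")
    add("OXPHOS",
        c(("nadh", -1), ("o2", -0.5), ("adp", -d), ("pi", -d), ("h", -(1 + d)),
          ("nad", 1), ("atp", d), ("h2o", 1 + d)),
        0, B, "COX1 and ATP1", "oxidative phosphorylation (P/O parameterized)")
    add("ETOH_FORM",
        c(("pyr", -1), ("nadh", -1), ("h", -2), ("etoh", 1), ("co2", 1), ("nad", 1)),
        0, B, "PDC1 and ADH1", "pyruvate to ethanol (lumped)")
    # fixed-flux maintenance: the cell cannot dissipate surplus ATP at will,
    # so fermentative carbon disposal (which nets ATP) is only available when
    # ATP is actually demanded — the basis of condition-dependent overflow
    add("NGAM",
        c(("atp", -1), ("h2o", -1), ("adp", 1), ("pi", 1), ("h", 1)),
        spec.ngam, spec.ngam, "", "non-growth-associated maintenance")

    # --- anabolism
    add("ALA_SYN",
        c(("pyr", -1), ("nh4", -1), ("nadph", -1), ("h", -1),
          ("ala", 1), ("nadp", 1), ("h2o", 1)),
        0, B, "ALT1", "alanine synthesis (lumped)")
    add("GLY_SYN",
        c(("pyr", -1), ("nh4", -1), ("nad", -1), ("h2o", -1),
          ("gly", 1), ("co2", 1), ("nadh", 1), ("h", 3)),
        0, B, "SHM2", "glycine synthesis (lumped)")
    add("SER_SYN",
        c(("pyr", -1), ("nh4", -1), ("ser", 1)),
        0, B, "SER2", "serine synthesis (lumped)")

    aa_coeff = _protein_coefficients(AA_FREQUENCIES)
    add("PROT_SYN",
        {**{f"{a}[c]": -v for a, v in aa_coeff.items()},
         "atp[c]": -4.0 * sum(aa_coeff.values()),
         "h2o[c]": -4.0 * sum(aa_coeff.values()) + sum(aa_coeff.values()),
         "adp[c]": 4.0 * sum(aa_coeff.values()),
         "pi[c]": 4.0 * sum(aa_coeff.values()),
         "h[c]": 4.0 * sum(aa_coeff.values()),
         "protein[c]": 1.0},
        0, B, "", "protein synthesis, 1 g polymer per unit flux")
    n_lip = 1000.0 / _LIPID_UNIT_MW  # mmol palmitate-equivalent per g lipid
    add("LIPID_SYN",
        c(("pyr", -8 * n_lip), ("nadph", -14 * n_lip), ("atp", -7 * n_lip),
          ("nad", -8 * n_lip),
          ("co2", 8 * n_lip), ("nadh", 8 * n_lip), ("nadp", 14 * n_lip),
          ("adp", 7 * n_lip), ("pi", 7 * n_lip), ("lipid", 1.0)),
        0, B, "FAS1 and FAS2", "lipid synthesis, 1 g per unit flux (lumped)")
    n_carb = 1000.0 / _CARB_UNIT_MW
    add("CARB_SYN",
        c(("g6p", -n_carb), ("carb", 1.0), ("pi", n_carb)),
        0, B, "", "storage/structural carbohydrate, 1 g per unit flux")

    carb_fraction = 1.0 - spec.protein_fraction - spec.lipid_fraction
    if carb_fraction < 0:
        raise ValueError("protein and lipid fractions exceed 1 g/gDW")
    add("GROWTH",
        c(("protein", -spec.protein_fraction), ("lipid", -spec.lipid_fraction),
          ("carb", -carb_fraction),
          ("atp", -spec.gam), ("h2o", -spec.gam),
          ("adp", spec.gam), ("pi", spec.gam), ("h", spec.gam)),
        0, B, "", "biomass pseudoreaction (1 gDW per unit flux)")

    # --- assemble
    met_ids: list[str] = []
    met_index: dict[str, int] = {}
    rows, cols, vals = [], [], []
    reaction_ids, lbs, ubs, rules = [], [], [], []
    names: dict[str, str] = {}
    for j, (rid, (stoich, lb, ub, rule, name)) in enumerate(rxns.items()):
        reaction_ids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        rules.append(rule)
        if name:
            names[rid] = name
        for met, coeff in stoich.items():
            if met not in met_index:
                met_index[met] = len(met_ids)
                met_ids.append(met)
            rows.append(met_index[met])
            cols.append(j)
            vals.append(float(coeff))

    formulas = {}
    for m in met_ids:
        base = m.split("[")[0]
        if base in _FORMULAS:
            formulas[m] = _FORMULAS[base]

    genes = sorted({g for rule in rules for g in _rule_gene_set(rule)})
    model = MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=reaction_ids,
        gene_ids=genes,
        stoichiometry=sp.csc_matrix(
            (vals, (rows, cols)), shape=(len(met_ids), len(reaction_ids))
        ),
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        gene_rules=rules,
        compartments={"c": "cytosol", "e": "extracellular"},
        biomass_reaction_id="GROWTH",
        metabolite_formulas=formulas,
        reaction_names=names,
    )
    return _restrict_carbon_sources(model, spec)


def _rule_gene_set(rule: str) -> set[str]:
    from .rules import rule_genes

    return rule_genes(rule)


def _restrict_carbon_sources(model: MetabolicModel, spec: ToyModelSpec) -> MetabolicModel:
    by_source = {"lactose": "EX_lac", "galactose": "EX_gal",
                 "glucose": "EX_glc", "galactitol": "EX_gol"}
    missing = set(spec.carbon_sources) - set(by_source)
    if missing:
        raise ValueError(f"unknown carbon source(s) {sorted(missing)}")
    return model


def toy_markers():
    """Default pathway/secretion markers for the toy model."""
    from .phenotypes import PathwayMarkers

    return PathwayMarkers(
        leloir_marker_reactions=("GAL1", "GAL7", "GAL10"),
        oxidoreductive_marker_reactions=(
            "XYL1_2_NADH", "XYL1_2_NADPH", "XYL1_1", "XYL1_3", "LAD1", "LXR4", "XYL2"
        ),
        nadh_reductase_ids=("XYL1_2_NADH",),
        nadph_reductase_ids=("XYL1_2_NADPH", "XYL1_1", "XYL1_3"),
        secretion_watchlist=("EX_gol", "EX_etoh", "EX_sbt", "EX_srb"),
    )


def toy_pathway_groups() -> dict[str, list[str]]:
    return {
        "glycolysis": ["GLYCO_UPPER", "GLYCO_LOWER"],
        "ppp": ["PPP"],
        "leloir": ["GAL1", "GAL7", "GAL10"],
        "oxidoreductive": ["XYL1_2_NADH", "XYL1_2_NADPH", "XYL1_1", "XYL1_3",
                           "LAD1", "LXR4", "XYL2"],
    }


def toy_energetics_map():
    from .energetics import EnergeticsMap

    return EnergeticsMap(
        oxphos_reaction="OXPHOS",
        ngam_reaction="NGAM",
        biomass_reaction="GROWTH",
        atp="atp[c]", adp="adp[c]", pi="pi[c]", h="h[c]", h2o="h2o[c]",
    )


def toy_biomass_map():
    from .energetics import BiomassMap

    return BiomassMap(
        biomass_reaction="GROWTH",
        protein_pool="protein[c]",
        lipid_pool="lipid[c]",
        carbohydrate_pool="carb[c]",
        protein_synthesis_reaction="PROT_SYN",
        amino_acids={f"{a}[c]": AA_RESIDUE_MW[a] for a in AA_RESIDUE_MW},
        water="h2o[c]",
    )


_EX_BY_CARBON = {"galactose": "EX_gal", "lactose": "EX_lac",
                 "glucose": "EX_glc", "galactitol": "EX_gol"}
_EX_BY_LIMIT = {"oxygen": "EX_o2", "nitrogen": "EX_nh4"}
_FREE_MEDIA = ("EX_o2", "EX_nh4", "EX_pi", "EX_h2o", "EX_h")


def toy_scenario(
    carbon: str = "galactose",
    limitation: str = "carbon",
    uptake_bound: float = 1.0,
) -> LimitationScenario:
    """The paper-style limitation recipes instantiated on the toy exchanges."""
    carbon_ex = _EX_BY_CARBON[carbon]
    if limitation == "carbon":
        limiting_ex = carbon_ex
    else:
        limiting_ex = _EX_BY_LIMIT[limitation]
    free = tuple(e for e in _FREE_MEDIA if e != limiting_ex)
    return LimitationScenario(
        carbon_exchange=carbon_ex,
        limiting_exchange=limiting_ex,
        limiting_uptake_bound=uptake_bound,
        free_exchanges=free,
        name=f"{carbon}/{limitation}-limited",
    )


def simulate_chemostat_data(
    model: MetabolicModel,
    dilution_rates=(0.05, 0.1),
    carbon_exchange: str = "EX_glc",
    oxygen_exchange: str = "EX_o2",
    co2_exchange: str = "EX_co2",
    noise_sd: float = 0.0,
    seed: int | None = None,
    free_exchanges: tuple[str, ...] = _FREE_MEDIA,
    oxygen_bounds=None,
):
    """Chemostat rate observations from the model plus relative Gaussian noise.

    ``oxygen_bounds`` optionally caps the oxygen uptake (mmol·gDW⁻¹·h⁻¹) per
    dilution rate (``None`` entries = fully aerobic).  Carbon-limited aerobic
    rates alone leave an exact trade-off between maintenance ATP and the P/O
    ratio; one oxygen-restricted observation makes all three energetic
    parameters identifiable.
    """
    from .energetics import ChemostatObservation

    if oxygen_bounds is None:
        oxygen_bounds = [None] * len(dilution_rates)
    if len(oxygen_bounds) != len(dilution_rates):
        raise ValueError("oxygen_bounds must match dilution_rates in length")
    rng = np.random.default_rng(seed)
    medium = model.with_bounds(
        {ex: (-DEFAULT_BOUND, DEFAULT_BOUND) for ex in free_exchanges}
    ).with_bounds({carbon_exchange: (-DEFAULT_BOUND, DEFAULT_BOUND)})
    observations = []
    for D, o2_cap in zip(dilution_rates, oxygen_bounds):
        vessel = medium if o2_cap is None else medium.with_bounds(
            {oxygen_exchange: (-abs(o2_cap), DEFAULT_BOUND)}
        )
        dist = chemostat_simulate(vessel, D, carbon_exchange)
        if not dist.is_optimal:
            raise ValueError(f"dilution rate {D} infeasible for this model")
        rates = np.array([
            -dist[carbon_exchange], -dist[oxygen_exchange], dist[co2_exchange]
        ])
        rates = rates * (1.0 + noise_sd * rng.standard_normal(3))
        observations.append(
            ChemostatObservation(
                dilution_rate=D,
                carbon_uptake=float(rates[0]),
                oxygen_uptake=float(rates[1]),
                co2_production=float(rates[2]),
                oxygen_bound=o2_cap,
            )
        )
    return observations


def simulate_expression(
    genes: list[str],
    conditions: list[str] | None = None,
    blocks: list[list[str]] | None = None,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Expression matrix with planted co-regulated blocks.

    Genes within a block share a latent per-condition profile plus i.i.d.
    Gaussian noise; all other genes are independent.  Returns the genes x
    conditions matrix and the ground-truth block label per gene (-1 for
    background).
    """
    if conditions is None:
        conditions = ["glucose", "lactose", "galactose", "cellobiose", "xylose"]
    blocks = blocks or []
    seen: set[str] = set()
    for block in blocks:
        overlap = seen & set(block)
        if overlap:
            raise ValueError(f"blocks overlap on {sorted(overlap)}")
        seen.update(block)
        if not set(block) <= set(genes):
            raise ValueError("block genes must be a subset of genes")
    rng = np.random.default_rng(seed)
    n_cond = len(conditions)
    data = rng.standard_normal((len(genes), n_cond))
    labels = {g: -1 for g in genes}
    gene_index = {g: i for i, g in enumerate(genes)}
    for b, block in enumerate(blocks):
        latent = rng.standard_normal(n_cond)
        # unit-variance latent profile so noise_sd sets the signal-to-noise
        latent = (latent - latent.mean()) / latent.std(ddof=0)
        for g in block:
            data[gene_index[g]] = latent + noise_sd * rng.standard_normal(n_cond)
            labels[g] = b
    frame = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), columns=conditions)
    return frame, labels
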