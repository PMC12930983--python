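"""Energetic-parameter fitting and biomass-composition updates.

Three parameters set a GEM's energy economy: GAM (growth-associated
maintenance, mmol ATP hydrolysed per gDW formed, a coefficient of the
biomass pseudoreaction), NGAM (non-growth-associated maintenance, a forced
ATP-hydrolysis flux in mmol·gDW⁻¹·h⁻¹) and the P/O ratio (ATP produced per
oxygen atom reduced by the respiratory chain, a stoichiometric coefficient of
the oxidative-phosphorylation reaction).  They are fitted by minimizing the
RMSE between chemostat-predicted and measured carbon uptake, oxygen uptake
and CO₂ production across dilution rates: a coarse grid search followed by
derivative-free local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .fba import chemostat_simulate
from .model import DEFAULT_BOUND, MetabolicModel

__all__ = [
    "ChemostatObservation",
    "EnergeticsParameters",
    "EnergeticsMap",
    "BiomassMap",
    "set_energetics",
    "get_energetics",
    "EnergeticsFitter",
    "fit_energetics",
    "update_biomass",
    "biomass_mass_audit",
]


@dataclass(frozen=True)
class ChemostatObservation:
    """Measured steady-state rates at one dilution rate (mmol·gDW⁻¹·h⁻¹)."""

    dilution_rate: float
    carbon_uptake: float
    oxygen_uptake: float
    co2_production: float
    protein_fraction: float | None = None
    lipid_fraction: float | None = None
    #: imposed oxygen-uptake cap during the run (None = fully aerobic)
    oxygen_bound: float | None = None

    def __post_init__(self):
        if self.dilution_rate <= 0:
            raise ValueError("dilution rate must be positive")
        for rate in (self.carbon_uptake, self.oxygen_uptake, self.co2_production):
            if not np.isfinite(rate):
                raise ValueError("rates must be finite")
        for frac in (self.protein_fraction, self.lipid_fraction):
            if frac is not None and not (0 <= frac <= 1):
                raise ValueError("biomass fractions must lie in [0, 1]")


@dataclass(frozen=True)
class EnergeticsParameters:
    gam: float  # mmol ATP / gDW
    ngam: float  # mmol ATP / gDW / h
    po_ratio: float  # dimensionless

    def __post_init__(self):
        if self.gam < 0 or self.ngam < 0 or self.po_ratio < 0:
            raise ValueError("energetic parameters must be nonnegative")
        if self.po_ratio > 3:
            raise ValueError("P/O ratio above 3 is not physical")


@dataclass(frozen=True)
class EnergeticsMap:
    """Where the energetic parameters live in a particular model."""

    oxphos_reaction: str
    ngam_reaction: str
    biomass_reaction: str
    atp: str
    adp: str
    pi: str
    h: str
    h2o: str


def get_energetics(model: MetabolicModel, emap: EnergeticsMap) -> EnergeticsParameters:
    S = model.stoichiometry
    midx, ridx = model.metabolite_index, model.reaction_index
    gam = -float(S[midx[emap.atp], ridx[emap.biomass_reaction]])
    ngam = float(model.lower_bounds[ridx[emap.ngam_reaction]])
    po = float(S[midx[emap.atp], ridx[emap.oxphos_reaction]])
    return EnergeticsParameters(gam=gam, ngam=ngam, po_ratio=po)


def set_energetics(
    model: MetabolicModel, emap: EnergeticsMap, params: EnergeticsParameters
) -> MetabolicModel:
    """Return a copy with GAM, NGAM and P/O written into the stoichiometry.

    The oxidative-phosphorylation reaction keeps its NADH/O2 stoichiometry;
    its ATP, ADP, Pi, proton and water coefficients are rewritten for the new
    P/O ratio.  The biomass reaction's maintenance-hydrolysis coefficients
    are rewritten for the new GAM, and the NGAM reaction's lower bound is set.
    """
    new = model.copy()
    S = new.stoichiometry.tolil()
    midx, ridx = new.metabolite_index, new.reaction_index
    d = params.po_ratio
    j = ridx[emap.oxphos_reaction]
    S[midx[emap.adp], j] = -d
    S[midx[emap.pi], j] = -d
    S[midx[emap.h], j] = -(1.0 + d)
    S[midx[emap.atp], j] = d
    S[midx[emap.h2o], j] = 1.0 + d
    j = ridx[emap.biomass_reaction]
    g = params.gam
    S[midx[emap.atp], j] = -g
    S[midx[emap.h2o], j] = -g
    S[midx[emap.adp], j] = g
    S[midx[emap.pi], j] = g
    S[midx[emap.h], j] = g
    new.stoichiometry = S.tocsc()
    j = ridx[emap.ngam_reaction]
    fixed = new.lower_bounds[j] == new.upper_bounds[j]
    new.lower_bounds[j] = params.ngam
    if fixed or new.upper_bounds[j] < params.ngam:
        new.upper_bounds[j] = params.ngam
    return new


class FitError(RuntimeError):
    """Raised when no feasible point exists on the search grid."""


class EnergeticsFitter:
    """RMSE fit of (GAM, NGAM, P/O) to chemostat rates (sklearn style).

    Parameters
    ----------
    model : MetabolicModel
        Model whose energetics are re-parameterized per candidate.
    energetics_map : EnergeticsMap
        Location of the tunable coefficients.
    carbon_exchange, oxygen_exchange, co2_exchange : str
        Exchange reactions compared against the measured rates.
    free_exchanges : tuple of str
        Medium components opened to -1000 during simulation.
    gam_grid, ngam_grid, po_grid : arrays
        Coarse search grid (defaults: GAM 10-120, NGAM 0-5, P/O 0.5-3).
    refine : bool
        Run Nelder-Mead from the best grid point.
    normalize : bool
        Scale each rate type by its mean measured magnitude before pooling,
        so carbon, oxygen and CO₂ residuals weigh comparably.

    Attributes (after ``fit``)
    --------------------------
    gam_, ngam_, po_ratio_ : fitted parameters.
    rmse_ : pooled RMSE at the optimum.
    residuals_ : DataFrame of per-dilution-rate residuals.
    report_ : dict with the grid objective surface and degeneracy flags.
    """

    def __init__(
        self,
        model: MetabolicModel,
        energetics_map: EnergeticsMap,
        carbon_exchange: str,
        oxygen_exchange: str = "EX_o2",
        co2_exchange: str = "EX_co2",
        free_exchanges: tuple[str, ...] = (),
        gam_grid=None,
        ngam_grid=None,
        po_grid=None,
        refine: bool = True,
        normalize: bool = True,
    ):
        self.model = model
        self.energetics_map = energetics_map
        self.carbon_exchange = carbon_exchange
        self.oxygen_exchange = oxygen_exchange
        self.co2_exchange = co2_exchange
        self.free_exchanges = free_exchanges
        self.gam_grid = np.asarray(gam_grid if gam_grid is not None else np.linspace(10, 120, 7))
        self.ngam_grid = np.asarray(ngam_grid if ngam_grid is not None else np.linspace(0, 5, 6))
        self.po_grid = np.asarray(po_grid if po_grid is not None else np.linspace(0.5, 3.0, 6))
        self.refine = refine
        self.normalize = normalize

    def get_params(self, deep: bool = True) -> dict:
        return {
            "model": self.model,
            "energetics_map": self.energetics_map,
            "carbon_exchange": self.carbon_exchange,
            "oxygen_exchange": self.oxygen_exchange,
            "co2_exchange": self.co2_exchange,
            "free_exchanges": self.free_exchanges,
            "gam_grid": self.gam_grid,
            "ngam_grid": self.ngam_grid,
            "po_grid": self.po_grid,
            "refine": self.refine,
            "normalize": self.normalize,
        }

    def set_params(self, **params) -> "EnergeticsFitter":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- prediction --------------------------------------------------------
    def _medium(self, model: MetabolicModel) -> MetabolicModel:
        opened = {ex: (-DEFAULT_BOUND, DEFAULT_BOUND) for ex in self.free_exchanges}
        opened[self.carbon_exchange] = (-DEFAULT_BOUND, DEFAULT_BOUND)
        return model.with_bounds(opened)

    def predict(
        self, params: EnergeticsParameters, observations
    ) -> pd.DataFrame | None:
        """Predicted (carbon uptake, O₂ uptake, CO₂ production) per run.

        ``observations`` may be ChemostatObservation objects (whose dilution
        rate and oxygen cap are reproduced) or bare dilution rates.
        """
        candidate = self._medium(set_energetics(self.model, self.energetics_map, params))
        o2_idx = candidate.reaction_index[self.oxygen_exchange]
        rows = []
        for obs in observations:
            if isinstance(obs, ChemostatObservation):
                D, o2_cap = obs.dilution_rate, obs.oxygen_bound
            else:
                D, o2_cap = float(obs), None
            vessel = candidate if o2_cap is None else candidate.with_bounds(
                {self.oxygen_exchange: (-abs(o2_cap), candidate.upper_bounds[o2_idx])}
            )
            dist = chemostat_simulate(vessel, D, self.carbon_exchange)
            if not dist.is_optimal:
                return None
            rows.append(
                {
                    "dilution_rate": D,
                    "carbon_uptake": -dist[self.carbon_exchange],
                    "oxygen_uptake": -dist[self.oxygen_exchange],
                    "co2_production": dist[self.co2_exchange],
                }
            )
        return pd.DataFrame(rows)

    def _rmse(self, params: EnergeticsParameters, observations) -> float | None:
        predicted = self.predict(params, observations)
        if predicted is None:
            return None
        measured = np.array(
            [[o.carbon_uptake, o.oxygen_uptake, o.co2_production] for o in observations]
        )
        model_rates = predicted[["carbon_uptake", "oxygen_uptake", "co2_production"]].to_numpy()
        residual = model_rates - measured
        if self.normalize:
            scale = np.maximum(np.abs(measured).mean(axis=0), 1e-12)
            residual = residual / scale
        return float(np.sqrt(np.mean(residual**2)))

    # -- fitting -----------------------------------------------------------
    def fit(self, observations: list[ChemostatObservation]) -> "EnergeticsFitter":
        if len(observations) < 1:
            raise ValueError("need at least one chemostat observation")
        surface = []
        best, best_rmse = None, np.inf
        for gam in self.gam_grid:
            for ngam in self.ngam_grid:
                for po in self.po_grid:
                    params = EnergeticsParameters(gam, ngam, po)
                    rmse = self._rmse(params, observations)
                    surface.append(
                        {"gam": gam, "ngam": ngam, "po_ratio": po, "rmse": rmse}
                    )
                    if rmse is not None and rmse < best_rmse:
                        best, best_rmse = params, rmse
        if best is None:
            raise FitError("every grid point was infeasible for the observed dilution rates")

        if self.refine:
            lo = np.array([self.gam_grid.min(), self.ngam_grid.min(), self.po_grid.min()])
            hi = np.array([self.gam_grid.max(), self.ngam_grid.max(), self.po_grid.max()])

            def objective(x):
                x = np.clip(x, lo, hi)
                rmse = self._rmse(EnergeticsParameters(*x), observations)
                return rmse if rmse is not None else 1e6

            res = minimize(
                objective,
                x0=[best.gam, best.ngam, best.po_ratio],
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400},
            )
            refined = EnergeticsParameters(*np.clip(res.x, lo, hi))
            refined_rmse = self._rmse(refined, observations)
            if refined_rmse is not None and refined_rmse <= best_rmse:
                best, best_rmse = refined, refined_rmse

        self.gam_, self.ngam_, self.po_ratio_ = best.gam, best.ngam, best.po_ratio
        self.params_ = best
        self.rmse_ = best_rmse
        predicted = self.predict(best, observations)
        measured = pd.DataFrame(
            [
                {
                    "dilution_rate": o.dilution_rate,
                    "carbon_uptake": o.carbon_uptake,
                    "oxygen_uptake": o.oxygen_uptake,
                    "co2_production": o.co2_production,
                }
                for o in observations
            ]
        )
        rate_cols = ["carbon_uptake", "oxygen_uptake", "co2_production"]
        self.residuals_ = measured[["dilution_rate"]].assign(
            **{c: predicted[c].to_numpy() - measured[c].to_numpy() for c in rate_cols}
        )
        n_rates = len({o.dilution_rate for o in observations})
        self.report_ = {
            "grid_surface": pd.DataFrame(surface),
            "degenerate_dilution": n_rates < 2,
            "n_observations": len(observations),
        }
        return self


def fit_energetics(
    model: MetabolicModel,
    observations: list[ChemostatObservation],
    energetics_map: EnergeticsMap,
    carbon_exchange: str,
    **kwargs,
) -> EnergeticsFitter:
    """Functional wrapper around :class:`EnergeticsFitter`."""
    return EnergeticsFitter(model, energetics_map, carbon_exchange, **kwargs).fit(observations)


# ---------------------------------------------------------------------------
# biomass composition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiomassMap:
    """Where biomass pools and the protein pseudoreaction live in a model.

    Pool pseudo-metabolites represent 1 g of polymer per mmol, so biomass
    coefficients are g·gDW⁻¹ mass fractions directly.  ``amino_acids`` maps
    amino-acid metabolite ids to residue masses (g/mol).
    """

    biomass_reaction: str
    protein_pool: str
    lipid_pool: str
    carbohydrate_pool: str
    protein_synthesis_reaction: str
    amino_acids: dict[str, float]
    water: str


class CompositionError(ValueError):
    """Raised when requested mass fractions cannot sum to 1 g/gDW."""


def biomass_mass_audit(model: MetabolicModel, bmap: BiomassMap) -> float:
    """Total grams of biomass polymer pools consumed per gDW formed."""
    stoich = model.reaction_stoichiometry(bmap.biomass_reaction)
    pools = (bmap.protein_pool, bmap.lipid_pool, bmap.carbohydrate_pool)
    return float(sum(-stoich.get(p, 0.0) for p in pools))


def update_biomass(
    model: MetabolicModel,
    bmap: BiomassMap,
    protein_fraction: float,
    lipid_fraction: float,
    aa_frequencies: dict[str, float] | None = None,
) -> MetabolicModel:
    """Rescale biomass composition to measured protein/lipid fractions.

    The carbohydrate (remainder) pool absorbs the balance so total biomass
    mass stays at 1 g·gDW⁻¹.  When amino-acid molar frequencies are given
    (summing to 1 within 1e-6), the protein pseudoreaction's amino-acid
    coefficients are rebuilt proportional to them, scaled by residue masses
    so one flux unit still polymerizes 1 g of protein; the polymerization
    ATP cost per residue is preserved.
    """
    if not (0 <= protein_fraction <= 1 and 0 <= lipid_fraction <= 1):
        raise CompositionError("fractions must lie in [0, 1]")
    carb = 1.0 - protein_fraction - lipid_fraction
    if carb < -1e-12:
        raise CompositionError(
            f"protein ({protein_fraction}) + lipid ({lipid_fraction}) exceed 1 g/gDW"
        )
    carb = max(carb, 0.0)

    new = model.copy()
    S = new.stoichiometry.tolil()
    midx, ridx = new.metabolite_index, new.reaction_index
    j = ridx[bmap.biomass_reaction]
    S[midx[bmap.protein_pool], j] = -protein_fraction
    S[midx[bmap.lipid_pool], j] = -lipid_fraction
    S[midx[bmap.carbohydrate_pool], j] = -carb

    if aa_frequencies is not None:
        total = sum(aa_frequencies.values())
        if abs(total - 1.0) > 1e-6:
            raise CompositionError(f"amino-acid frequencies sum to {total}, not 1")
        bare = {_strip(a) for a in bmap.amino_acids}
        unknown = {k for k in aa_frequencies if k not in bmap.amino_acids and k not in bare}
        if unknown:
            raise CompositionError(f"unknown amino acid(s) {sorted(unknown)}")
        jp = ridx[bmap.protein_synthesis_reaction]
        old = model.reaction_stoichiometry(bmap.protein_synthesis_reaction)
        old_total_aa = sum(-old.get(a, 0.0) for a in bmap.amino_acids)
        if old_total_aa <= 0:
            raise CompositionError("protein synthesis reaction consumes no amino acids")
        # all non-amino-acid, non-pool coefficients (ATP cost, peptide water,
        # hydrolysis products) scale per residue
        per_residue = {
            m: v / old_total_aa
            for m, v in old.items()
            if m not in bmap.amino_acids and m != bmap.protein_pool
        }
        # molar frequencies may be keyed by metabolite id or by its bare name
        freqs = {a: aa_frequencies.get(a, aa_frequencies.get(_strip(a), 0.0)) for a in bmap.amino_acids}
        mean_res = sum(freqs[a] * bmap.amino_acids[a] for a in bmap.amino_acids)
        if mean_res <= 0:
            raise CompositionError("frequencies give a nonpositive mean residue mass")
        # mmol of each residue per gram of polymer
        new_coeffs = {a: 1000.0 * freqs[a] / mean_res for a in bmap.amino_acids}
        new_total_aa = sum(new_coeffs.values())
        for a, coeff in new_coeffs.items():
            S[midx[a], jp] = -coeff
        for m, per_res in per_residue.items():
            S[midx[m], jp] = per_res * new_total_aa

    new.stoichiometry = S.tocsc()
    new._check_integrity()
    return new


def _strip(metabolite_id: str) -> str:
    return metabolite_id.split("[")[0]
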