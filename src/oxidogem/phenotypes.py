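"""Phenotype labelling of sampled flux distributions.

Each sampled column is labelled by galactose-pathway usage (Leloir only,
oxidoreductive only, dual, none), by the set of watchlist metabolites it
secretes (positive exchange flux above a small epsilon) and by the redox
cofactor its galactose-reductase flux runs on; labels aggregate into the
percentage tables reported per carbon source and limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fba import FLUX_EPSILON
from .sampling import SamplingResult

__all__ = ["PathwayMarkers", "PhenotypeSummary", "classify", "cofactor_usage", "summarize_table"]

PATHWAY_LABELS = ("leloir_only", "oxidoreductive_only", "dual", "none")
COFACTOR_LABELS = ("nadh_only", "nadph_only", "dual", "none")


@dataclass(frozen=True)
class PathwayMarkers:
    """Reaction ids marking each pathway and the secretion watchlist.

    The reductase id tuples hold the NADH-linked and NADPH-linked galactose
    reductase variants (several NADPH-only isoenzymes may exist).
    """

    leloir_marker_reactions: tuple[str, ...]
    oxidoreductive_marker_reactions: tuple[str, ...]
    nadh_reductase_ids: tuple[str, ...]
    nadph_reductase_ids: tuple[str, ...]
    secretion_watchlist: tuple[str, ...]

    def __post_init__(self):
        overlap = set(self.leloir_marker_reactions) & set(self.oxidoreductive_marker_reactions)
        if overlap:
            raise ValueError(f"marker sets overlap on {sorted(overlap)}")

    def validate_for(self, reaction_ids: list[str]) -> None:
        known = set(reaction_ids)
        for group in (
            self.leloir_marker_reactions,
            self.oxidoreductive_marker_reactions,
            self.nadh_reductase_ids,
            self.nadph_reductase_ids,
            self.secretion_watchlist,
        ):
            missing = set(group) - known
            if missing:
                raise KeyError(f"marker reaction(s) {sorted(missing)} not in model")


@dataclass
class PhenotypeSummary:
    """Per-sample labels plus aggregated percentages for one scenario."""

    per_sample: pd.DataFrame  # columns: pathway, cofactor, secreted_<ex> flags
    pathway_percent: dict[str, float]
    cofactor_percent: dict[str, float]
    secretion_percent: dict[str, float]
    scenario_name: str
    n_samples: int
    flux_epsilon: float


def _active(result: SamplingResult, markers: tuple[str, ...], eps: float, strict: bool) -> np.ndarray:
    if not markers:
        return np.zeros(result.n_samples, dtype=bool)
    rows = np.abs(np.vstack([result.flux_of(r) for r in markers])) > eps
    return rows.all(axis=0) if strict else rows.any(axis=0)


def classify(
    result: SamplingResult,
    markers: PathwayMarkers,
    flux_epsilon: float = FLUX_EPSILON,
    strict_chain: bool = False,
) -> PhenotypeSummary:
    """Label every sampled distribution and aggregate percentages.

    A pathway counts as active when the maximum absolute flux over its marker
    reactions exceeds ``flux_epsilon`` (with ``strict_chain`` every marker
    must carry flux); a metabolite counts as secreted when its exchange flux
    exceeds ``flux_epsilon`` (positive = out of the cell).
    """
    markers.validate_for(result.reaction_ids)
    n = result.n_samples

    leloir = _active(result, markers.leloir_marker_reactions, flux_epsilon, strict_chain)
    oxido = _active(result, markers.oxidoreductive_marker_reactions, flux_epsilon, strict_chain)
    pathway = np.where(
        leloir & oxido, "dual",
        np.where(leloir, "leloir_only", np.where(oxido, "oxidoreductive_only", "none")),
    )

    cofactor = _cofactor_labels(result, markers, flux_epsilon)

    data = {"pathway": pathway, "cofactor": cofactor}
    secretion_percent = {}
    for ex in markers.secretion_watchlist:
        secreting = result.flux_of(ex) > flux_epsilon
        data[f"secreted_{ex}"] = secreting
        secretion_percent[ex] = 100.0 * secreting.mean()

    per_sample = pd.DataFrame(data)
    pathway_percent = {
        label: 100.0 * float((pathway == label).mean()) for label in PATHWAY_LABELS
    }
    cofactor_percent = {
        label: 100.0 * float((cofactor == label).mean()) for label in COFACTOR_LABELS
    }
    return PhenotypeSummary(
        per_sample=per_sample,
        pathway_percent=pathway_percent,
        cofactor_percent=cofactor_percent,
        secretion_percent=secretion_percent,
        scenario_name=result.scenario.name,
        n_samples=n,
        flux_epsilon=flux_epsilon,
    )


def _cofactor_labels(
    result: SamplingResult, markers: PathwayMarkers, eps: float
) -> np.ndarray:
    nadh = _active(result, markers.nadh_reductase_ids, eps, strict=False)
    nadph = _active(result, markers.nadph_reductase_ids, eps, strict=False)
    return np.where(
        nadh & nadph, "dual",
        np.where(nadh, "nadh_only", np.where(nadph, "nadph_only", "none")),
    )


def cofactor_usage(
    result: SamplingResult,
    markers: PathwayMarkers,
    flux_epsilon: float = FLUX_EPSILON,
) -> pd.DataFrame:
    """Per-sample cofactor label and NADH-vs-NADPH preference.

    ``prefers_nadh`` compares total NADH-variant flux against total
    NADPH-variant flux of the galactose reductase; filter on
    ``oxidoreductive_active`` for pathway-conditional preference rates.
    """
    markers.validate_for(result.reaction_ids)
    nadh_flux = np.sum(
        [np.abs(result.flux_of(r)) for r in markers.nadh_reductase_ids], axis=0
    )
    nadph_flux = np.sum(
        [np.abs(result.flux_of(r)) for r in markers.nadph_reductase_ids], axis=0
    )
    oxido = _active(result, markers.oxidoreductive_marker_reactions, flux_epsilon, False)
    return pd.DataFrame(
        {
            "cofactor": _cofactor_labels(result, markers, flux_epsilon),
            "nadh_flux": nadh_flux,
            "nadph_flux": nadph_flux,
            "prefers_nadh": nadh_flux > nadph_flux,
            "oxidoreductive_active": oxido,
        }
    )


def summarize_table(summaries: dict[str, PhenotypeSummary]) -> pd.DataFrame:
    """Secretion-percentage table: one row per watchlist exchange, one column
    per condition (scenario name).  Missing scenarios appear as NaN columns.
    """
    if not summaries:
        return pd.DataFrame()
    watchlists = [tuple(s.secretion_percent) for s in summaries.values()]
    if len(set(watchlists)) != 1:
        raise ValueError("summaries use different secretion watchlists")
    table = pd.DataFrame(
        {name: s.secretion_percent for name, s in summaries.items()}
    )
    table.index.name = "exchange"
    return table
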