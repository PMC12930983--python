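"""Core data model for constraint-based metabolic networks.

A :class:`MetabolicModel` holds the stoichiometric matrix S (metabolites x
reactions, negative coefficients for substrates, positive for products), flux
bounds in mmol·gDW⁻¹·h⁻¹, Boolean gene rules per reaction, compartments and
optional elemental formulas.  Exchange reactions are boundary pseudo-reactions
with exactly one nonzero stoichiometric coefficient; by convention a negative
exchange flux is uptake and a positive one secretion.

Compartments are tagged on metabolite identifiers as a square-bracket suffix,
e.g. ``"galactose[c]"``; this is an internal convention only and is never
required of input files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .rules import GeneRuleError, evaluate_gene_rule, rule_genes, rule_is_valid

__all__ = [
    "MetabolicModel",
    "ValidationReport",
    "ModelIntegrityError",
    "model_stats",
    "validate",
    "parse_formula",
    "split_compartment",
    "DEFAULT_BOUND",
]

DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class ModelIntegrityError(ValueError):
    """Raised when a model violates a structural invariant."""


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula like ``C6H12O6`` into element counts."""
    if not formula:
        return {}
    counts: dict[str, float] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, number = match.groups()
        counts[element] = counts.get(element, 0.0) + (float(number) if number else 1.0)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def split_compartment(metabolite_id: str) -> tuple[str, str | None]:
    """Split ``"glc[c]"`` into ``("glc", "c")``; no suffix gives ``(id, None)``."""
    if metabolite_id.endswith("]") and "[" in metabolite_id:
        base, _, comp = metabolite_id[:-1].rpartition("[")
        return base, comp
    return metabolite_id, None


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) metabolic model.

    Attributes
    ----------
    metabolite_ids, reaction_ids, gene_ids
        Unique identifiers; metabolite ids carry a ``[compartment]`` suffix.
    stoichiometry
        Sparse S matrix, shape ``(n_metabolites, n_reactions)``.
    lower_bounds, upper_bounds
        Per-reaction flux bounds (mmol·gDW⁻¹·h⁻¹).
    gene_rules
        Per-reaction Boolean expression over gene ids ('' = spontaneous).
    compartments
        Mapping compartment id -> descriptive name.
    biomass_reaction_id
        Identifier of the growth pseudoreaction, if any.
    metabolite_formulas
        Optional elemental composition per metabolite id.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    gene_ids: list[str]
    stoichiometry: sp.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    gene_rules: list[str]
    compartments: dict[str, str] = field(default_factory=dict)
    biomass_reaction_id: str | None = None
    metabolite_formulas: dict[str, str] = field(default_factory=dict)
    reaction_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stoichiometry = sp.csc_matrix(self.stoichiometry)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self._check_integrity()

    # -- integrity ---------------------------------------------------------
    def _check_integrity(self) -> None:
        n_m, n_r = self.stoichiometry.shape
        if len(self.metabolite_ids) != n_m or len(self.reaction_ids) != n_r:
            raise ModelIntegrityError("id lists do not match S dimensions")
        for name, ids in (
            ("metabolite", self.metabolite_ids),
            ("reaction", self.reaction_ids),
            ("gene", self.gene_ids),
        ):
            if len(set(ids)) != len(ids):
                seen, dup = set(), None
                for i in ids:
                    if i in seen:
                        dup = i
                        break
                    seen.add(i)
                raise ModelIntegrityError(f"duplicated {name} id {dup!r}")
        if len(self.gene_rules) != n_r:
            raise ModelIntegrityError("gene_rules length does not match reactions")
        if self.lower_bounds.shape != (n_r,) or self.upper_bounds.shape != (n_r,):
            raise ModelIntegrityError("bounds length does not match reactions")
        if np.any(self.lower_bounds > self.upper_bounds):
            bad = self.reaction_ids[int(np.argmax(self.lower_bounds > self.upper_bounds))]
            raise ModelIntegrityError(f"lower bound exceeds upper bound for {bad!r}")
        if n_r and self.stoichiometry.getnnz(axis=0).min() < 1:
            empty = self.reaction_ids[int(self.stoichiometry.getnnz(axis=0).argmin())]
            raise ModelIntegrityError(f"reaction {empty!r} has no stoichiometry")
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in self.reaction_ids:
            raise ModelIntegrityError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        known = set(self.gene_ids)
        for rxn, rule in zip(self.reaction_ids, self.gene_rules):
            if rule and rule_is_valid(rule):
                missing = rule_genes(rule) - known
                if missing:
                    raise ModelIntegrityError(
                        f"rule of {rxn!r} references unknown gene(s) {sorted(missing)}"
                    )

    # -- derived views -----------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def metabolite_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.metabolite_ids)}

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r: j for j, r in enumerate(self.reaction_ids)}

    @property
    def exchange_reaction_ids(self) -> list[str]:
        """Reactions with exactly one nonzero stoichiometric coefficient."""
        nnz = self.stoichiometry.getnnz(axis=0)
        return [r for r, n in zip(self.reaction_ids, nnz) if n == 1]

    def reaction_stoichiometry(self, reaction_id: str) -> dict[str, float]:
        j = self.reaction_index[reaction_id]
        col = self.stoichiometry.getcol(j).tocoo()
        return {self.metabolite_ids[i]: v for i, v in zip(col.row, col.data)}

    def rg_matrix(self) -> sp.csr_matrix:
        """Binary reaction-gene matrix RG (reactions x genes).

        Entry (j, k) is 1 exactly when gene k appears in reaction j's rule.
        """
        gene_index = {g: k for k, g in enumerate(self.gene_ids)}
        rows, cols = [], []
        for j, rule in enumerate(self.gene_rules):
            for g in rule_genes(rule):
                rows.append(j)
                cols.append(gene_index[g])
        data = np.ones(len(rows))
        return sp.csr_matrix(
            (data, (rows, cols)), shape=(self.n_reactions, self.n_genes)
        )

    def metabolite_compartment(self, metabolite_id: str) -> str | None:
        return split_compartment(metabolite_id)[1]

    # -- editing -----------------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            gene_ids=list(self.gene_ids),
            stoichiometry=self.stoichiometry.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            gene_rules=list(self.gene_rules),
            compartments=dict(self.compartments),
            metabolite_formulas=dict(self.metabolite_formulas),
            reaction_names=dict(self.reaction_names),
        )

    def with_bounds(self, bounds: dict[str, tuple[float, float]]) -> "MetabolicModel":
        """Return a copy with the given per-reaction (lower, upper) bounds."""
        new = self.copy()
        idx = new.reaction_index
        for rxn, (lo, hi) in bounds.items():
            j = idx[rxn]
            new.lower_bounds[j] = lo
            new.upper_bounds[j] = hi
        new._check_integrity()
        return new


@dataclass
class ValidationReport:
    """Structural and elemental audit of a model (report, never raises)."""

    unbalanced_reactions: list[tuple[str, str, float]]
    orphan_metabolites: list[str]
    dead_end_metabolites: list[str]
    rule_errors: list[tuple[str, str]]
    stats: dict[str, int]

    @property
    def is_clean(self) -> bool:
        return not (self.unbalanced_reactions or self.rule_errors)

    def to_frame(self):
        import pandas as pd

        rows = [("unbalanced", r, f"{el}:{imb:g}") for r, el, imb in self.unbalanced_reactions]
        rows += [("orphan_metabolite", m, "") for m in self.orphan_metabolites]
        rows += [("dead_end_metabolite", m, "") for m in self.dead_end_metabolites]
        rows += [("rule_error", r, msg) for r, msg in self.rule_errors]
        return pd.DataFrame(rows, columns=["issue", "id", "detail"])


def model_stats(model: MetabolicModel) -> dict[str, int]:
    """Counts of unique genes, reactions, metabolites and compartments."""
    comps = set(model.compartments)
    for m in model.metabolite_ids:
        comp = split_compartment(m)[1]
        if comp is not None:
            comps.add(comp)
    return {
        "genes": model.n_genes,
        "reactions": model.n_reactions,
        "metabolites": model.n_metabolites,
        "compartments": len(comps),
    }


def validate(
    model: MetabolicModel,
    elements: tuple[str, ...] = ("C", "H", "O", "N", "P"),
    tol: float = 1e-6,
) -> ValidationReport:
    """Audit a model: elemental balance, orphans, dead ends, rule syntax.

    Elemental balance is checked only for non-exchange reactions in which
    every participating metabolite carries a formula; exchange reactions are
    boundary pseudo-reactions and exempt by construction.
    """
    exchanges = set(model.exchange_reaction_ids)
    formulas = {
        m: parse_formula(f) for m, f in model.metabolite_formulas.items() if f
    }

    unbalanced: list[tuple[str, str, float]] = []
    for rxn in model.reaction_ids:
        if rxn in exchanges:
            continue
        stoich = model.reaction_stoichiometry(rxn)
        if not all(m in formulas for m in stoich):
            continue
        for element in elements:
            imbalance = sum(
                coeff * formulas[m].get(element, 0.0) for m, coeff in stoich.items()
            )
            if abs(imbalance) > tol:
                unbalanced.append((rxn, element, imbalance))

    nnz_per_met = model.stoichiometry.getnnz(axis=1)
    orphans = [m for m, n in zip(model.metabolite_ids, nnz_per_met) if n == 0]

    # dead ends: metabolites only produced or only consumed by non-exchange
    # reactions, considering reversibility
    dead_ends: list[str] = []
    coo = model.stoichiometry.tocoo()
    exch_cols = {model.reaction_index[r] for r in exchanges}
    producible = np.zeros(model.n_metabolites, dtype=bool)
    consumable = np.zeros(model.n_metabolites, dtype=bool)
    for i, j, v in zip(coo.row, coo.col, coo.data):
        if j in exch_cols:
            continue
        fwd = model.upper_bounds[j] > 0
        rev = model.lower_bounds[j] < 0
        if (v > 0 and fwd) or (v < 0 and rev):
            producible[i] = True
        if (v < 0 and fwd) or (v > 0 and rev):
            consumable[i] = True
    for i, m in enumerate(model.metabolite_ids):
        if nnz_per_met[i] and producible[i] != consumable[i]:
            dead_ends.append(m)

    rule_errors: list[tuple[str, str]] = []
    for rxn, rule in zip(model.reaction_ids, model.gene_rules):
        try:
            evaluate_gene_rule(rule)
        except GeneRuleError as exc:
            rule_errors.append((rxn, str(exc)))

    return ValidationReport(
        unbalanced_reactions=unbalanced,
        orphan_metabolites=orphans,
        dead_end_metabolites=dead_ends,
        rule_errors=rule_errors,
        stats=model_stats(model),
    )
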