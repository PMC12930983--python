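"""Programmatic model curation: reaction/exchange additions, bound edits,
cofactor-variant encoding and gene deletions.

Each edit is a :class:`CurationAction` carrying its provenance string, so a
curated model can be reproduced by replaying the ordered action log on the
draft model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .model import DEFAULT_BOUND, MetabolicModel, ModelIntegrityError
from .rules import evaluate_gene_rule, rule_genes

__all__ = [
    "CurationAction",
    "apply_curation",
    "apply_action",
    "add_reaction",
    "delete_genes",
    "encode_cofactor_variants",
    "save_actions",
    "load_actions",
]


@dataclass(frozen=True)
class CurationAction:
    """One invertible model edit.

    ``kind`` is one of ``add_reaction``, ``add_exchange``, ``set_bounds``,
    ``set_rule`` or ``delete_gene``; ``payload`` holds the edit content and
    ``provenance`` a free-text citation for the change.
    """

    kind: str
    payload: dict
    provenance: str = ""

    _KINDS = ("add_reaction", "add_exchange", "set_bounds", "set_rule", "delete_gene")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown action kind {self.kind!r}")


def add_reaction(
    model: MetabolicModel,
    reaction_id: str,
    stoichiometry: dict[str, float],
    lower_bound: float = 0.0,
    upper_bound: float = DEFAULT_BOUND,
    gene_rule: str = "",
    name: str = "",
    formulas: dict[str, str] | None = None,
) -> MetabolicModel:
    """Return a copy of the model with one reaction (and any new metabolites
    or genes it references) appended."""
    if reaction_id in model.reaction_index:
        raise ModelIntegrityError(f"duplicate reaction id {reaction_id!r}")
    new = model.copy()
    met_index = dict(new.metabolite_index)
    for met in stoichiometry:
        if met not in met_index:
            met_index[met] = len(new.metabolite_ids)
            new.metabolite_ids.append(met)
    rows = [met_index[m] for m in stoichiometry]
    vals = [float(v) for v in stoichiometry.values()]
    col = sp.csc_matrix(
        (vals, (rows, [0] * len(rows))), shape=(len(new.metabolite_ids), 1)
    )
    S = sp.vstack(
        [new.stoichiometry,
         sp.csc_matrix((len(new.metabolite_ids) - new.stoichiometry.shape[0],
                        new.stoichiometry.shape[1]))]
    )
    new.stoichiometry = sp.hstack([S, col]).tocsc()
    new.reaction_ids.append(reaction_id)
    new.lower_bounds = np.append(new.lower_bounds, lower_bound)
    new.upper_bounds = np.append(new.upper_bounds, upper_bound)
    new.gene_rules.append(gene_rule)
    if name:
        new.reaction_names[reaction_id] = name
    for g in sorted(rule_genes(gene_rule) - set(new.gene_ids)):
        new.gene_ids.append(g)
    if formulas:
        new.metabolite_formulas.update(formulas)
    new._check_integrity()
    return new


def apply_action(model: MetabolicModel, action: CurationAction) -> MetabolicModel:
    p = action.payload
    if action.kind in ("add_reaction", "add_exchange"):
        new = add_reaction(
            model,
            reaction_id=p["id"],
            stoichiometry=p["stoichiometry"],
            lower_bound=p.get("lower_bound", 0.0),
            upper_bound=p.get("upper_bound", DEFAULT_BOUND),
            gene_rule=p.get("gene_rule", ""),
            name=p.get("name", ""),
            formulas=p.get("formulas"),
        )
        if action.kind == "add_exchange" and p["id"] not in new.exchange_reaction_ids:
            raise ModelIntegrityError(
                f"{p['id']!r} is not an exchange (needs exactly one metabolite)"
            )
        return new
    if action.kind == "set_bounds":
        return model.with_bounds({p["id"]: (p["lower_bound"], p["upper_bound"])})
    if action.kind == "set_rule":
        new = model.copy()
        j = new.reaction_index[p["id"]]
        new.gene_rules[j] = p["gene_rule"]
        for g in sorted(rule_genes(p["gene_rule"]) - set(new.gene_ids)):
            new.gene_ids.append(g)
        new._check_integrity()
        return new
    if action.kind == "delete_gene":
        return delete_genes(model, {p["gene"]})
    raise ValueError(f"unknown action kind {action.kind!r}")  # pragma: no cover


def apply_curation(
    model: MetabolicModel, actions: list[CurationAction]
) -> MetabolicModel:
    """Apply an ordered list of curation actions."""
    for action in actions:
        model = apply_action(model, action)
    return model


def delete_genes(model: MetabolicModel, genes: set[str]) -> MetabolicModel:
    """Knock out genes: reactions whose rule evaluates False get bounds (0, 0).

    Reactions without a gene rule, and reactions whose rule stays True (e.g.
    an isoenzyme survives an ``or``), are untouched.  Deleting more genes can
    only grow the blocked set, never relax bounds.
    """
    unknown = set(genes) - set(model.gene_ids)
    if unknown:
        raise KeyError(f"unknown gene(s) {sorted(unknown)}")
    new = model.copy()
    for j, rule in enumerate(new.gene_rules):
        if rule and not evaluate_gene_rule(rule, genes):
            new.lower_bounds[j] = 0.0
            new.upper_bounds[j] = 0.0
    return new


def encode_cofactor_variants(
    model: MetabolicModel,
    reaction_id: str,
    template: dict[str, float],
    cofactor_pairs: list[tuple[str, str]],
    gene_rule: str = "",
    lower_bound: float = 0.0,
    upper_bound: float = DEFAULT_BOUND,
    name: str = "",
) -> tuple[MetabolicModel, list[str]]:
    """Add one reaction per redox cofactor from a cofactor-free template.

    ``cofactor_pairs`` lists (reduced, oxidized) metabolite ids, e.g.
    ``[("nadh[c]", "nad[c]"), ("nadph[c]", "nadp[c]")]``; each variant
    consumes one reduced cofactor plus a proton and releases the oxidized
    form, shares the gene rule, and is independently boundable.
    """
    if not cofactor_pairs:
        raise ValueError("cofactor list must not be empty")
    for reduced, oxidized in cofactor_pairs:
        for met in (reduced, oxidized):
            if met not in model.metabolite_index:
                raise KeyError(f"unknown cofactor metabolite {met!r}")
    added = []
    for reduced, oxidized in cofactor_pairs:
        tag = reduced.split("[")[0].upper()
        rid = f"{reaction_id}_{tag}"
        stoich = dict(template)
        stoich[reduced] = stoich.get(reduced, 0.0) - 1.0
        stoich[oxidized] = stoich.get(oxidized, 0.0) + 1.0
        model = add_reaction(
            model, rid, stoich, lower_bound, upper_bound, gene_rule,
            name=f"{name} ({tag})" if name else "",
        )
        added.append(rid)
    return model, added


def save_actions(actions: list[CurationAction], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [{"kind": a.kind, "payload": a.payload, "provenance": a.provenance}
             for a in actions],
            fh, indent=1,
        )
        fh.write("\n")


def load_actions(path: str | Path) -> list[CurationAction]:
    with open(path) as fh:
        raw = json.load(fh)
    return [CurationAction(r["kind"], r["payload"], r.get("provenance", "")) for r in raw]
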