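"""Readers and writers: native JSON dialect and SBML Level 3 + FBC.

The JSON dialect stores metabolites (id, compartment, formula), reactions
(id, stoichiometry mapping, bounds, gene rule), genes and compartments; it is
the package's canonical round-trip format.  SBML with the FBC extension is
supported for interchange with published genome-scale models; flux bounds are
taken from FBC parameters when present and otherwise default to the
±1000 mmol·gDW⁻¹·h⁻¹ convention ((0, 1000) when the reaction is declared
irreversible).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .model import DEFAULT_BOUND, MetabolicModel, ModelIntegrityError, split_compartment

__all__ = ["read_model", "write_model", "read_json", "write_json", "read_sbml", "write_sbml", "ModelParseError"]


class ModelParseError(ValueError):
    """Raised when a model file is malformed; names the offending element."""


def read_model(path: str | Path) -> MetabolicModel:
    """Read a model from SBML (``.xml``/``.sbml``) or native JSON."""
    path = Path(path)
    if path.suffix.lower() in {".xml", ".sbml"}:
        return read_sbml(path)
    return read_json(path)


def write_model(model: MetabolicModel, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".xml", ".sbml"}:
        write_sbml(model, path)
    else:
        write_json(model, path)


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    reactions = []
    for j, rxn in enumerate(model.reaction_ids):
        reactions.append(
            {
                "id": rxn,
                "stoichiometry": model.reaction_stoichiometry(rxn),
                "lower_bound": float(model.lower_bounds[j]),
                "upper_bound": float(model.upper_bounds[j]),
                "gene_rule": model.gene_rules[j],
                **({"name": model.reaction_names[rxn]} if rxn in model.reaction_names else {}),
            }
        )
    metabolites = []
    for m in model.metabolite_ids:
        entry: dict = {"id": m}
        comp = split_compartment(m)[1]
        if comp is not None:
            entry["compartment"] = comp
        if m in model.metabolite_formulas:
            entry["formula"] = model.metabolite_formulas[m]
        metabolites.append(entry)
    return {
        "metabolites": metabolites,
        "reactions": reactions,
        "genes": list(model.gene_ids),
        "compartments": dict(model.compartments),
        "biomass_reaction_id": model.biomass_reaction_id,
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    try:
        met_entries = data["metabolites"]
        rxn_entries = data["reactions"]
    except KeyError as exc:
        raise ModelParseError(f"missing top-level section {exc}") from exc

    metabolite_ids = [m["id"] for m in met_entries]
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    if len(met_index) != len(metabolite_ids):
        raise ModelIntegrityError("duplicated metabolite id in file")
    formulas = {m["id"]: m["formula"] for m in met_entries if m.get("formula")}

    reaction_ids, rules, lbs, ubs = [], [], [], []
    names: dict[str, str] = {}
    rows, cols, vals = [], [], []
    for j, r in enumerate(rxn_entries):
        try:
            rid = r["id"]
            stoich = r["stoichiometry"]
        except KeyError as exc:
            raise ModelParseError(f"reaction entry {j} missing field {exc}") from exc
        reaction_ids.append(rid)
        rules.append(r.get("gene_rule", "") or "")
        lbs.append(r.get("lower_bound", -DEFAULT_BOUND))
        ubs.append(r.get("upper_bound", DEFAULT_BOUND))
        if "name" in r:
            names[rid] = r["name"]
        for met, coeff in stoich.items():
            if met not in met_index:
                raise ModelParseError(
                    f"reaction {rid!r} references undeclared metabolite {met!r}"
                )
            rows.append(met_index[met])
            cols.append(j)
            vals.append(float(coeff))

    S = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(metabolite_ids), len(reaction_ids))
    )
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        gene_ids=list(data.get("genes", [])),
        stoichiometry=S,
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        gene_rules=rules,
        compartments=dict(data.get("compartments", {})),
        biomass_reaction_id=data.get("biomass_reaction_id"),
        metabolite_formulas=formulas,
        reaction_names=names,
    )


def read_json(path: str | Path) -> MetabolicModel:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"invalid JSON in {path}: {exc}") from exc
    return _model_from_dict(data)


def write_json(model: MetabolicModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SBML L3 + FBC
# ---------------------------------------------------------------------------

_SBML_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sbml_id(raw: str) -> str:
    sid = _SBML_BAD.sub("_", raw)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "_" + sid
    return sid


def read_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML Level 3 document, using the FBC extension when present."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None or doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        detail = first.getMessage().strip() if first is not None else "no model element"
        raise ModelParseError(f"cannot read SBML from {path}: {detail}")
    sbml_model = doc.getModel()
    fbc = sbml_model.getPlugin("fbc")

    compartments = {
        c.getId(): c.getName() or c.getId()
        for c in (sbml_model.getCompartment(i) for i in range(sbml_model.getNumCompartments()))
    }

    metabolite_ids, formulas = [], {}
    species_to_id: dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        spe = sbml_model.getSpecies(i)
        raw = spe.getId()
        base = raw[2:] if raw.startswith("M_") else raw
        comp = spe.getCompartment()
        # strip a trailing compartment suffix duplicated from the attribute
        if comp and base.endswith(f"_{comp}"):
            base = base[: -(len(comp) + 1)]
        mid = f"{base}[{comp}]" if comp else base
        if mid in species_to_id.values():
            raise ModelIntegrityError(f"duplicated species id {raw!r}")
        species_to_id[raw] = mid
        metabolite_ids.append(mid)
        sp_fbc = spe.getPlugin("fbc")
        if sp_fbc is not None and sp_fbc.isSetChemicalFormula():
            formulas[mid] = sp_fbc.getChemicalFormula()

    gene_ids: list[str] = []
    gp_label: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            label = gp.getLabel() or gp.getId()
            gp_label[gp.getId()] = label
            gene_ids.append(label)

    def association_to_rule(assoc) -> str:
        import libsbml as _ls

        if assoc is None:
            return ""
        if isinstance(assoc, _ls.GeneProductRef):
            return gp_label.get(assoc.getGeneProduct(), assoc.getGeneProduct())
        if isinstance(assoc, _ls.FbcAnd):
            parts = [association_to_rule(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
            return "(" + " and ".join(parts) + ")"
        if isinstance(assoc, _ls.FbcOr):
            parts = [association_to_rule(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
            return "(" + " or ".join(parts) + ")"
        raise ModelParseError(f"unsupported gene association element {assoc}")

    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    reaction_ids, rules, lbs, ubs = [], [], [], []
    names: dict[str, str] = {}
    rows, cols, vals = [], [], []
    for j in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(j)
        raw = rxn.getId()
        rid = raw[2:] if raw.startswith("R_") else raw
        reaction_ids.append(rid)
        if rxn.getName():
            names[rid] = rxn.getName()

        seen: dict[str, float] = {}
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            if ref.getSpecies() not in species_to_id:
                raise ModelParseError(
                    f"reaction {raw!r} references undeclared species {ref.getSpecies()!r}"
                )
            mid = species_to_id[ref.getSpecies()]
            seen[mid] = seen.get(mid, 0.0) - (ref.getStoichiometry() or 1.0)
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            if ref.getSpecies() not in species_to_id:
                raise ModelParseError(
                    f"reaction {raw!r} references undeclared species {ref.getSpecies()!r}"
                )
            mid = species_to_id[ref.getSpecies()]
            seen[mid] = seen.get(mid, 0.0) + (ref.getStoichiometry() or 1.0)
        for mid, coeff in seen.items():
            if coeff != 0.0:
                rows.append(met_index[mid])
                cols.append(len(reaction_ids) - 1)
                vals.append(coeff)

        r_fbc = rxn.getPlugin("fbc")
        lo, hi = None, None
        if r_fbc is not None:
            if r_fbc.isSetLowerFluxBound():
                par = sbml_model.getParameter(r_fbc.getLowerFluxBound())
                lo = par.getValue() if par is not None else None
            if r_fbc.isSetUpperFluxBound():
                par = sbml_model.getParameter(r_fbc.getUpperFluxBound())
                hi = par.getValue() if par is not None else None
        if lo is None:
            lo = -DEFAULT_BOUND if rxn.getReversible() else 0.0
        if hi is None:
            hi = DEFAULT_BOUND
        lo = max(lo, -DEFAULT_BOUND) if np.isfinite(lo) else -DEFAULT_BOUND
        hi = min(hi, DEFAULT_BOUND) if np.isfinite(hi) else DEFAULT_BOUND
        lbs.append(lo)
        ubs.append(hi)
        rules.append(association_to_rule(
            r_fbc.getGeneProductAssociation().getAssociation()
            if r_fbc is not None and r_fbc.getGeneProductAssociation() is not None
            else None
        ))

    # genes referenced only through rules (no FBC gene product list)
    from .rules import rule_genes, rule_is_valid

    known = set(gene_ids)
    for rule in rules:
        if rule and rule_is_valid(rule):
            for g in sorted(rule_genes(rule) - known):
                gene_ids.append(g)
                known.add(g)

    S = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(metabolite_ids), len(reaction_ids))
    )
    biomass = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getObjective(0)
        if obj.getNumFluxObjectives() > 0:
            raw = obj.getFluxObjective(0).getReaction()
            biomass = raw[2:] if raw.startswith("R_") else raw
            if biomass not in reaction_ids:
                biomass = None
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        gene_ids=gene_ids,
        stoichiometry=S,
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        gene_rules=rules,
        compartments=compartments,
        biomass_reaction_id=biomass,
        metabolite_formulas=formulas,
        reaction_names=names,
    )


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as SBML Level 3 Version 1 with FBC version 2."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId("model")
    m_fbc = sbml_model.getPlugin("fbc")
    m_fbc.setStrict(False)

    comps = dict(model.compartments)
    for m in model.metabolite_ids:
        comp = split_compartment(m)[1]
        if comp is not None and comp not in comps:
            comps[comp] = comp
    if not comps:
        comps = {"c": "cytosol"}
    for cid, cname in comps.items():
        comp = sbml_model.createCompartment()
        comp.setId(_sbml_id(cid))
        comp.setName(cname)
        comp.setConstant(True)

    species_id: dict[str, str] = {}
    for m in model.metabolite_ids:
        base, comp = split_compartment(m)
        comp = comp or next(iter(comps))
        sid = f"M_{_sbml_id(base)}_{_sbml_id(comp)}"
        species_id[m] = sid
        spe = sbml_model.createSpecies()
        spe.setId(sid)
        spe.setName(base)
        spe.setCompartment(_sbml_id(comp))
        spe.setHasOnlySubstanceUnits(False)
        spe.setBoundaryCondition(False)
        spe.setConstant(False)
        if m in model.metabolite_formulas:
            spe.getPlugin("fbc").setChemicalFormula(model.metabolite_formulas[m])

    gene_sid: dict[str, str] = {}
    for g in model.gene_ids:
        gp = m_fbc.createGeneProduct()
        sid = f"G_{_sbml_id(g)}"
        gene_sid[g] = sid
        gp.setId(sid)
        gp.setLabel(g)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    def rule_to_infix(rule: str) -> str:
        # substitute gene ids with their SBML ids, preserving structure
        tokens = re.findall(r"\(|\)|[^\s()]+", rule)
        out = []
        for t in tokens:
            if t in "()" or t.lower() in {"and", "or"}:
                out.append(t.lower())
            else:
                out.append(gene_sid[t])
        return " ".join(out)

    for j, rid in enumerate(model.reaction_ids):
        rxn = sbml_model.createReaction()
        rxn.setId(f"R_{_sbml_id(rid)}")
        if rid in model.reaction_names:
            rxn.setName(model.reaction_names[rid])
        rxn.setReversible(bool(model.lower_bounds[j] < 0))
        rxn.setFast(False)
        for met, coeff in model.reaction_stoichiometry(rid).items():
            ref = rxn.createReactant() if coeff < 0 else rxn.createProduct()
            ref.setSpecies(species_id[met])
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        r_fbc = rxn.getPlugin("fbc")
        r_fbc.setLowerFluxBound(bound_param(float(model.lower_bounds[j])))
        r_fbc.setUpperFluxBound(bound_param(float(model.upper_bounds[j])))
        rule = model.gene_rules[j]
        if rule:
            gpa = r_fbc.createGeneProductAssociation()
            # match declared gene products by id; never auto-create new ones
            gpa.setAssociation(rule_to_infix(rule), True, False)

    if model.biomass_reaction_id is not None:
        obj = m_fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        m_fbc.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction(f"R_{_sbml_id(model.biomass_reaction_id)}")
        fo.setCoefficient(1.0)

    libsbml.writeSBMLToFile(doc, str(path))
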