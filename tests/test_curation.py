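"""Curation actions: additions, gene deletions, cofactor variants."""

import networkx as nx
import numpy as np
import pytest

from oxidogem.curation import (
    CurationAction,
    apply_curation,
    delete_genes,
    encode_cofactor_variants,
    load_actions,
    save_actions,
)
from oxidogem.model import ModelIntegrityError
from oxidogem.synth import GAL_CLUSTER, ToyModelSpec, build_toy_model


def test_empty_action_list_is_identity(toy_model):
    same = apply_curation(toy_model, [])
    assert same.reaction_ids == toy_model.reaction_ids
    assert np.allclose(same.lower_bounds, toy_model.lower_bounds)


def test_add_exchange_grows_exchange_set(toy_model):
    before = len(toy_model.exchange_reaction_ids)
    action = CurationAction(
        "add_exchange",
        {"id": "EX_tag", "stoichiometry": {"tagatose[e]": -1.0}, "lower_bound": 0.0},
        provenance="secreted product observed extracellularly",
    )
    after = apply_curation(toy_model, [action])
    assert len(after.exchange_reaction_ids) == before + 1
    assert "EX_tag" in after.exchange_reaction_ids


def test_duplicate_reaction_id_rejected(toy_model):
    action = CurationAction("add_reaction", {"id": "GAL1", "stoichiometry": {"gal[c]": -1}})
    with pytest.raises(ModelIntegrityError):
        apply_curation(toy_model, [action])


def test_action_log_round_trip(toy_model, tmp_path):
    actions = [
        CurationAction("set_bounds", {"id": "GAL1", "lower_bound": 0.0, "upper_bound": 5.0}, "cap"),
        CurationAction("delete_gene", {"gene": "LXR4"}, "mutant"),
    ]
    save_actions(actions, tmp_path / "log.json")
    replayed = apply_curation(toy_model, load_actions(tmp_path / "log.json"))
    direct = apply_curation(toy_model, actions)
    assert np.allclose(replayed.lower_bounds, direct.lower_bounds)
    assert np.allclose(replayed.upper_bounds, direct.upper_bounds)


def _reachable(model, source, target):
    """Graph oracle: directed metabolite reachability over S (forward bounds)."""
    g = nx.DiGraph()
    for rxn in model.reaction_ids:
        j = model.reaction_index[rxn]
        stoich = model.reaction_stoichiometry(rxn)
        subs = [m for m, c in stoich.items() if c < 0]
        prods = [m for m, c in stoich.items() if c > 0]
        if model.upper_bounds[j] > 0:
            g.add_edges_from((s, p) for s in subs for p in prods)
        if model.lower_bounds[j] < 0:
            g.add_edges_from((p, s) for s in subs for p in prods)
    return g.has_node(source) and g.has_node(target) and nx.has_path(g, source, target)


def test_hexulose_reductase_completes_pathway():
    """Adding the L-xylo-3-hexulose reductase step stoichiometrically connects
    beta-D-galactose to fructose-6-phosphate through the oxidoreductive route."""
    base = build_toy_model()
    # remove the LXR4 step to emulate the draft model's gap
    gapped = base.with_bounds({"LXR4": (0.0, 0.0)})
    # reachability oracle must respect the closed reaction: rebuild without it
    import scipy.sparse as sp

    keep = [r for r in base.reaction_ids if r != "LXR4"]
    cols = [base.reaction_index[r] for r in keep]
    from dataclasses import replace

    draft = replace(
        base,
        reaction_ids=keep,
        stoichiometry=base.stoichiometry[:, cols],
        lower_bounds=base.lower_bounds[cols],
        upper_bounds=base.upper_bounds[cols],
        gene_rules=[base.gene_rules[j] for j in cols],
    )
    assert not _reachable(draft, "xhl[c]", "f6p[c]")
    cured = apply_curation(
        draft,
        [CurationAction(
            "add_reaction",
            {
                "id": "LXR4",
                "stoichiometry": {"xhl[c]": -1, "nadph[c]": -1, "h[c]": -1,
                                  "sbt[c]": 1, "nadp[c]": 1},
                "gene_rule": "LXR4",
            },
            provenance="ortholog-predicted hexulose reductase",
        )],
    )
    assert _reachable(cured, "gal[c]", "f6p[c]")
    assert _reachable(cured, "xhl[c]", "f6p[c]")


class TestDeleteGenes:
    def test_gal_cluster_deletion_blocks_leloir(self, toy_model):
        mutant = delete_genes(toy_model, set(GAL_CLUSTER))
        for rxn in ("GAL1", "GAL7", "GAL10"):
            j = mutant.reaction_index[rxn]
            assert mutant.lower_bounds[j] == 0.0 and mutant.upper_bounds[j] == 0.0

    def test_single_gene_deletion_blocks_only_its_reaction(self, toy_model):
        mutant = delete_genes(toy_model, {"SER2"})
        j = mutant.reaction_index["SER_SYN"]
        assert mutant.upper_bounds[j] == 0.0
        untouched = [r for r in mutant.reaction_ids if r != "SER_SYN"]
        for r in untouched:
            k = mutant.reaction_index[r]
            assert mutant.upper_bounds[k] == toy_model.upper_bounds[k]

    def test_gene_absent_from_all_rules_changes_nothing(self, toy_model):
        padded = toy_model.copy()
        padded.gene_ids.append("ORF_UNUSED")
        mutant = delete_genes(padded, {"ORF_UNUSED"})
        assert np.allclose(mutant.lower_bounds, toy_model.lower_bounds)
        assert np.allclose(mutant.upper_bounds, toy_model.upper_bounds)

    def test_isoenzyme_semantics(self, toy_model):
        j = toy_model.reaction_index["SDH_SRB"]  # rule: Seq_5357 or Seq_2923
        one = delete_genes(toy_model, {"Seq_5357"})
        assert one.upper_bounds[j] > 0
        both = delete_genes(toy_model, {"Seq_5357", "Seq_2923"})
        assert both.upper_bounds[j] == 0.0

    def test_unknown_gene_raises(self, toy_model):
        with pytest.raises(KeyError):
            delete_genes(toy_model, {"NOT_A_GENE"})

    def test_blocked_set_grows_monotonically(self, toy_model):
        """Deletion never relaxes bounds; more deletions block a superset."""
        small = delete_genes(toy_model, {"XYL1_2"})
        large = delete_genes(toy_model, {"XYL1_2", "LAD1", "COX1"})
        blocked_small = set(np.flatnonzero(small.upper_bounds == 0))
        blocked_large = set(np.flatnonzero(large.upper_bounds == 0))
        assert blocked_small <= blocked_large
        assert np.all(small.upper_bounds <= toy_model.upper_bounds)
        assert np.all(small.lower_bounds >= np.minimum(toy_model.lower_bounds, 0))


class TestCofactorVariants:
    TEMPLATE = {"gal[c]": -1.0, "gol[c]": 1.0}

    def test_dual_cofactor_template(self, toy_model):
        model, added = encode_cofactor_variants(
            toy_model, "AR2", self.TEMPLATE,
            [("nadh[c]", "nad[c]"), ("nadph[c]", "nadp[c]")],
            gene_rule="XYL1_2",
        )
        assert added == ["AR2_NADH", "AR2_NADPH"]
        for rid in added:
            j = model.reaction_index[rid]
            assert model.gene_rules[j] == "XYL1_2"
        assert model.reaction_stoichiometry("AR2_NADH")["nadh[c]"] == -1.0
        assert model.reaction_stoichiometry("AR2_NADPH")["nadph[c]"] == -1.0

    def test_single_cofactor(self, toy_model):
        model, added = encode_cofactor_variants(
            toy_model, "AR1", self.TEMPLATE, [("nadph[c]", "nadp[c]")], gene_rule="XYL1_1"
        )
        assert added == ["AR1_NADPH"]

    def test_empty_cofactor_list_rejected(self, toy_model):
        with pytest.raises(ValueError):
            encode_cofactor_variants(toy_model, "AR0", self.TEMPLATE, [])

    def test_unknown_cofactor_rejected(self, toy_model):
        with pytest.raises(KeyError):
            encode_cofactor_variants(toy_model, "ARX", self.TEMPLATE, [("fadh2[c]", "fad[c]")])
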