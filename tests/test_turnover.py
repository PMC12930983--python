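"""Metabolite turnover transform and PCA machinery."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from oxidogem.model import MetabolicModel
from oxidogem.sampling import SamplingConfig, SamplingResult, sample
from oxidogem.synth import toy_scenario
from oxidogem.turnover import (
    TurnoverPCA,
    atp_turnover,
    overlay,
    to_turnover,
    top_contributors,
    turnover_vector,
)


def chain_model():
    """A -> B -> C with unit coefficients."""
    return MetabolicModel(
        metabolite_ids=["A[c]", "B[c]", "C[c]"],
        reaction_ids=["r1", "r2"],
        gene_ids=[],
        stoichiometry=sp.csc_matrix(np.array([[-1.0, 0.0], [1.0, -1.0], [0.0, 1.0]])),
        lower_bounds=np.array([0.0, 0.0]),
        upper_bounds=np.array([10.0, 10.0]),
        gene_rules=["", ""],
    )


def test_chain_turnover_values():
    """For A->B->C at flux 2, the interior metabolite turns over at 2 and the
    endpoints at 1 (the tau formula halves the absolute throughput)."""
    m = chain_model()
    tau = turnover_vector(np.array([2.0, 2.0]), m)
    assert tau == pytest.approx([1.0, 2.0, 1.0])


def test_zero_flux_zero_turnover():
    m = chain_model()
    assert turnover_vector(np.zeros(2), m) == pytest.approx([0.0, 0.0, 0.0])


def test_turnover_equals_production_and_consumption(toy_model):
    """At steady state, tau of an interior metabolite equals both its total
    production and total consumption (brute-force sign split of S·v)."""
    res = sample(toy_model, toy_scenario("galactose", "oxygen"),
                 SamplingConfig(n_samples=10, seed=2))
    S = toy_model.stoichiometry.toarray()
    for k in range(res.n_samples):
        v = res.flux_matrix[:, k]
        contrib = S * v  # metabolites x reactions, signed rates
        production = np.where(contrib > 0, contrib, 0).sum(axis=1)
        consumption = -np.where(contrib < 0, contrib, 0).sum(axis=1)
        tau = turnover_vector(v, toy_model)
        assert tau == pytest.approx(production, abs=1e-5)
        assert tau == pytest.approx(consumption, abs=1e-5)


def test_turnover_matrix_shape_and_nonnegativity(toy_model):
    res = sample(toy_model, toy_scenario("galactose", "carbon"),
                 SamplingConfig(n_samples=15, seed=4))
    frame = to_turnover(res, toy_model)
    assert frame.shape[0] == 15
    assert (frame.to_numpy() >= 0).all()
    # boundary metabolites excluded by default
    assert not any(m.endswith("[e]") for m in frame.columns)
    full = to_turnover(res, toy_model, intracellular_only=False)
    assert full.shape[1] == toy_model.n_metabolites


@pytest.fixture(scope="module")
def turnover(toy_model):
    res = sample(toy_model, toy_scenario("galactose", "oxygen"),
                 SamplingConfig(n_samples=80, seed=5))
    return to_turnover(res, toy_model)


class TestTurnoverPCA:
    def test_variance_conserved(self, turnover):
        pca = TurnoverPCA(n_components=10).fit(turnover)
        centered = turnover - turnover.mean(axis=0)
        total = float((centered**2).sum().sum() / (len(turnover) - 1))
        assert pca.explained_variance_.sum() == pytest.approx(total, rel=1e-6)
        assert np.all(np.diff(pca.explained_variance_) <= 1e-9)

    def test_loadings_orthonormal(self, turnover):
        pca = TurnoverPCA(n_components=3).fit(turnover)
        L = pca.loadings_.to_numpy()
        assert L.T @ L == pytest.approx(np.eye(3), abs=1e-8)

    def test_scores_reproduce_transform(self, turnover):
        pca = TurnoverPCA(n_components=2).fit(turnover)
        assert pca.transform(turnover) == pytest.approx(pca.scores_, abs=1e-8)

    def test_duplicated_samples_identical_scores(self, turnover):
        doubled = pd.concat([turnover, turnover.iloc[:5]], ignore_index=True)
        pca = TurnoverPCA(n_components=2).fit(doubled)
        assert pca.scores_[:5] == pytest.approx(pca.scores_[-5:], abs=1e-8)

    def test_permuting_samples_permutes_scores(self, turnover):
        pca = TurnoverPCA(n_components=2).fit(turnover)
        perm = np.random.default_rng(0).permutation(len(turnover))
        permuted = TurnoverPCA(n_components=2).fit(turnover.iloc[perm].reset_index(drop=True))
        assert permuted.scores_ == pytest.approx(pca.scores_[perm], abs=1e-6)
        assert permuted.loadings_.to_numpy() == pytest.approx(
            pca.loadings_.to_numpy(), abs=1e-6
        )

    def test_single_variance_carrier_dominates_pc1(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({
            "big": 100 * rng.standard_normal(200),
            "small1": 0.01 * rng.standard_normal(200),
            "small2": 0.01 * rng.standard_normal(200),
        })
        pca = TurnoverPCA(n_components=2).fit(X)
        assert abs(pca.loadings_.loc["big", "PC1"]) > 0.99

    def test_constant_matrix_rejected(self):
        X = pd.DataFrame(np.ones((10, 4)))
        with pytest.raises(ValueError):
            TurnoverPCA(2).fit(X)

    def test_get_set_params(self):
        pca = TurnoverPCA(n_components=2)
        assert pca.get_params() == {"n_components": 2}
        pca.set_params(n_components=3)
        assert pca.n_components == 3


class TestTopContributors:
    def test_positive_direction_rule(self):
        loadings = pd.DataFrame({"PC1": [1.0, 0.2, 0.05]}, index=["a", "b", "c"])
        assert top_contributors(loadings, 0, "positive") == ["a", "b"]

    def test_all_equal_returns_all(self):
        loadings = pd.DataFrame({"PC1": [0.5, 0.5, 0.5]}, index=list("abc"))
        assert top_contributors(loadings, 0, "positive") == ["a", "b", "c"]

    def test_negative_direction_rule(self):
        loadings = pd.DataFrame({"PC1": [-0.8, -0.05, 0.3]}, index=["a", "b", "c"])
        assert top_contributors(loadings, 0, "negative") == ["a"]
        # an order-of-magnitude smaller but within-threshold loading counts
        borderline = pd.DataFrame({"PC1": [-0.8, -0.09, 0.3]}, index=["a", "b", "c"])
        assert top_contributors(borderline, 0, "negative") == ["a", "b"]

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        col = rng.standard_normal(30)
        base = pd.DataFrame({"PC1": col})
        scaled = pd.DataFrame({"PC1": 7.3 * col})
        for direction in ("positive", "negative"):
            assert top_contributors(base, 0, direction) == top_contributors(scaled, 0, direction)


class TestOverlay:
    def test_overlay_columns_and_normalization(self, toy_model, markers):
        from oxidogem.phenotypes import classify

        res = sample(toy_model, toy_scenario("galactose", "oxygen"),
                     SamplingConfig(n_samples=60, seed=6))
        pca = TurnoverPCA(2).fit(to_turnover(res, toy_model))
        summary = classify(res, markers)
        atp = atp_turnover(res, toy_model)
        table = overlay(pca, summary, atp)
        assert {"PC1", "PC2", "pathway", "atp_turnover_norm"} <= set(table.columns)
        assert table["atp_turnover_norm"].min() == pytest.approx(0.0)
        assert table["atp_turnover_norm"].max() == pytest.approx(1.0)
        # the maximal-ATP sample maps to exactly 1
        assert table["atp_turnover_norm"].iloc[int(np.argmax(atp))] == pytest.approx(1.0)

    def test_ethanol_secretors_separate_in_pc_space(self, toy_model, markers):
        """O2-limited ethanol secretion stratifies the score cloud: a 2-means
        split of (PC1, PC2) has positive silhouette against the labels when
        both classes are present."""
        from sklearn.metrics import silhouette_score

        from oxidogem.phenotypes import classify

        res = sample(toy_model, toy_scenario("galactose", "oxygen"),
                     SamplingConfig(n_samples=150, seed=9))
        pca = TurnoverPCA(2).fit(to_turnover(res, toy_model))
        summary = classify(res, markers)
        labels = summary.per_sample["secreted_EX_gol"].to_numpy()
        if labels.all() or not labels.any():
            labels = summary.per_sample["cofactor"].to_numpy() == "nadh_only"
        assert silhouette_score(pca.scores_, labels) > 0

    def test_ordering_mismatch_rejected(self, toy_model, markers):
        from oxidogem.phenotypes import classify

        res = sample(toy_model, toy_scenario("galactose", "carbon"),
                     SamplingConfig(n_samples=20, seed=1))
        pca = TurnoverPCA(2).fit(to_turnover(res, toy_model))
        summary = classify(res, markers)
        summary.per_sample = summary.per_sample.iloc[:-1]
        with pytest.raises(ValueError):
            overlay(pca, summary)
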