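"""Metabolite turnover (flux-sum) analysis and PCA of sampled distributions.

The turnover of metabolite *i* in a flux distribution *v* is

    tau_i = 1/2 * sum_j |S_ij * v_j|

the total rate at which the metabolite is transformed across all reactions it
partakes in; at steady state it equals both the total production and the
total consumption rate.  Sampled turnover distributions are reduced by
mean-centered PCA (no variable scaling); the metabolites contributing most to
a component are those whose loading is within one order of magnitude of the
extreme loading in the chosen direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .model import MetabolicModel, split_compartment
from .phenotypes import PhenotypeSummary
from .sampling import SamplingResult

__all__ = ["to_turnover", "TurnoverPCA", "top_contributors", "overlay", "atp_turnover"]


def to_turnover(
    result: SamplingResult,
    model: MetabolicModel,
    intracellular_only: bool = True,
    boundary_compartment: str = "e",
) -> pd.DataFrame:
    """Turnover matrix (samples x metabolites) for a sampling result.

    With ``intracellular_only`` metabolites of the boundary compartment are
    dropped, so transport fluxes are not double-counted as extracellular
    turnover.
    """
    if list(result.reaction_ids) != list(model.reaction_ids):
        raise ValueError("sampling result and model have mismatched reactions")
    abs_S = abs(model.stoichiometry)
    tau = 0.5 * (abs_S @ np.abs(result.flux_matrix))  # metabolites x samples
    mets = model.metabolite_ids
    frame = pd.DataFrame(tau.T, columns=mets)
    if intracellular_only:
        keep = [m for m in mets if split_compartment(m)[1] != boundary_compartment]
        frame = frame[keep]
    return frame


def turnover_vector(v: np.ndarray, model: MetabolicModel) -> np.ndarray:
    """tau for a single flux vector, over all metabolites."""
    return 0.5 * np.asarray(abs(model.stoichiometry) @ np.abs(v)).ravel()


class TurnoverPCA:
    """Mean-centered PCA of turnover distributions (scikit-learn style).

    Parameters
    ----------
    n_components : int
        Number of principal components to retain.

    Attributes (after ``fit``)
    --------------------------
    loadings_ : DataFrame, metabolites x components, orthonormal columns,
        each column flipped so its largest-magnitude entry is positive.
    scores_ : ndarray, samples x components.
    explained_variance_ : per-component variance, nonincreasing.
    explained_variance_ratio_ : fractions of total variance.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "TurnoverPCA":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame | np.ndarray, y=None) -> "TurnoverPCA":
        X = pd.DataFrame(X)
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("need at least 2 samples and 2 metabolites")
        if float(X.var(axis=0, ddof=1).sum()) <= 0:
            raise ValueError("turnover matrix is constant; PCA is degenerate")
        n_comp = min(self.n_components, X.shape[0] - 1, X.shape[1])
        self._pca = PCA(n_components=n_comp, svd_solver="full")
        scores = self._pca.fit_transform(X.to_numpy())
        loadings = self._pca.components_.T  # metabolites x components
        # deterministic sign convention
        flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
        flip[flip == 0] = 1.0
        loadings = loadings * flip
        scores = scores * flip
        self.feature_names_in_ = np.asarray(X.columns)
        self.loadings_ = pd.DataFrame(
            loadings, index=X.columns,
            columns=[f"PC{k + 1}" for k in range(loadings.shape[1])],
        )
        self.scores_ = scores
        self.explained_variance_ = self._pca.explained_variance_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        self.mean_ = self._pca.mean_
        return self

    def transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = pd.DataFrame(X)
        centered = X.to_numpy() - self.mean_
        return centered @ self.loadings_.to_numpy()

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_

    def top_contributors(self, component: int = 0, direction: str = "positive") -> list[str]:
        """Metabolites within one order of magnitude of the extreme loading."""
        return top_contributors(self.loadings_, component, direction)


def top_contributors(
    loadings: pd.DataFrame, component: int = 0, direction: str = "positive"
) -> list[str]:
    """Apply the order-of-magnitude selector on one loading column.

    Positive direction: metabolites with loading >= max_loading / 10;
    negative direction symmetric around the minimum.  Scale invariant by
    construction.
    """
    col = loadings.iloc[:, component]
    if direction == "positive":
        peak = col.max()
        if peak <= 0:
            return []
        return list(col.index[col >= peak / 10.0])
    if direction == "negative":
        trough = col.min()
        if trough >= 0:
            return []
        return list(col.index[col <= trough / 10.0])
    raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")


def atp_turnover(
    result: SamplingResult,
    model: MetabolicModel,
    atp_ids: tuple[str, ...] = ("atp[c]",),
) -> np.ndarray:
    """Total intracellular ATP turnover per sample (sum over compartments)."""
    idx = model.metabolite_index
    missing = [m for m in atp_ids if m not in idx]
    if missing:
        raise KeyError(f"ATP metabolite(s) {missing} not in model")
    rows = [idx[m] for m in atp_ids]
    abs_S = abs(model.stoichiometry).tocsr()[rows, :]
    return 0.5 * np.asarray(abs_S @ np.abs(result.flux_matrix)).sum(axis=0)


def overlay(
    pca: TurnoverPCA,
    labels: PhenotypeSummary,
    atp: np.ndarray | None = None,
) -> pd.DataFrame:
    """Annotated score table: PC1/PC2 plus phenotype labels per sample.

    ATP turnover, when given, is min-max normalized to [0, 1] across samples
    (constant vectors map to 0).
    """
    scores = pca.scores_
    if scores.shape[0] != len(labels.per_sample):
        raise ValueError("sample ordering mismatch between PCA and labels")
    table = labels.per_sample.copy()
    table.insert(0, "PC1", scores[:, 0])
    table.insert(1, "PC2", scores[:, 1] if scores.shape[1] > 1 else 0.0)
    if atp is not None:
        atp = np.asarray(atp, dtype=float)
        if atp.shape[0] != scores.shape[0]:
            raise ValueError("ATP turnover length mismatch")
        span = atp.max() - atp.min()
        table["atp_turnover_norm"] = (atp - atp.min()) / span if span > 0 else 0.0
    return table
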