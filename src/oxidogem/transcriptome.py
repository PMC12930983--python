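"""Transcriptome integration on the metabolite–gene network.

Reporter-metabolite scoring aggregates differential-expression evidence of
the genes neighbouring each metabolite: per gene, Z = Phi^-1(1 - p); per
metabolite with k neighbour genes, Z_met = sum(Z_gene) / sqrt(k); the score
is corrected against the mean and standard deviation of random size-k gene
sets drawn from the background, converted to a two-sided p-value and adjusted
for multiple testing (Benjamini-Hochberg).  A significant reporter metabolite
marks a node of coordinated transcriptional regulation.

Cross-condition co-expression uses the Pearson correlation with a two-sided
t-test (df = n_conditions - 2) for every gene pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import MetabolicModel, split_compartment
from .rules import rule_genes

__all__ = ["ReporterScore", "reporter_metabolites", "metabolite_gene_adjacency", "expression_correlation"]

_P_FLOOR = np.finfo(float).tiny


@dataclass
class ReporterScore:
    metabolite: str
    n_genes: int
    z_raw: float
    z_corrected: float
    p_value: float
    adjusted_p: float
    direction: float  # mean log-fold-change sign of neighbour genes


def metabolite_gene_adjacency(
    model: MetabolicModel, collapse_compartments: bool = True
) -> dict[str, set[str]]:
    """Map each metabolite to the genes whose reactions produce or consume it.

    With ``collapse_compartments`` the compartment tag is stripped, so
    currency metabolites duplicated across compartments aggregate into one
    node.
    """
    reaction_genes = [rule_genes(rule) for rule in model.gene_rules]
    adjacency: dict[str, set[str]] = {}
    coo = model.stoichiometry.tocoo()
    for i, j in zip(coo.row, coo.col):
        genes = reaction_genes[j]
        if not genes:
            continue
        met = model.metabolite_ids[i]
        if collapse_compartments:
            met = split_compartment(met)[0]
        adjacency.setdefault(met, set()).update(genes)
    return adjacency


def reporter_metabolites(
    model: MetabolicModel,
    de: pd.DataFrame,
    n_background_draws: int = 10_000,
    seed: int | None = None,
    collapse_compartments: bool = True,
) -> pd.DataFrame:
    """Score every metabolite as a reporter of transcriptional regulation.

    ``de`` must carry a gene identifier index (or a ``gene_id`` column) and a
    ``p_value`` column; an optional ``log_fc`` column provides direction.
    Only genes present in both the table and the model contribute.  Returns a
    DataFrame sorted by adjusted p-value.
    """
    if "gene_id" in de.columns:
        de = de.set_index("gene_id")
    if "p_value" not in de.columns:
        raise ValueError("differential-expression table needs a 'p_value' column")
    pvals = de["p_value"].astype(float)
    if ((pvals <= 0) | (pvals > 1)).any():
        pvals = pvals.clip(lower=_P_FLOOR, upper=1.0)

    genes = [g for g in pvals.index if g in set(model.gene_ids)]
    if not genes:
        raise ValueError("no overlap between expression table and model genes")
    z_gene = pd.Series(stats.norm.ppf(1.0 - pvals.loc[genes].clip(_P_FLOOR, 1 - 1e-16)), index=genes)
    direction = (
        np.sign(de.loc[genes, "log_fc"]).astype(float)
        if "log_fc" in de.columns
        else pd.Series(0.0, index=genes)
    )

    adjacency = metabolite_gene_adjacency(model, collapse_compartments)
    rng = np.random.default_rng(seed)
    z_values = z_gene.to_numpy()

    records = []
    bg_cache: dict[int, tuple[float, float]] = {}
    for met, neighbours in sorted(adjacency.items()):
        scored = [g for g in neighbours if g in z_gene.index]
        k = len(scored)
        if k == 0:
            continue
        z_met = float(z_gene.loc[scored].sum() / np.sqrt(k))
        if k not in bg_cache:
            draws = rng.choice(z_values, size=(n_background_draws, k), replace=True)
            sums = draws.sum(axis=1) / np.sqrt(k)
            bg_cache[k] = (float(sums.mean()), float(sums.std(ddof=1)))
        mu, sd = bg_cache[k]
        z_corr = (z_met - mu) / sd if sd > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z_corr)))
        records.append(
            ReporterScore(
                metabolite=met,
                n_genes=k,
                z_raw=z_met,
                z_corrected=z_corr,
                p_value=p,
                adjusted_p=np.nan,
                direction=float(direction.loc[scored].mean()),
            )
        )
    if not records:
        raise ValueError("no metabolite has scored neighbour genes")
    frame = pd.DataFrame([r.__dict__ for r in records])
    frame["adjusted_p"] = multipletests(frame["p_value"], method="fdr_bh")[1].clip(_P_FLOOR, 1.0)
    return frame.sort_values(["adjusted_p", "p_value"]).reset_index(drop=True)


def expression_correlation(
    matrix: pd.DataFrame, pairs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Pearson r with a two-sided t-test for gene pairs across conditions.

    ``matrix`` is genes x conditions (>= 3 conditions).  Without an explicit
    pair list, all unordered pairs are scored.  Zero-variance genes yield
    NaN r with a ``degenerate`` flag rather than a fabricated value.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 conditions for correlation testing")
    if not np.isfinite(matrix.to_numpy()).all():
        raise ValueError("expression matrix contains non-finite values")
    X = matrix.to_numpy(dtype=float)
    genes = list(matrix.index)
    n = X.shape[1]
    sd = X.std(axis=1, ddof=1)

    centered = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = centered / denom[:, None]
    corr = normed @ normed.T

    index = {g: i for i, g in enumerate(genes)}
    if pairs is None:
        pairs = [(genes[i], genes[j]) for i in range(len(genes)) for j in range(i + 1, len(genes))]

    rows = []
    df = n - 2
    for gi, gj in pairs:
        i, j = index[gi], index[gj]
        degenerate = sd[i] == 0 or sd[j] == 0
        if degenerate:
            r, p = np.nan, np.nan
        else:
            r = float(np.clip(corr[i, j], -1.0, 1.0))
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt(df / (1.0 - r * r))
                p = float(2.0 * stats.t.sf(abs(t), df))
        rows.append({"gene_i": gi, "gene_j": gj, "r": r, "p_value": p, "degenerate": degenerate})
    return pd.DataFrame(rows)
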