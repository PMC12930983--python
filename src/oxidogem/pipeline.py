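"""End-to-end study orchestration from one configuration.

``run_study`` chains the full analysis — model loading (or toy generation),
optional curation replay, FBA scenario grid, random-objective sampling,
phenotype classification, turnover PCA and transcriptome integration — and
writes every table plus a manifest with seeds and content hashes, so a rerun
with the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .curation import apply_curation, load_actions
from .io import read_model, write_json
from .model import MetabolicModel, model_stats
from .phenotypes import PathwayMarkers, classify, cofactor_usage, summarize_table
from .sampling import SamplingConfig, sample
from .transcriptome import expression_correlation, reporter_metabolites
from .turnover import TurnoverPCA, atp_turnover, overlay, to_turnover

__all__ = ["RunConfig", "run_study"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full study run.

    ``model_path`` of ``None`` builds the toy model.  The scenario grid is a
    tuple of (carbon source, limitation) pairs using the toy naming; custom
    models may pass explicit scenarios through ``scenarios``.
    """

    output_dir: str
    model_path: str | None = None
    curation_actions_path: str | None = None
    scenario_grid: tuple[tuple[str, str], ...] = (
        ("galactose", "carbon"), ("galactose", "oxygen"), ("galactose", "nitrogen"),
        ("lactose", "carbon"), ("lactose", "oxygen"), ("lactose", "nitrogen"),
    )
    n_samples: int = 1000
    seed: int = 0
    growth_floor_fraction: float = 0.5
    objective_density: float | None = None
    flux_epsilon: float = 1e-6
    expression_blocks: tuple[tuple[str, ...], ...] = (
        ("GAL1", "GAL7", "GAL10", "XYL1_2", "LAC4"),
    )

    def __post_init__(self):
        if not self.scenario_grid:
            raise ValueError("scenario grid must not be empty")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: RunConfig, markers: PathwayMarkers | None = None) -> dict:
    """Execute the study; returns the output manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: str(v) for k, v in config.__dict__.items()},
                      "outputs": {}, "stages": []}

    def record(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        # --- model
        if config.model_path is None:
            model = synth.build_toy_model()
            markers = markers or synth.toy_markers()
        else:
            model = read_model(config.model_path)
            if markers is None:
                raise ValueError("custom models require explicit pathway markers")
        if config.curation_actions_path is not None:
            model = apply_curation(model, load_actions(config.curation_actions_path))
        model_file = out / "model.json"
        write_json(model, model_file)
        record("model", model_file)
        manifest["model_stats"] = model_stats(model)
        manifest["stages"].append("model")

        # --- sampling + classification per scenario
        summaries = {}
        rng = np.random.default_rng(config.seed)
        for carbon, limitation in config.scenario_grid:
            scenario = synth.toy_scenario(carbon, limitation)
            cfg = SamplingConfig(
                n_samples=config.n_samples,
                growth_floor_fraction=config.growth_floor_fraction,
                seed=int(rng.integers(2**31 - 1)),
                objective_density=config.objective_density,
            )
            result = sample(model, scenario, cfg)
            summary = classify(result, markers, config.flux_epsilon)
            summaries[scenario.name] = summary
            name = f"{carbon}_{limitation}"
            labels_file = out / f"labels_{name}.tsv"
            summary.per_sample.to_csv(labels_file, sep="\t", index=False)
            record(f"labels_{name}", labels_file)

            cof = cofactor_usage(result, markers, config.flux_epsilon)
            cof_file = out / f"cofactor_{name}.tsv"
            cof.to_csv(cof_file, sep="\t", index=False)
            record(f"cofactor_{name}", cof_file)

            # turnover PCA overlay for this scenario
            turnover = to_turnover(result, model)
            pca = TurnoverPCA(n_components=2).fit(turnover)
            table = overlay(pca, summary, atp_turnover(result, model))
            overlay_file = out / f"overlay_{name}.tsv"
            table.to_csv(overlay_file, sep="\t", index=False)
            record(f"overlay_{name}", overlay_file)
        manifest["stages"].append("sampling")

        table = summarize_table(summaries)
        table_file = out / "secretion_table.tsv"
        table.to_csv(table_file, sep="\t")
        record("secretion_table", table_file)
        manifest["stages"].append("classification")

        # --- transcriptome integration on synthetic expression data
        blocks = [list(b) for b in config.expression_blocks]
        matrix, truth = synth.simulate_expression(
            list(model.gene_ids), blocks=blocks, seed=config.seed
        )
        expr_file = out / "expression_matrix.tsv"
        matrix.to_csv(expr_file, sep="\t")
        record("expression_matrix", expr_file)

        corr = expression_correlation(matrix)
        corr_file = out / "coexpression.tsv"
        corr.to_csv(corr_file, sep="\t", index=False)
        record("coexpression", corr_file)

        de = pd.DataFrame(
            {
                "p_value": np.where(
                    [truth[g] >= 0 for g in model.gene_ids], 1e-6,
                    np.random.default_rng(config.seed).uniform(0.05, 1.0, model.n_genes),
                ),
                "log_fc": [1.0 if truth[g] >= 0 else 0.0 for g in model.gene_ids],
            },
            index=pd.Index(model.gene_ids, name="gene_id"),
        )
        reporters = reporter_metabolites(model, de, n_background_draws=2000, seed=config.seed)
        rep_file = out / "reporter_metabolites.tsv"
        reporters.to_csv(rep_file, sep="\t", index=False)
        record("reporter_metabolites", rep_file)
        manifest["stages"].append("transcriptome")

    except Exception as exc:
        manifest["error"] = {"stage": manifest["stages"][-1] if manifest["stages"] else "init",
                             "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    manifest_file = out / "manifest.json"
    manifest_file.write_text(json.dumps(manifest, indent=1))
    return manifest
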