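"""Configuration-driven orchestration of the full analysis.

``run_all`` takes a dataset (read from CSV or synthesised) through the
four report families — univariate trait screen, combined-stress
interaction classification, PERMANOVA with pairwise contrasts, and the
sPLS-DA bundle — writing CSV/JSON outputs plus a manifest that suffices
to re-run the bundle bit-identically.  All numerical work happens in the
stage modules; this file only sequences them.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import PlantDataset
from .interaction import interaction_screen
from .permanova import pairwise_permanova, permanova, standardize_and_distance
from .splsda import (correlate_scores, fit_splsda, loading_group_assignment,
                     perf, tune)
from .synthetic import ConfigError, SyntheticConfig, generate_dataset
from .univariate import render_table, trait_screen

log = logging.getLogger("rootstress")

__all__ = ["RunConfig", "run_all", "trait_matrix", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are kept."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    seed: int
    outdir: str = "rootstress_out"
    input_csv: str | None = None          # mutually exclusive with synthetic
    synthetic: SyntheticConfig | None = None
    alpha: float = 0.05
    n_permutations: int = 999
    folds: int = 5
    repeats: int = 50
    max_ncomp: int = 3
    keepX_grid: list[int] | None = None
    #: which tidy root types enter the multivariate stages
    trait_root_types: tuple[str, ...] = (
        "primary", "seminal", "primary_lateral", "seminal_lateral")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.n_permutations < 99:
            raise ConfigError("n_permutations must be >= 99")
        if self.input_csv is None and self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if "seed" not in data:
            raise ConfigError("config file must set a seed")
        if "synthetic" in data and data["synthetic"] is not None:
            syn = dict(data["synthetic"])
            syn.setdefault("seed", data["seed"])
            if "treatments" in syn:
                syn["treatments"] = tuple(syn["treatments"])
            data["synthetic"] = SyntheticConfig(**syn)
        if "trait_root_types" in data:
            data["trait_root_types"] = tuple(data["trait_root_types"])
        return cls(**data)


def trait_matrix(dataset: PlantDataset,
                 root_types: tuple[str, ...]) -> tuple[pd.DataFrame, np.ndarray]:
    """Wide samples x traits matrix restricted to the chosen root types,
    plus the aligned treatment label vector."""
    wide = dataset.to_wide()
    keep = [c for c in wide.columns
            if c != "treatment" and c.split(".", 1)[0] in root_types]
    x = wide[keep].dropna(axis=1)
    return x, wide["treatment"].to_numpy()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise StageError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("load")
def _load(config: RunConfig) -> PlantDataset:
    if config.input_csv is not None:
        return PlantDataset.read_csv(config.input_csv)
    return generate_dataset(config.synthetic)


@_stage("univariate")
def _univariate(config: RunConfig, dataset: PlantDataset, outdir: Path) -> pd.DataFrame:
    screen = trait_screen(dataset, alpha=config.alpha)
    screen.to_csv(outdir / "univariate_screen.csv", index=False)
    render_table(screen, dataset.treatments).to_csv(
        outdir / "univariate_tables.csv", index=False)
    return screen


@_stage("interaction")
def _interaction(config: RunConfig, dataset: PlantDataset, outdir: Path) -> pd.DataFrame:
    report = interaction_screen(dataset, alpha=config.alpha)
    report.to_csv(outdir / "interaction_report.csv", index=False)
    return report


@_stage("permanova")
def _permanova(config: RunConfig, dataset: PlantDataset, outdir: Path) -> dict:
    x, labels = trait_matrix(dataset, config.trait_root_types)
    d = standardize_and_distance(x)
    overall = permanova(d, labels, n_permutations=config.n_permutations,
                        seed=config.seed + 1)
    pairs = pairwise_permanova(d, labels, n_permutations=config.n_permutations,
                               seed=config.seed + 2)
    pairs.to_csv(outdir / "permanova_pairwise.csv", index=False)
    block = asdict(overall)
    (outdir / "permanova_overall.json").write_text(json.dumps(block, indent=1))
    return block


@_stage("splsda")
def _splsda(config: RunConfig, dataset: PlantDataset, outdir: Path) -> dict:
    x, labels = trait_matrix(dataset, config.trait_root_types)
    max_ncomp = min(config.max_ncomp, len(x) - 1, x.shape[1])
    curve = perf(x, labels, max_ncomp=max_ncomp, folds=config.folds,
                 repeats=config.repeats, seed=config.seed + 3)
    ncomp = curve.best()
    keep, tune_curves = tune(x, labels, ncomp=ncomp,
                             keepX_grid=config.keepX_grid, folds=config.folds,
                             repeats=config.repeats, seed=config.seed + 4)
    model = fit_splsda(x, labels, ncomp=ncomp, keepX=keep)
    model.to_json(outdir / "splsda_model.json")

    pd.DataFrame({
        "ncomp": curve.grid, "overall_error": curve.overall, "ber": curve.ber,
        "overall_sd": curve.overall_sd, "ber_sd": curve.ber_sd,
    }).to_csv(outdir / "splsda_perf.csv", index=False)
    pd.concat([
        pd.DataFrame({"component": h + 1, "keepX": c.grid, "ber": c.ber,
                      "ber_sd": c.ber_sd})
        for h, c in enumerate(tune_curves)
    ]).to_csv(outdir / "splsda_tune.csv", index=False)

    scores = pd.DataFrame(model.scores, index=x.index,
                          columns=[f"comp{h+1}" for h in range(ncomp)])
    scores.insert(0, "treatment", labels)
    scores.to_csv(outdir / "splsda_scores.csv")
    loadings = pd.DataFrame(model.weights, index=model.feature_names,
                            columns=[f"comp{h+1}" for h in range(ncomp)])
    loadings.to_csv(outdir / "splsda_loadings.csv")
    pd.concat([
        loading_group_assignment(model, x, labels, component=h + 1).assign(component=h + 1)
        for h in range(ncomp)
    ]).to_csv(outdir / "splsda_loading_groups.csv", index=False)

    # correlate plant weights with latent scores when plant totals exist
    plant = dataset.traits[dataset.traits["root_type"] == "plant"]
    corr_rows = []
    for wt_trait in ("fresh_weight", "dry_weight"):
        w = plant[plant["trait"] == wt_trait].set_index("plant_id")["value"]
        if len(w) == len(x):
            c = correlate_scores(model.scores, w.reindex(x.index).to_numpy())
            c.insert(0, "plant_weight", wt_trait)
            corr_rows.append(c)
    if corr_rows:
        pd.concat(corr_rows).to_csv(outdir / "score_correlations.csv", index=False)

    return {"ncomp": ncomp, "keepX": keep,
            "ber_at_ncomp": float(curve.ber[ncomp - 1]),
            "explained_variance": model.explained_variance.tolist()}


def run_all(config: RunConfig) -> dict:
    """Run every stage and return the JSON-ready manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = _load(config)
    dataset.write_csv(outdir / "dataset.csv")
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "n_plants": dataset.n_plants(),
        "treatments": dataset.treatments,
    }
    screen = _univariate(config, dataset, outdir)
    manifest["univariate"] = {
        "n_traits": int(len(screen)),
        "n_significant_anova": int(screen["anova_significant"].sum()),
        "n_differing_from_control": int(screen["differs_from_control"].sum()),
    }
    report = _interaction(config, dataset, outdir)
    manifest["interaction"] = {
        "n_classified": int(len(report)),
        "labels": report["label"].value_counts().to_dict() if len(report) else {},
    }
    manifest["permanova"] = _permanova(config, dataset, outdir)
    manifest["splsda"] = _splsda(config, dataset, outdir)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    out = asdict(config)
    if config.synthetic is not None:
        syn = asdict(config.synthetic)
        syn["specs"] = f"<{len(config.synthetic.specs)} trait specs>"
        out["synthetic"] = syn
    return out
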