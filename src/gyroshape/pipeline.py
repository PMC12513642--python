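"""End-to-end orchestration: separation -> shape PCA -> embedding -> index.

One mandatory top-level seed is split deterministically into per-stage seeds,
and every stage's parameters, seeds, and soft warnings are recorded in a JSON
manifest, so a run is reproducible bit for bit from its manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .curves import Trajectory
from .index import (
    DEFAULT_Y_VARS,
    age_mixed_model,
    baseline_comparison,
    bootstrap_pls,
    pearson_panel,
    repeated_shape_pca,
)
from .io import read_clinical, read_trajectories
from .pca import fit_shape_pca, project
from .registration import separate_phase_amplitude

__all__ = ["RunConfig", "run_pipeline", "stage_seeds"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    ``seed`` is mandatory and is the single source of randomness: per-stage
    seeds are derived from it deterministically.
    """

    trajectories_path: str = ""
    clinical_path: str = ""
    out_dir: str = "gyroshape_out"
    grid_length: int = 200
    tol: float = 1e-4
    max_iter: int = 20
    n_retained: int = 3
    n_runs: int = 100
    n_boot: int = 10000
    train_frac: float = 0.7
    n_components: int = 3
    y_vars: tuple[str, ...] = DEFAULT_Y_VARS
    index_cohorts: tuple[str, ...] = ("DMD", "SMA")
    seed: int = 0
    center_phases: bool = True
    presmooth: bool = False
    refit_alignment: bool = True
    baseline_n_boot: int = 1000
    alpha: float = 0.01
    make_plots: bool = False

    def validate(self) -> None:
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must be in (0, 1)")
        if self.n_runs < 1 or self.n_boot < 1 or self.n_retained < 1:
            raise ValueError("n_runs, n_boot, n_retained must be >= 1")
        if self.grid_length < 8:
            raise ValueError("grid_length must be >= 8")


def stage_seeds(seed: int, stages: tuple[str, ...]) -> dict[str, int]:
    """Deterministically split one seed into named per-stage seeds (< 2^31)."""
    rng = np.random.default_rng(seed)
    return {s: int(rng.integers(0, 2**31 - 1)) for s in stages}


STAGES = ("embedding", "index", "baseline", "mixed_model")


def run_pipeline(
    config: RunConfig,
    trajectories: list[Trajectory] | None = None,
    clinical: pd.DataFrame | None = None,
) -> dict:
    """Execute the full analysis and write all stage artifacts.

    Inputs may be given in memory or read from the configured paths.  Returns
    the manifest dict; hard failures raise with the failing stage named,
    soft warnings accumulate in the manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed, STAGES)
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stage_seeds": seeds,
        "warnings": [],
        "artifacts": [],
    }

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        _stage("load")
        if trajectories is None:
            trajectories = read_trajectories(config.trajectories_path, config.grid_length)
        if clinical is None:
            clinical = read_clinical(config.clinical_path)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'load' failed: {e}") from e

    activities = sorted({t.activity for t in trajectories})
    manifest["n_trajectories"] = len(trajectories)
    manifest["activities"] = activities

    try:
        _stage("separate+pca")
        for act in activities:
            curves = [t for t in trajectories if t.activity == act]
            sep = separate_phase_amplitude(
                curves, tol=config.tol, max_iter=config.max_iter,
                center_phases=config.center_phases,
            )
            if not sep.converged:
                manifest["warnings"].append(f"separation for {act} did not converge")
            sep.save(out / f"separation_{act}")
            model = fit_shape_pca(sep.aligned_srvfs, n_retained=config.n_retained, activity=act)
            model.save(out / f"pca_{act}")
            scores = pd.DataFrame(
                [
                    {"subject_id": c.subject_id, "visit": c.visit, "activity": act,
                     **{f"VPC{k + 1}": s for k, s in enumerate(project(q, model))}}
                    for c, q in zip(curves, sep.aligned_srvfs)
                ]
            )
            scores.to_csv(out / f"scores_{act}.csv", index=False)
            manifest["artifacts"] += [f"separation_{act}", f"pca_{act}", f"scores_{act}.csv"]
            manifest[f"variance_fractions_{act}"] = model.variance_fractions.tolist()
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'separate+pca' failed: {e}") from e

    try:
        _stage("embedding")
        embedding = repeated_shape_pca(
            trajectories, n_runs=config.n_runs, n_retained=2,
            seed=seeds["embedding"], refit_alignment=config.refit_alignment,
            tol=config.tol, max_iter=config.max_iter,
        )
        embedding.to_csv(out / "embedding.csv", index=False)
        manifest["artifacts"].append("embedding.csv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'embedding' failed: {e}") from e

    try:
        _stage("index")
        if clinical is None or clinical.empty:
            raise ValueError("clinical table is required for the index stage")
        feats = [c for c in embedding.columns if c.startswith("VPC")]
        merged = embedding.merge(
            clinical[clinical["cohort"].isin(config.index_cohorts)], on="subject_id"
        ).dropna(subset=list(config.y_vars) + feats)
        index_model = bootstrap_pls(
            merged[feats], merged[list(config.y_vars)],
            n_boot=config.n_boot, train_frac=config.train_frac,
            n_components=config.n_components, seed=seeds["index"],
        )
        (out / "index.json").write_text(json.dumps(index_model.summary(), indent=2))
        pd.DataFrame(
            index_model.corr_distribution,
            columns=[f"component_{k + 1}" for k in range(index_model.n_components)],
        ).to_csv(out / "index_correlations.csv", index=False)
        pd.DataFrame(index_model.coef_distribution, columns=feats).to_csv(
            out / "index_coefficients.csv", index=False
        )
        manifest["artifacts"] += ["index.json", "index_correlations.csv", "index_coefficients.csv"]
        manifest["index_median_correlation"] = float(index_model.medians[0])
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'index' failed: {e}") from e

    try:
        _stage("correlations")
        panel = pearson_panel(embedding, clinical)
        panel.to_csv(out / "correlations.csv", index=False)
        manifest["artifacts"].append("correlations.csv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'correlations' failed: {e}") from e

    try:
        _stage("mixed_model")
        act0 = activities[0]
        per_visit = pd.read_csv(out / f"scores_{act0}.csv").rename(columns={"VPC1": "score"})
        mm = age_mixed_model(per_visit[["subject_id", "visit", "score"]], clinical,
                             alpha=config.alpha)
        mm.to_csv(out / "mixed_model.csv", index=False)
        if mm.attrs.get("note"):
            manifest["warnings"].append(f"mixed model: {mm.attrs['note']}")
        manifest["artifacts"].append("mixed_model.csv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'mixed_model' failed: {e}") from e

    try:
        _stage("baseline")
        baseline = baseline_comparison(
            trajectories, clinical, n_boot=config.baseline_n_boot,
            train_frac=config.train_frac, n_components=config.n_components,
            seed=seeds["baseline"], y_vars=config.y_vars,
            cohorts=config.index_cohorts,
        )
        baseline.to_csv(out / "baseline_comparison.csv", index=False)
        manifest["artifacts"].append("baseline_comparison.csv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'baseline' failed: {e}") from e

    if config.make_plots:
        _write_plots(out, activities)
        manifest["artifacts"].append("plots")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _write_plots(out: Path, activities: list[str]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots = out / "plots"
    plots.mkdir(exist_ok=True)
    for act in activities:
        sep = pd.read_csv(out / f"separation_{act}" / "mean.csv")
        fig, ax = plt.subplots()
        ax.plot(sep["t"], sep["mean"])
        ax.set_xlabel("normalized time")
        ax.set_ylabel("angular velocity (deg/s)")
        ax.set_title(f"Shape mean ({act})")
        fig.savefig(plots / f"mean_{act}.png", dpi=100)
        plt.close(fig)
    corr = pd.read_csv(out / "index_correlations.csv")
    fig, ax = plt.subplots()
    ax.hist(corr["component_1"].dropna(), bins=40)
    ax.set_xlabel("held-out canonical correlation (component 1)")
    ax.set_ylabel("replicates")
    fig.savefig(plots / "bootstrap_correlation.png", dpi=100)
    plt.close(fig)
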