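"""End-to-end pipeline: simulate (or load) -> diversity -> clustering -> DAPC ->
phenotypic integration -> biomarkers, driven by one schema-validated JSON config.

Every stage draws its seed deterministically from the global seed
(``sha256(f"{seed}:{stage}")`` truncated below 2^31), so a stage rerun in
isolation reproduces its pipeline-level output.  All artifacts are plain TSV or
JSON with sorted keys and no timestamps: rerunning an identical config yields
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .datamodel import (
    EmissionMatrix,
    merge_platforms,
    read_compound_records,
    read_emission_matrix,
    read_species_annotation,
    write_compound_records,
    write_emission_matrix,
    write_species_annotation,
)
from .simulate import SimulationScenario, simulate
from .diversity import species_summaries, write_diversity_table
from .clustering import cluster_compounds, spearman_distance_matrix, \
    write_cluster_table, write_tree_json
from .dapc import default_m_grid, fit_dapc, labels_for_samples, predict_dapc, \
    xval_select_m
from .integration import pi_panel
from .biomarkers import DEFAULT_SUBSET_GRID, MLTask, run_task

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


class InputPaths(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ptr: str
    gc: str
    species: str
    compounds: str


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    diversity: bool = True
    clustering: bool = True
    dapc: bool = True
    integration: bool = True
    biomarkers: bool = True


class ClusteringConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = 17
    linkage: Literal["average", "complete", "single", "ward"] = "average"


class DAPCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    labels: list[str] = Field(default_factory=lambda: [
        "phylum", "trophic_mode", "alt_trophic_mode", "lifestyle",
        "substrate", "host_type"])
    n_rep: int = 30
    training_fraction: float = 0.9
    grid_points: int = 10
    # emission rates span orders of magnitude; discriminant analysis runs on
    # log1p profiles by default so center/scale acts on the log-abundance scale
    log_transform: bool = True


class IntegrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_null: int = 10_000
    null_mode: Literal["permute", "subset"] = "permute"


class BiomarkerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tasks: list[str] = Field(default_factory=lambda: ["trophic_mode"])
    platforms: list[Literal["PTR", "GC"]] = Field(default_factory=lambda: ["PTR", "GC"])
    subset_grid: list[int] = Field(default_factory=lambda: list(DEFAULT_SUBSET_GRID))
    cv_folds: int = 10
    test_fraction: float = 0.25


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str
    seed: int = 0
    scenario: Optional[SimulationScenario] = None  # simulate when set ...
    inputs: Optional[InputPaths] = None            # ... else load from paths
    stages: StageToggles = Field(default_factory=StageToggles)
    clustering: ClusteringConfig = Field(default_factory=ClusteringConfig)
    dapc: DAPCConfig = Field(default_factory=DAPCConfig)
    integration: IntegrationConfig = Field(default_factory=IntegrationConfig)
    biomarkers: BiomarkerConfig = Field(default_factory=BiomarkerConfig)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text(encoding="utf-8"))


def _dump_json(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8", newline="\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages in dependency order; returns the run dir.

    A stage failure writes ``status.json`` with the failed stage and re-raises;
    artifacts of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    manifest = {
        # out_dir excluded: the same analysis into a different directory is
        # the same run for reproducibility purposes
        "config_sha256": hashlib.sha256(json.dumps(
            config.model_dump(exclude={"out_dir"}), sort_keys=True,
            default=str).encode()).hexdigest(),
        "version": __version__,
        "global_seed": config.seed,
        "stage_seeds": {},
        "stages": status,
    }

    def finish(stage: str, ok: bool = True) -> None:
        status[stage] = "ok" if ok else "failed"
        _dump_json({"stages": status}, out / "status.json")

    current = "data"
    try:
        if config.scenario is not None:
            sc = config.scenario.model_copy(
                update={"seed": stage_seed(config.seed, "simulate")})
            manifest["stage_seeds"]["simulate"] = sc.seed
            ptr, gc, annotations, compounds, _truth = simulate(sc)
            write_emission_matrix(ptr, out / "ptr.tsv")
            write_emission_matrix(gc, out / "gc.tsv")
            write_species_annotation(annotations.values(), out / "species.tsv")
            write_compound_records(compounds.values(), out / "compounds.tsv")
        elif config.inputs is not None:
            ptr = read_emission_matrix(config.inputs.ptr, "PTR")
            gc = read_emission_matrix(config.inputs.gc, "GC")
            annotations = read_species_annotation(config.inputs.species)
            compounds = read_compound_records(config.inputs.compounds)
        else:
            raise ValueError("config needs either a scenario or input paths")
        combined = merge_platforms(ptr, gc)
        write_emission_matrix(combined, out / "combined.tsv")
        finish("data")

        if config.stages.diversity:
            current = "diversity"
            write_diversity_table(species_summaries(ptr), out / "diversity_ptr.tsv")
            write_diversity_table(species_summaries(gc), out / "diversity_gc.tsv")
            finish("diversity")
        else:
            status["diversity"] = "skipped"

        if config.stages.clustering:
            current = "clustering"
            dist = spearman_distance_matrix(combined)
            k = min(config.clustering.k, combined.n_compounds)
            assignment = cluster_compounds(dist, k=k,
                                           linkage=config.clustering.linkage)
            write_cluster_table(assignment, out / "clusters.tsv")
            write_tree_json(assignment, out / "tree.json")
            finish("clustering")
        else:
            status["clustering"] = "skipped"

        if config.stages.dapc:
            current = "dapc"
            seed = stage_seed(config.seed, "dapc")
            manifest["stage_seeds"]["dapc"] = seed
            X = np.log1p(combined.values) if config.dapc.log_transform \
                else combined.values
            for label in config.dapc.labels:
                lab = labels_for_samples(combined, annotations, label)
                rows = [i for i, v in enumerate(lab) if v is not None]
                y = [lab[i] for i in rows]
                k = len(set(y))
                grid = default_m_grid(len(rows), combined.n_compounds, k,
                                      config.dapc.grid_points)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    xval = xval_select_m(X[rows], y, grid,
                                         config.dapc.training_fraction,
                                         config.dapc.n_rep, seed=seed)
                    model = fit_dapc(X[rows], y, xval.chosen_m,
                                     feature_names=combined.compound_ids)
                    pred = predict_dapc(model, X[rows])
                agreement = float(np.mean(np.array(pred.assignments) == np.array(y)))
                _dump_json({
                    "label": label,
                    "chosen_m": xval.chosen_m,
                    "xval": {str(m): {"mean_success": xval.mean_success[m],
                                      "rmse": xval.rmse[m]} for m in xval.grid},
                    "groups": list(model.groups),
                    "training_assignment_agreement": agreement,
                    "coordinates": {
                        f"{combined.sample_ids[i][0]}:{combined.sample_ids[i][1]}":
                            [float(v) for v in pred.coordinates[j]]
                        for j, i in enumerate(rows)},
                    "assignments": {
                        f"{combined.sample_ids[i][0]}:{combined.sample_ids[i][1]}":
                            pred.assignments[j]
                        for j, i in enumerate(rows)},
                }, out / f"dapc_{label}.json")
            finish("dapc")
        else:
            status["dapc"] = "skipped"

        if config.stages.integration:
            current = "integration"
            seed = stage_seed(config.seed, "integration")
            manifest["stage_seeds"]["integration"] = seed
            panel = pi_panel(combined, annotations, compounds,
                             n_null=config.integration.n_null,
                             mode=config.integration.null_mode, seed=seed)
            _dump_json([{k: v for k, v in asdict(r).items()} for r in panel],
                       out / "pi_panel.json")
            finish("integration")
        else:
            status["integration"] = "skipped"

        if config.stages.biomarkers:
            current = "biomarkers"
            seed = stage_seed(config.seed, "biomarkers")
            manifest["stage_seeds"]["biomarkers"] = seed
            reports = []
            platform_of = {"PTR": ptr, "GC": gc}
            for label in config.biomarkers.tasks:
                for plat in config.biomarkers.platforms:
                    task = MLTask(label=label, platform=plat, seed=seed,
                                  test_fraction=config.biomarkers.test_fraction,
                                  cv_folds=config.biomarkers.cv_folds)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        rep = run_task(platform_of[plat], annotations, task,
                                       subset_grid=config.biomarkers.subset_grid)
                    reports.append({
                        "task": label, "platform": plat,
                        "n_passing": rep.n_passing, "note": rep.note,
                        "consensus": list(rep.consensus),
                        "mean_ranks": {k: v for k, v in sorted(rep.mean_ranks.items())},
                        "mean_accuracy": rep.mean_accuracy,
                        "mean_sensitivity": rep.mean_sensitivity,
                        "mean_p_value": rep.mean_p_value,
                        "models": [{
                            "model_id": m.model_id,
                            "optimal_subset_size": m.optimal_subset_size,
                            "top15": list(m.top15),
                            "accuracy": m.accuracy,
                            "sensitivity": m.sensitivity,
                            "accuracy_p_value": m.accuracy_p_value,
                            "passed": m.passed,
                        } for m in rep.models],
                    })
            _dump_json(reports, out / "biomarkers.json")
            finish("biomarkers")
        else:
            status["biomarkers"] = "skipped"

        _dump_json({"stages": status}, out / "status.json")
        _dump_json(manifest, out / "manifest.json")
        return out
    except Exception:
        finish(current, ok=False)
        _dump_json(manifest, out / "manifest.json")
        raise
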