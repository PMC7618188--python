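"""End-to-end orchestration: cohort -> graph -> layered SBM -> localisation.

Sequences the full analysis: generate or load a cohort, resample masks to
the analysis grid, apply the >=70% compartment inclusion rule, accumulate
and filter the two-channel graph, fit the layered SBM and its
layer-randomised null, compare their description lengths, screen blocks,
back-project the task-dominant map, extract the candidate ROI from a
(pseudo) meta-analytic z map, and compare predictive models by WAIC.

Every stochastic stage draws its seed deterministically from the master
seed through a named counter, so a rerun with the same config reproduces
every artifact bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import imaging, lesion_graph, roi_model_compare, sbm, synthetic_cohort

log = logging.getLogger("lesiongraph")

_STAGES = ("cohort", "scores", "null", "fit", "fit_null", "meta_map", "regression")


@dataclass
class RunConfig:
    """All pipeline parameters plus the master seed.

    ``mode`` is ``"synthetic"`` (generate a cohort) or ``"masks"`` (load
    NIfTI masks + a score table from ``input_dir``).
    """

    mode: str = "synthetic"
    input_dir: str | None = None
    output_dir: str | None = None
    master_seed: int = 0
    # synthetic cohort
    n_patients: int = 150
    grid: int = 24
    voxel_size_mm: float = 4.0
    effect_beta: float = 20.0
    test: str = "stroop"
    # imaging
    resample_factor: int = 1
    min_fraction: float = 0.5
    inclusion_threshold: float = 0.70
    apply_inclusion: bool = True
    # graph
    connectivity: int = 26
    top_fraction: float = 0.5
    min_degree: int = 3
    # sbm
    sbm_wait: int = 100
    sbm_max_sweeps: int = 250
    sbm_anneal_sweeps: int = 60
    sbm_max_blocks: int = 256
    sbm_restarts: int = 2
    beta_min: float = 1.0
    beta_max: float = 10.0
    alpha: float = 0.05
    n_retention_permutations: int = 20
    # ROI / model comparison
    roi_threshold: float = 3.1
    roi_peak_z: float = 6.0
    pca_k: int = 5
    g: float | None = None
    mcmc_samples: int = 10_000
    mcmc_burn_in: int = 10_000

    def stage_seed(self, stage: str) -> int:
        """Counter-based per-stage seed derived from the master seed."""
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=self.master_seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and config echo."""

    def __init__(self, stage: str, config: RunConfig, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}\nconfig: {dataclasses.asdict(config)}")
        self.stage = stage


def _sbm_config(config: RunConfig, stage: str) -> sbm.SBMConfig:
    return sbm.SBMConfig(
        seed=config.stage_seed(stage),
        beta_range=(config.beta_min, config.beta_max),
        wait=config.sbm_wait,
        max_sweeps=config.sbm_max_sweeps,
        anneal_sweeps=config.sbm_anneal_sweeps,
        max_blocks=config.sbm_max_blocks,
        restarts=config.sbm_restarts,
    )


def build_cohort(config: RunConfig):
    """Stage 1: synthesise or load the cohort and template."""
    if config.mode == "synthetic":
        shape = (config.grid,) * 3
        template = synthetic_cohort.default_template(shape, config.voxel_size_mm)
        archetypes = synthetic_cohort.default_archetypes(template)
        truth = synthetic_cohort.default_truth(template, beta=config.effect_beta)
        cohort = synthetic_cohort.generate_cohort(
            template, archetypes, truth, config.n_patients,
            seed=config.stage_seed("cohort"), test_names=(config.test,),
        )
        return cohort, template
    if config.input_dir is None:
        raise ValueError("masks mode requires input_dir")
    src = Path(config.input_dir)
    brain = imaging.read_mask(src / "brain_mask.nii.gz")
    labels = imaging.read_volume(src / "compartments.nii.gz", kind="labels")
    template = imaging.BrainTemplate(
        shape=brain.shape,
        voxel_size_mm=float(np.abs(brain.affine[0, 0])),
        brain_mask=brain.astype_bool(),
        labels=labels.data.astype(np.int16),
        affine=brain.affine,
    )
    cohort = synthetic_cohort.load_cohort(src, template)
    return cohort, template


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and optionally writes) the report."""
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    stage = "cohort"
    try:
        cohort, template = build_cohort(config)
        log.info("cohort: %d patients on grid %s", len(cohort), template.shape)

        stage = "resample"
        if config.resample_factor > 1:
            fine_affine = template.affine
            template = imaging.resample_template(template, config.resample_factor)
            patients = []
            for p in cohort.patients:
                vol = imaging.Volume(p.mask.astype(np.uint8), fine_affine, "mask")
                coarse = imaging.resample_mask(
                    vol, config.resample_factor, config.min_fraction
                )
                patients.append(dataclasses.replace(p, mask=coarse.astype_bool()))
            truth = cohort.truth
            if truth is not None and truth.substrate.shape != template.shape:
                truth = None  # ground truth lives on the fine grid; skip recovery scoring
            cohort = synthetic_cohort.LesionCohort(
                template=template, patients=patients, truth=truth, seed=cohort.seed
            )

        stage = "inclusion"
        included = []
        assignments = {}
        for p in cohort.patients:
            vol = imaging.Volume(p.mask.astype(np.uint8), template.affine, "mask")
            _, comp = imaging.compartment_fractions(
                vol, template, threshold=config.inclusion_threshold
            )
            if comp is not None or not config.apply_inclusion:
                included.append(p)
                assignments[p.id] = comp.name if comp else "unassigned"
        if not included:
            raise ValueError("no patient satisfies the compartment inclusion rule")
        included_cohort = synthetic_cohort.LesionCohort(
            template=template, patients=included, truth=cohort.truth, seed=cohort.seed
        )
        log.info("inclusion: %d/%d patients retained", len(included), len(cohort))

        stage = "graph"
        graph = lesion_graph.accumulate_graph(
            included_cohort, config.test, connectivity=config.connectivity
        )
        graph = lesion_graph.filter_nodes(
            graph, top_fraction=config.top_fraction, min_degree=config.min_degree
        )
        graph = lesion_graph.rescale_weights(graph)
        layered = lesion_graph.to_layered(graph)
        log.info("graph: %d nodes, %d edges", graph.n_nodes, graph.n_edges)

        stage = "fit"
        null_seed = config.stage_seed("null")
        null_graph = lesion_graph.randomize_layers(layered, seed=null_seed)
        fit, fit_null, odds = sbm.compare_to_null(
            layered, null_graph, _sbm_config(config, "fit")
        )
        s_null = fit_null.S
        log.info("entropy: layered %.3f vs null %.3f nats (odds exponent %.3f)", fit.S, s_null, odds)

        stage = "block_tests"
        significance = sbm.permutation_retention(
            fit, layered,
            n_permutations=config.n_retention_permutations,
            seed=config.stage_seed("fit_null"),
            alpha=config.alpha,
        )
        task_map = sbm.back_project(fit, significance, template, dominance="task")
        sbm_support = task_map.data > 0

        stage = "meta_map"
        report_extra: dict = {}
        roi = None
        if config.mode == "synthetic" and cohort.truth is not None:
            zmap = synthetic_cohort.make_meta_map(
                template, cohort.truth.decoy, peak_z=config.roi_peak_z,
                seed=config.stage_seed("meta_map"),
            )
            medial = template.compartment_mask(imaging.Compartment.MEDIAL_WALL)
            roi = imaging.extract_roi(
                zmap, threshold=config.roi_threshold,
                connectivity=config.connectivity, within=medial,
            )
            report_extra["dice_substrate"] = imaging.dice(sbm_support, cohort.truth.substrate)
            report_extra["dice_decoy"] = imaging.dice(sbm_support, cohort.truth.decoy)

        stage = "regression"
        comparison = None
        pca_var: dict[str, float] = {}
        if roi is not None and sbm_support.any():
            masks = included_cohort.masks()
            y = included_cohort.scores(config.test)
            candidates = []
            try:
                m_sbm = roi_model_compare.extract_region_matrix(masks, sbm_support, name="sbm")
                x_sbm, v_sbm = roi_model_compare.pca_reduce(m_sbm, k=config.pca_k)
                pca_var["sbm"] = v_sbm
                candidates.append(("sbm", x_sbm))
                m_roi = roi_model_compare.extract_region_matrix(masks, roi, name="roi")
                x_roi, v_roi = roi_model_compare.pca_reduce(m_roi, k=config.pca_k)
                pca_var["roi"] = v_roi
                candidates.append(("roi", x_roi))
                candidates.append(("sbm+roi", np.hstack([x_sbm, x_roi])))
                comparison = roi_model_compare.compare_models(
                    candidates, y, g=config.g,
                    n_samples=config.mcmc_samples, burn_in=config.mcmc_burn_in,
                    seed=config.stage_seed("regression"),
                )
            except ValueError as err:
                log.warning("model comparison skipped: %s", err)
    except StageError:
        raise
    except Exception as err:
        raise StageError(stage, config, err) from err

    retained = sbm.BlockSignificance(significance.table, config.alpha).retained_blocks("task")
    report = {
        "config": dataclasses.asdict(config),
        "n_patients": len(cohort),
        "n_included": len(included),
        "graph": {"n_nodes": graph.n_nodes, "n_edges": graph.n_edges},
        "entropy_layered_nats": fit.S,
        "entropy_null_nats": s_null,
        "log_posterior_odds": odds,
        "n_blocks": fit.n_blocks,
        "retained_task_blocks": [int(x) for x in retained],
        "pca_variance_fraction": pca_var,
    }
    report.update(report_extra)
    if comparison is not None:
        report["waic"] = {
            row["name"]: {"waic": row["waic"], "lppd": row["lppd"], "p_waic": row["p_waic"], "rank": int(row["rank"])}
            for _, row in comparison.table.iterrows()
        }
        report["best_model"] = comparison.best

    if out:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        imaging.write_volume(task_map, out / "task_dominant_map.nii.gz")
        significance.table.to_csv(out / "block_significance.csv", index=False)
        lesion_graph.write_graph(graph, out / "graph")
        np.savetxt(out / "block_assignment.tsv", np.column_stack([fit.node_voxels, fit.b]), fmt="%d", header="voxel\tblock", comments="")
        if roi is not None:
            imaging.write_volume(
                imaging.Volume(roi.to_mask(), template.affine, "mask"), out / "roi_mask.nii.gz"
            )
        config.to_json(out / "config.json")
    return report
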