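"""End-to-end pipeline: synthetic landscape -> occurrence dataset ->
ensemble SDM -> seed-production models -> future projection.

A single :class:`PipelineConfig` holds every threshold of the workflow
(envelope coverage, pseudo-absence ratio, screening cutoffs, split-sample
settings, TSS cutoff, habitat threshold, altitude cut, occupancy weight)
plus one master seed from which each stage deterministically derives its
own seed. Stage artifacts are written under ``outdir`` together with a
manifest (config hash + seed); re-running a stage with unchanged inputs
reuses the artifacts on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import demography, geodata, occurrence, projection, sdm, synthetic
from .geodata import Raster, TrailSet

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

# the workflow's canonical constants; validate_config warns on deviations
REFERENCE_DEFAULTS = {
    "envelope_q": 0.95,
    "pa_ratio": 10,
    "d2_min": 0.30,
    "rho_max": 0.70,
    "calib_frac": 0.8,
    "reps": 10,
    "tss_min": 0.80,
    "p_min": 0.5,
    "alt_min": 394.0,
}


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 1
    # synthetic stage
    n_occurrences: int = 424
    n_trails: int = 12
    n_sites: int = 7
    plots_per_site: int = 7
    truth: dict = field(default_factory=dict)  # SyntheticTruth overrides
    # occurrence stage
    envelope_q: float = 0.95
    pa_ratio: int = 10
    d2_min: float = 0.30
    rho_max: float = 0.70
    predictors: tuple[str, ...] = ("temperature", "precipitation", "tri")
    # sdm stage
    learners: tuple[str, ...] = ("glm", "sre", "gbm", "rf")
    reps: int = 10
    calib_frac: float = 0.8
    tss_min: float = 0.80
    # habitat / projection
    p_min: float = 0.5
    alt_min: float = 394.0
    occupancy_weight: str = "pocc"
    stepwise: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("predictors", "learners"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_yaml(self, path: str) -> None:
        doc = dataclasses.asdict(self)
        doc["predictors"] = list(self.predictors)
        doc["learners"] = list(self.learners)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    def config_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> dict:
    """Domain checks (errors) and deviation-from-reference warnings."""
    errors, warnings_ = [], []
    checks = [
        ("envelope_q", 0.0 < config.envelope_q <= 1.0, "must be in (0, 1]"),
        ("pa_ratio", config.pa_ratio >= 1, "must be >= 1"),
        ("d2_min", 0.0 <= config.d2_min <= 1.0, "must be in [0, 1]"),
        ("rho_max", 0.0 < config.rho_max <= 1.0, "must be in (0, 1]"),
        ("calib_frac", 0.0 < config.calib_frac <= 1.0, "must be in (0, 1]"),
        ("reps", config.reps >= 1, "must be >= 1"),
        ("tss_min", -1.0 <= config.tss_min < 1.0, "must be in [-1, 1)"),
        ("p_min", 0.0 <= config.p_min < 1.0, "must be in [0, 1)"),
        ("occupancy_weight", config.occupancy_weight in ("pocc", "unit"), "must be pocc|unit"),
        ("learners", all(l in sdm.LEARNERS for l in config.learners), "unknown learner"),
    ]
    for name, ok, msg in checks:
        if not ok:
            errors.append(f"{name}: {msg} (got {getattr(config, name)!r})")
    for name, ref in REFERENCE_DEFAULTS.items():
        if getattr(config, name) != ref:
            warnings_.append(f"{name} deviates from the workflow default {ref!r}")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return {"errors": errors, "warnings": warnings_}


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(master).generate_state(n)]


def _manifest_path(outdir: str, stage: str) -> str:
    return os.path.join(outdir, stage, "manifest.json")


def _write_manifest(outdir: str, stage: str, payload: dict) -> None:
    os.makedirs(os.path.join(outdir, stage), exist_ok=True)
    with open(_manifest_path(outdir, stage), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _manifest_matches(outdir: str, stage: str, payload: dict) -> bool:
    path = _manifest_path(outdir, stage)
    if not os.path.exists(path):
        return False
    with open(path) as fh:
        return json.load(fh) == payload


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the final summary document."""
    validate_config(config)
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    cfg_hash = config.config_hash()

    # ---- stage: synth -----------------------------------------------------
    stage = "synth"
    truth = synthetic.SyntheticTruth(seed=seeds[0], **config.truth)
    rasters = synthetic.make_landscape(truth, seed=seeds[0])
    trails = synthetic.make_trails(truth, rasters, n_trails=config.n_trails, seed=seeds[1])
    occ_points = synthetic.sample_occurrences(
        truth, rasters, n_points=config.n_occurrences, seed=seeds[2]
    )
    if occ_points.empty:
        raise StageError(stage, "no occurrences generated")
    manifest = {"stage": stage, "config": cfg_hash, "seed": seeds[0]}
    if not _manifest_matches(out, stage, manifest):
        stage_dir = os.path.join(out, stage)
        os.makedirs(stage_dir, exist_ok=True)
        for name in ("elevation", "temperature", "precipitation", "tri"):
            geodata.write_ascii_grid(rasters[name], os.path.join(stage_dir, f"{name}.asc"))
        trails.to_geojson(os.path.join(stage_dir, "trails.geojson"))
        geodata.write_points_csv(occ_points, os.path.join(stage_dir, "occurrences.csv"))
        truth.to_json(os.path.join(stage_dir, "truth.json"))
        _write_manifest(out, stage, manifest)

    # ---- stage: occurrence dataset ---------------------------------------
    stage = "occ"
    spec = rasters["tri"].spec
    pts = geodata.assign_cells(occ_points, spec)
    pres = geodata.dedupe_presences(pts)
    for name in config.predictors:
        pres = geodata.extract_at_points(rasters[name], pres, column=name)
    n_missing = int(pres[list(config.predictors)].isna().any(axis=1).sum())
    if n_missing:
        pres = pres.dropna(subset=list(config.predictors))
    if len(pres) < 5:
        raise StageError(stage, f"only {len(pres)} presences after dedup/extraction")
    # candidate cells = every valid cell of the grid
    rr, cc = np.meshgrid(np.arange(spec.n_rows), np.arange(spec.n_cols), indexing="ij")
    cx, cy = spec.cell_center(rr.ravel(), cc.ravel())
    cand = pd.DataFrame({"x": cx, "y": cy, "row": rr.ravel(), "col": cc.ravel()})
    for name in config.predictors:
        cand[name] = rasters[name].values[cand["row"], cand["col"]]
    cand = cand.dropna(subset=list(config.predictors))
    envelope = occurrence.fit_envelope(pres, list(config.predictors), q=config.envelope_q)
    presence_cells = set(zip(pres["row"], pres["col"]))
    pa = occurrence.sample_pseudo_absences(
        envelope, cand, n_presence=len(pres), ratio=config.pa_ratio,
        seed=seeds[3], presence_cells=presence_cells,
    )
    pres = pres.copy()
    pres["label"] = "presence"
    dataset = pd.concat([pres, pa], ignore_index=True)[
        ["x", "y", "row", "col", "label", *config.predictors]
    ]
    labels01 = (dataset["label"] == "presence").to_numpy().astype(int)
    imps = {
        p: occurrence.univariate_importance(dataset[p].to_numpy(), labels01)
        for p in config.predictors
    }
    corr = occurrence.spearman_matrix(dataset, list(config.predictors))
    screen = occurrence.screen_predictors(imps, corr, d2_min=config.d2_min, rho_max=config.rho_max)
    if not screen.retained:
        raise StageError(stage, "no predictor survived screening")
    manifest = {"stage": stage, "config": cfg_hash, "seed": seeds[3]}
    stage_dir = os.path.join(out, stage)
    os.makedirs(stage_dir, exist_ok=True)
    geodata.write_points_csv(dataset, os.path.join(stage_dir, "dataset.csv"))
    envelope.to_json(os.path.join(stage_dir, "envelope.json"))
    with open(os.path.join(stage_dir, "screening.json"), "w") as fh:
        json.dump(
            {"importances": imps, "retained": screen.retained, "dropped": screen.dropped},
            fh, indent=1, sort_keys=True,
        )
    _write_manifest(out, stage, manifest)

    # ---- stage: sdm -------------------------------------------------------
    stage = "sdm"
    predictors = screen.retained
    ensemble, members = sdm.fit_sdm(
        dataset, predictors, learners=list(config.learners), reps=config.reps,
        calib_frac=config.calib_frac, tss_min=config.tss_min, seed=seeds[4],
    )
    prob_now = sdm.predict_map(ensemble, {p: rasters[p] for p in predictors})
    future_rasters = dict(rasters)
    future_rasters["temperature"] = rasters["temperature_future"]
    future_rasters["precipitation"] = rasters["precipitation_future"]
    prob_fut = sdm.predict_map(ensemble, {p: future_rasters[p] for p in predictors})
    masked_now, removed_now = sdm.apply_masks(
        prob_now, substrate_mask=rasters["substrate_mask"],
        landcover_mask=rasters["landcover_mask"], altitude=rasters["elevation"],
        alt_min=config.alt_min,
    )
    masked_fut, removed_fut = sdm.apply_masks(
        prob_fut, substrate_mask=rasters["substrate_mask"],
        landcover_mask=rasters["landcover_mask"], altitude=rasters["elevation"],
        alt_min=config.alt_min,
    )
    hab_now = sdm.habitat_summary(
        masked_now, p_min=config.p_min,
        cell_area_km2=(spec.cell_size / 1000.0) ** 2, label="current",
        masked_counts=removed_now,
    )
    hab_fut = sdm.habitat_summary(
        masked_fut, p_min=config.p_min,
        cell_area_km2=(spec.cell_size / 1000.0) ** 2, label="future",
        masked_counts=removed_fut,
    )
    importances = {
        p: sdm.permutation_importance(ensemble, dataset, p, n_perm=3, seed=seeds[4])
        for p in predictors
    }
    stage_dir = os.path.join(out, stage)
    os.makedirs(stage_dir, exist_ok=True)
    geodata.write_ascii_grid(prob_now, os.path.join(stage_dir, "prob_current.asc"))
    geodata.write_ascii_grid(prob_fut, os.path.join(stage_dir, "prob_future.asc"))
    geodata.write_ascii_grid(masked_now, os.path.join(stage_dir, "prob_current_masked.asc"))
    geodata.write_ascii_grid(masked_fut, os.path.join(stage_dir, "prob_future_masked.asc"))
    with open(os.path.join(stage_dir, "sdm_summary.json"), "w") as fh:
        json.dump(
            {
                "n_members_fitted": len(members),
                "n_members_retained": len(ensemble.members),
                "member_tss": {f"{m.learner_id}_rep{m.rep}": m.tss for m in members},
                "permutation_importance": importances,
                "habitat_current_cells": hab_now.n_cells,
                "habitat_future_cells": hab_fut.n_cells,
                "habitat_net_loss_pct": sdm.net_loss(hab_now, hab_fut),
            },
            fh, indent=1, sort_keys=True,
        )
    _write_manifest(out, stage, {"stage": stage, "config": cfg_hash, "seed": seeds[4]})

    # ---- stage: demography ------------------------------------------------
    stage = "demog"
    plots, infl, _ = synthetic.make_demography(
        truth, prob_now, trails, n_sites=config.n_sites,
        plots_per_site=config.plots_per_site, seed=seeds[5],
    )
    models = fit_demography_models(plots, infl, stepwise=config.stepwise)
    stage_dir = os.path.join(out, stage)
    os.makedirs(stage_dir, exist_ok=True)
    plots.to_csv(os.path.join(stage_dir, "plots.csv"), index=False)
    infl.to_csv(os.path.join(stage_dir, "inflorescences.csv"), index=False)
    with open(os.path.join(stage_dir, "fitness_models.json"), "w") as fh:
        json.dump({k: m.to_dict() for k, m in models.items()}, fh, indent=1, sort_keys=True)
    _write_manifest(out, stage, {"stage": stage, "config": cfg_hash, "seed": seeds[5]})

    # ---- stage: projection ------------------------------------------------
    stage = "project"
    summary = projection.project_range(
        models["number_plot"], models["mass_plot"], masked_now, masked_fut,
        p_min=config.p_min, cell_area_km2=(spec.cell_size / 1000.0) ** 2,
        weight=config.occupancy_weight,
    )
    doc = projection.report(summary, os.path.join(out, stage))
    _write_manifest(out, stage, {"stage": stage, "config": cfg_hash, "seed": seeds[5]})
    doc["habitat"] = {"current_cells": hab_now.n_cells, "future_cells": hab_fut.n_cells}
    doc["screening"] = {"retained": screen.retained}
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
    return doc


PLOT_TERMS = [
    "favorability",
    "trail_distance_m",
    "hemiparasite_cover",
    "cushion_cover",
    "woody_cover",
    "mean_inflorescence_height_cm",
    "favorability:trail_distance_m",
]
INFL_TERMS = [
    "favorability",
    "trail_distance_m",
    "hemiparasite_cover",
    "woody_cover",
    "height_cm",
    "favorability:trail_distance_m",
]


def fit_demography_models(
    plots: pd.DataFrame,
    infl: pd.DataFrame,
    stepwise: bool = True,
) -> dict[str, demography.FitnessModel]:
    """Fit the four seed-production models (number/mass x plot/inflorescence).

    Random-effect structures: plot count model site + plot-level OLRE; plot
    mass model site; inflorescence count model site + plot + OLRE;
    inflorescence mass model site + plot.
    """
    plot_preds = PLOT_TERMS[:-1]
    std_p, scal_p = demography.prepare_predictors(plots, plot_preds)
    groups_count_p = {
        "site": plots["site_id"].to_numpy(),
        "plot_olre": np.arange(len(plots)),
    }
    groups_mass_p = {"site": plots["site_id"].to_numpy()}

    infl_full = infl.merge(
        plots[["plot_id", "site_id", "favorability", "trail_distance_m",
               "hemiparasite_cover", "woody_cover"]],
        on=["plot_id", "site_id"], how="left",
    )
    infl_preds = INFL_TERMS[:-1]
    std_i, scal_i = demography.prepare_predictors(infl_full, infl_preds)
    counts_i = np.array(
        [
            demography.seeds_per_inflorescence(s, a)
            for s, a in zip(infl_full["mean_seeds_per_anthodium"], infl_full["anthodium_count"])
        ]
    )
    mass_i = (
        demography.fresh_to_dry(
            infl_full["mean_fresh_mass_per_anthodium_mg"].to_numpy()
        )
        * infl_full["anthodium_count"].to_numpy()
    )
    groups_count_i = {
        "site": infl_full["site_id"].to_numpy(),
        "plot": infl_full["plot_id"].to_numpy(),
        "olre": np.arange(len(infl_full)),
    }
    groups_mass_i = {
        "site": infl_full["site_id"].to_numpy(),
        "plot": infl_full["plot_id"].to_numpy(),
    }

    counts_p = plots["seed_number_per_m2"].to_numpy()
    mass_p = plots["dry_seed_mass_mg_per_m2"].to_numpy()

    if stepwise:
        m_num_p = demography.stepwise_backward(
            counts_p, std_p, PLOT_TERMS, groups_count_p, "poisson",
            olre="plot_olre", scaling=scal_p, label="number_plot",
        )
        m_mass_p = demography.stepwise_backward(
            np.cbrt(mass_p), std_p, PLOT_TERMS, groups_mass_p, "gaussian",
            scaling=scal_p, label="mass_plot",
        )
        m_num_i = demography.stepwise_backward(
            counts_i, std_i, INFL_TERMS, groups_count_i, "poisson",
            olre="olre", scaling=scal_i, label="number_infl",
        )
        m_mass_i = demography.stepwise_backward(
            np.cbrt(mass_i), std_i, INFL_TERMS, groups_mass_i, "gaussian",
            scaling=scal_i, label="mass_infl",
        )
    else:
        m_num_p = demography.fit_count_model(
            counts_p, std_p, PLOT_TERMS, groups_count_p, olre="plot_olre",
            scaling=scal_p, label="number_plot",
        )
        m_mass_p = demography.fit_mass_model(
            mass_p, std_p, PLOT_TERMS, groups_mass_p, scaling=scal_p, label="mass_plot",
        )
        m_num_i = demography.fit_count_model(
            counts_i, std_i, INFL_TERMS, groups_count_i, olre="olre",
            scaling=scal_i, label="number_infl",
        )
        m_mass_i = demography.fit_mass_model(
            mass_i, std_i, INFL_TERMS, groups_mass_i, scaling=scal_i, label="mass_infl",
        )
    return {
        "number_plot": m_num_p,
        "mass_plot": m_mass_p,
        "number_infl": m_num_i,
        "mass_infl": m_mass_i,
    }
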