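"""End-to-end orchestration of the vial fitness analysis.

Stages run in a fixed order — contamination filter, vital schedules,
fitness lambda, treatment statistics, perturbation grids, MGWA — each
reading only earlier stages' outputs and writing CSVs plus a JSON
provenance record (config, seed, package version), so a rerun with the
same config is byte-identical and the pipeline is re-entrant from any
stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .vial_data import (
    read_vial_table,
    write_vial_table,
    read_contamination_log,
    write_contamination_log,
    contamination_filter,
    to_survival_records,
    survival_records_to_frame,
)
from .leslie import assemble_schedule, vial_fitness
from .perturbation import permutation_grid, results_to_frames, DEFAULT_FACTOR_DENOMINATORS
from .group_stats import (
    GroupedValues,
    kruskal_wallis,
    dunn_test,
    pairwise_logrank,
    compact_letter_display,
)
from .mgwa import FitnessPanel, read_og_matrix, run_mgwa, shapiro_check
from .synthetic import default_design, simulate_study, simulate_og_matrix, StudyDesign

logger = logging.getLogger("flyfitness")

__all__ = ["PipelineConfig", "run_all", "stage_simulate", "stage_fitness", "stage_stats", "stage_permute", "stage_mgwa"]

_CONFIG_FIELDS = {
    "input_dir",
    "output_dir",
    "extrapolation",
    "censoring",
    "alpha",
    "factor_denominators",
    "perturb_classes",
    "exclude_treatments",
    "threshold_cfu",
    "consecutive_weeks",
    "og_matrix",
    "annotations",
    "seed",
}


@dataclass
class PipelineConfig:
    input_dir: str = "."
    output_dir: str = "results"
    extrapolation: str = "rate"
    censoring: str = "remove"
    alpha: float = 0.05
    factor_denominators: tuple = DEFAULT_FACTOR_DENOMINATORS
    perturb_classes: tuple = (2,)
    exclude_treatments: tuple = ("pathogen",)
    threshold_cfu: float = 200.0
    consecutive_weeks: int = 2
    og_matrix: str | None = None
    annotations: str | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("factor_denominators", "perturb_classes", "exclude_treatments"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def _provenance(cfg: PipelineConfig, out: Path, stage: str) -> None:
    blob = json.dumps(cfg.to_dict(), sort_keys=True)
    record = {
        "stage": stage,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": cfg.seed,
        "flyfitness_version": __version__,
    }
    (out / f"provenance_{stage}.json").write_text(json.dumps(record, indent=2, sort_keys=True))


def _load_kept_vials(cfg: PipelineConfig):
    indir = Path(cfg.input_dir)
    vials = read_vial_table(indir / "vials.csv", indir / "intervals.csv")
    contam_path = indir / "contamination.csv"
    removed: list[str] = []
    if contam_path.exists():
        logs = read_contamination_log(contam_path)
        vials, removed = contamination_filter(
            vials, logs, threshold_cfu=cfg.threshold_cfu, consecutive_weeks=cfg.consecutive_weeks
        )
    return vials, removed


def stage_simulate(cfg: PipelineConfig, design: StudyDesign | None = None) -> Path:
    """Write a synthetic study (vials, intervals, contamination, OG matrix,
    per-treatment truth lambdas) into the input directory."""
    indir = Path(cfg.input_dir)
    indir.mkdir(parents=True, exist_ok=True)
    design = design or default_design(seed=cfg.seed)
    vials, logs, truth = simulate_study(design)
    write_vial_table(vials, indir / "vials.csv", indir / "intervals.csv")
    write_contamination_log(logs, indir / "contamination.csv")
    genome_strains = [a.name for a in design.treatments if a.name not in ("axenic",) and not a.pathogen_like]
    planted = tuple(1 if i < len(genome_strains) // 2 else 0 for i in range(len(genome_strains)))
    og, _shifts = simulate_og_matrix(
        n_ogs=100, strain_ids=genome_strains, planted_pattern=planted, effect_delta=0.0, seed=design.seed
    )
    df = pd.DataFrame(og.presence, columns=og.strain_ids)
    df.insert(0, "og_id", og.og_ids)
    df.to_csv(indir / "og_matrix.csv", index=False)
    (indir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    logger.info("simulated %d vials across %d treatments", len(vials), len(design.treatments))
    return indir


def stage_fitness(cfg: PipelineConfig) -> pd.DataFrame:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    vials, removed = _load_kept_vials(cfg)
    if removed:
        logger.info("contamination filter removed vials: %s", removed)
    fitness = vial_fitness(vials, extrapolation=cfg.extrapolation, censoring=cfg.censoring)
    fitness.to_csv(out / "fitness.csv", index=False)
    survival = survival_records_to_frame(to_survival_records(vials))
    survival.to_csv(out / "survival_records.csv", index=False)
    _provenance(cfg, out, "fitness")
    return fitness


def stage_stats(cfg: PipelineConfig) -> pd.DataFrame:
    out = Path(cfg.output_dir)
    fitness = pd.read_csv(out / "fitness.csv")
    survival = pd.read_csv(out / "survival_records.csv")
    rows = []

    grouped = GroupedValues(fitness["lambda"].tolist(), fitness["treatment"].tolist())
    h, p = kruskal_wallis(grouped)
    dunn = dunn_test(grouped)
    letters = compact_letter_display(dunn, alpha=cfg.alpha).letters
    for g in sorted(letters):
        rows.append(
            {"analysis": "fitness", "test": "kruskal-wallis+dunn", "statistic": h,
             "df": grouped.n_groups() - 1, "p": p, "treatment": g, "letters": letters[g]}
        )

    from .vial_data import SurvivalRecord

    records = [
        SurvivalRecord(r.vial_id, r.treatment, r.time_days, int(r.event))
        for r in survival.itertuples()
    ]
    lr = pairwise_logrank(records)
    lr_letters = compact_letter_display(lr, alpha=cfg.alpha).letters
    for g in sorted(lr_letters):
        rows.append(
            {"analysis": "lifespan", "test": "pairwise-logrank", "statistic": float("nan"),
             "df": 1, "p": float("nan"), "treatment": g, "letters": lr_letters[g]}
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "stats_summary.csv", index=False)
    _provenance(cfg, out, "stats")
    return df


def stage_permute(cfg: PipelineConfig) -> pd.DataFrame:
    out = Path(cfg.output_dir)
    vials, _ = _load_kept_vials(cfg)
    schedules = {
        v.vial_id: assemble_schedule(v, extrapolation=cfg.extrapolation, censoring=cfg.censoring)
        for v in vials
    }
    treatments = {v.vial_id: v.treatment for v in vials}
    factors = tuple(1.0 / d for d in cfg.factor_denominators)
    frames = []
    summaries = []
    for trait in ("survival", "fecundity"):
        results = permutation_grid(
            schedules,
            treatments,
            trait,
            factors=factors,
            classes=cfg.perturb_classes,
            exclude_treatments=cfg.exclude_treatments,
            alpha=cfg.alpha,
        )
        per_vial, summary = results_to_frames(results)
        frames.append(per_vial)
        summaries.append(summary)
    pd.concat(frames, ignore_index=True).to_csv(out / "permutations.csv", index=False)
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(out / "permutation_summary.csv", index=False)
    _provenance(cfg, out, "permute")
    return summary


def stage_mgwa(cfg: PipelineConfig) -> pd.DataFrame | None:
    out = Path(cfg.output_dir)
    og_path = cfg.og_matrix or str(Path(cfg.input_dir) / "og_matrix.csv")
    if not Path(og_path).exists():
        logger.info("no OG matrix at %s; MGWA stage skipped", og_path)
        return None
    og = read_og_matrix(og_path)
    fitness = pd.read_csv(out / "fitness.csv")
    panel_df = fitness.rename(columns={"treatment": "strain_id", "experiment_day": "experiment"})[
        ["vial_id", "strain_id", "experiment", "lambda"]
    ]
    panel_df = panel_df[panel_df["strain_id"].isin(og.strain_ids)].reset_index(drop=True)
    panel = FitnessPanel(data=panel_df, exclusions=tuple(cfg.exclude_treatments))
    w, p = shapiro_check(panel.included()["lambda"])
    logger.info("fitness response Shapiro-Wilk W=%.4f p=%.4g", w, p)
    annotations = None
    if cfg.annotations and Path(cfg.annotations).exists():
        ann = pd.read_csv(cfg.annotations)
        annotations = dict(zip(ann["og_id"].astype(str), ann["annotation"].astype(str)))
    table = run_mgwa(panel, og, annotations=annotations)
    df = table.to_frame(annotations)
    df.to_csv(out / "mgwa_results.csv", index=False)
    _provenance(cfg, out, "mgwa")
    return df


def run_all(cfg: PipelineConfig, simulate: bool = False) -> Path:
    """Run every stage in order; a stage failure halts with its name."""
    stages = ([("simulate", lambda: stage_simulate(cfg))] if simulate else []) + [
        ("fitness", lambda: stage_fitness(cfg)),
        ("stats", lambda: stage_stats(cfg)),
        ("permute", lambda: stage_permute(cfg)),
        ("mgwa", lambda: stage_mgwa(cfg)),
    ]
    for name, fn in stages:
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return Path(cfg.output_dir)
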