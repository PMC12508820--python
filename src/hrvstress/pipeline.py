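"""Orchestration, configuration and on-disk formats for the full pipeline.

Binds the stages — simulate, preprocess, train/evaluate, gee, report — into
one reproducible run driven by a YAML configuration. Every run directory
carries a provenance record (configuration hash, seeds, package version) and
all artifacts are plain text: cohort CSV + config JSON sidecar, per-task
segment matrices (CSV) with JSON metadata, tidy results CSV, coefficient and
contrast CSVs, and a markdown summary.

Seed policy: one global seed; each stage derives its own seed by stable
hashing of (global seed, stage name), so stages are independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import CVConfig, TASKS, run_repeated_cv
from .gee import build_long_table, contrasts_frame, epoch_contrasts, fit_gee, phase_contrasts
from .preprocess import Segment, make_epoch_dataset, make_phase_dataset
from .resnet1d import ModelSpec, TrainConfig
from .synthetic import (
    BeatSeries,
    SimConfig,
    simulate_cohort,
    simulate_recordings,
)

__all__ = [
    "RunConfig",
    "MissingArtifactError",
    "ConfigSchemaError",
    "stable_seed",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_segments",
    "read_segments",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "evaluate", "gee", "report")

COHORT_COLUMNS = [
    "participant_id", "group", "visit", "phase", "beat_index", "time_s", "rri_ms",
]


class MissingArtifactError(FileNotFoundError):
    """An upstream artifact required by a requested stage is absent."""


class ConfigSchemaError(ValueError):
    """The run configuration violates its schema."""


def stable_seed(global_seed: int, *parts) -> int:
    """Deterministic sub-seed below 2**31 from a global seed and labels."""
    digest = hashlib.sha256(repr((global_seed,) + parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_yaml``)."""

    out_dir: Path
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    epoch_model_spec: Optional[ModelSpec] = None
    train: TrainConfig = field(default_factory=TrainConfig)
    reps: int = 10
    folds: int = 10
    tasks: Tuple[str, ...] = tuple(TASKS)
    strategies: Tuple[str, ...] = ("separate", "combined")
    zscore: bool = False
    gee_cov_struct: str = "exchangeable"

    @classmethod
    def from_dict(cls, raw: dict, out_dir: Path) -> "RunConfig":
        known = {
            "seed", "sim", "model", "epoch_model", "train", "evaluation", "gee",
        }
        bad = set(raw) - known
        if bad:
            raise ConfigSchemaError(f"unknown configuration keys: {sorted(bad)}")

        def build(cls_, section: dict, name: str):
            fields = {f.name for f in dataclasses.fields(cls_)}
            bad = set(section) - fields
            if bad:
                raise ConfigSchemaError(f"unknown keys in {name!r}: {sorted(bad)}")
            return cls_(**section)

        seed = int(raw.get("seed", 0))
        sim_raw = dict(raw.get("sim", {}))
        # YAML keys arrive as plain dicts; coerce attendance keys to int
        if "visit_attendance" in sim_raw:
            sim_raw["visit_attendance"] = {
                int(k): v for k, v in sim_raw["visit_attendance"].items()
            }
        sim = build(SimConfig, {**sim_raw, "seed": sim_raw.get("seed", seed)}, "sim")
        model_raw = dict(raw.get("model", {}))
        if "stages" in model_raw:
            model_raw["stages"] = tuple(tuple(s) for s in model_raw["stages"])
        model = build(ModelSpec, model_raw, "model")
        epoch_model = None
        if "epoch_model" in raw:
            em = dict(raw["epoch_model"])
            if "stages" in em:
                em["stages"] = tuple(tuple(s) for s in em["stages"])
            epoch_model = build(ModelSpec, em, "epoch_model")
        train_cfg = build(TrainConfig, dict(raw.get("train", {})), "train")
        ev = dict(raw.get("evaluation", {}))
        gee_raw = dict(raw.get("gee", {}))
        cfg = cls(
            out_dir=out_dir,
            seed=seed,
            sim=sim,
            model_spec=model,
            epoch_model_spec=epoch_model,
            train=train_cfg,
            reps=int(ev.get("reps", 10)),
            folds=int(ev.get("folds", 10)),
            tasks=tuple(ev.get("tasks", tuple(TASKS))),
            strategies=tuple(ev.get("strategies", ("separate", "combined"))),
            zscore=bool(ev.get("zscore", False)),
            gee_cov_struct=str(gee_raw.get("cov_struct", "exchangeable")),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: Path, out_dir: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, out_dir)

    def validate(self) -> None:
        self.sim.validate()
        bad_tasks = set(self.tasks) - set(TASKS)
        if bad_tasks:
            raise ConfigSchemaError(f"unknown tasks: {sorted(bad_tasks)}")
        bad_strategies = set(self.strategies) - {"separate", "combined"}
        if bad_strategies:
            raise ConfigSchemaError(f"unknown strategies: {sorted(bad_strategies)}")
        if self.reps < 1 or self.folds < 2:
            raise ConfigSchemaError("evaluation requires reps >= 1 and folds >= 2")

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def epoch_spec(self) -> ModelSpec:
        if self.epoch_model_spec is not None:
            return self.epoch_model_spec
        return dataclasses.replace(self.model_spec, input_len=240)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


# ---------------------------------------------------------------------------
# Cohort CSV round trip
# ---------------------------------------------------------------------------


def write_cohort_csv(
    recordings: Sequence[BeatSeries], path: Path, sim_config: Optional[SimConfig] = None
) -> None:
    """Write beat series as a tidy CSV plus a JSON sidecar with the SimConfig."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for s in recordings:
        frames.append(pd.DataFrame({
            "participant_id": s.participant_id,
            "group": s.group,
            "visit": s.visit,
            "phase": s.phase,
            "beat_index": np.arange(len(s.rri)),
            "time_s": np.round(s.beat_times, 9),
            "rri_ms": np.round(s.rri, 6),
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=COHORT_COLUMNS))
    df.to_csv(path, index=False, float_format="%.9f")
    if sim_config is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(_jsonable(sim_config), indent=2, sort_keys=True))


def read_cohort_csv(path: Path) -> List[BeatSeries]:
    """Read the cohort CSV back into validated beat series.

    Raises a ValueError naming the offending CSV line for duplicated beat
    indices or non-monotone beat times; an empty (header-only) file yields an
    empty cohort with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise MissingArtifactError(f"cohort CSV not found: {path}")
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s: empty cohort file", path)
        return []
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1
    out: List[BeatSeries] = []
    for (pid, visit, phase), sub in df.groupby(
        ["participant_id", "visit", "phase"], sort=True
    ):
        sub = sub.sort_values("beat_index")
        dup = sub["beat_index"].duplicated()
        if dup.any():
            line = int(sub.loc[dup, "_line"].iloc[0])
            raise ValueError(f"{path}: duplicated beat_index at line {line}")
        times = sub["time_s"].to_numpy()
        if np.any(np.diff(times) <= 0):
            bad = int(np.argmax(np.diff(times) <= 0)) + 1
            line = int(sub["_line"].iloc[bad])
            raise ValueError(f"{path}: non-monotone beat times at line {line}")
        group = str(sub["group"].iloc[0])
        series = BeatSeries(
            participant_id=str(pid), visit=int(visit), phase=str(phase),
            beat_times=times, rri=sub["rri_ms"].to_numpy(), group=group,
        )
        out.append(series)
    return out


# ---------------------------------------------------------------------------
# Segment store
# ---------------------------------------------------------------------------


def write_segments(segments: Sequence[Segment], directory: Path, name: str) -> None:
    """One CSV value matrix + one JSON metadata list per segment collection."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    values = np.stack([s.values for s in segments]) if segments else np.empty((0, 0))
    pd.DataFrame(values).to_csv(directory / f"{name}_values.csv", index=False)
    meta = [
        {"participant_id": s.participant_id, "group": s.group, "visit": s.visit,
         "label": s.label, "n_valid": s.n_valid}
        for s in segments
    ]
    (directory / f"{name}_meta.json").write_text(json.dumps(meta, indent=1))


def read_segments(directory: Path, name: str) -> List[Segment]:
    directory = Path(directory)
    values_path = directory / f"{name}_values.csv"
    meta_path = directory / f"{name}_meta.json"
    for p in (values_path, meta_path):
        if not p.exists():
            raise MissingArtifactError(f"segment artifact not found: {p}")
    values = pd.read_csv(values_path).to_numpy()
    meta = json.loads(meta_path.read_text())
    if len(values) != len(meta):
        raise ValueError(f"{name}: value matrix and metadata lengths differ")
    return [
        Segment(values=values[i], n_valid=m["n_valid"], label=m["label"],
                participant_id=m["participant_id"], group=m["group"],
                visit=m["visit"])
        for i, m in enumerate(meta)
    ]


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------


def _provenance(config: RunConfig) -> dict:
    return {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: stable_seed(config.seed, s) for s in STAGES},
    }


def run_pipeline(config: RunConfig, stages: Iterable[str] = STAGES) -> Dict[str, object]:
    """Run the requested stages in fixed order; returns a summary dict.

    Stage order is simulate -> preprocess -> evaluate -> gee -> report. A
    stage whose inputs were not produced in this run reads them from
    ``config.out_dir``; a missing artifact raises MissingArtifactError naming
    the absent file.
    """
    requested = [s for s in STAGES if s in set(stages)]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigSchemaError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "provenance.json").write_text(json.dumps(_provenance(config), indent=2))

    summary: Dict[str, object] = {"config_hash": config.config_hash()}
    cohort_path = out / "cohort.csv"
    seg_dir = out / "segments"

    if "simulate" in requested:
        cohort = simulate_cohort(config.sim)
        recordings = simulate_recordings(cohort, config.sim)
        write_cohort_csv(recordings, cohort_path, config.sim)
        summary["n_participants"] = len(cohort)
        summary["n_recordings"] = len(recordings)
        logger.info("simulate: %d participants, %d recordings",
                    len(cohort), len(recordings))

    if "preprocess" in requested:
        recordings = read_cohort_csv(cohort_path)
        phase_segs = make_phase_dataset(recordings, zscore=config.zscore)
        epoch_segs = make_epoch_dataset(recordings, zscore=config.zscore)
        write_segments(phase_segs, seg_dir, "phase5min")
        write_segments(epoch_segs, seg_dir, "epoch1min")
        summary["n_phase_segments"] = len(phase_segs)
        summary["n_epoch_segments"] = len(epoch_segs)
        logger.info("preprocess: %d phase segments, %d epoch segments",
                    len(phase_segs), len(epoch_segs))

    if "evaluate" in requested:
        phase_segs = read_segments(seg_dir, "phase5min")
        epoch_segs = read_segments(seg_dir, "epoch1min")
        frames = []
        eval_summary: Dict[str, dict] = {}
        for task in config.tasks:
            segs = phase_segs if task == "phase5min" else epoch_segs
            spec = (config.model_spec if task == "phase5min"
                    else config.epoch_spec())
            for strategy in config.strategies:
                cv_cfg = CVConfig(
                    reps=config.reps, folds=config.folds,
                    seed=stable_seed(config.seed, "evaluate", task, strategy),
                    model_spec=spec, train_config=config.train,
                )
                results = run_repeated_cv(segs, task, strategy, cv_cfg)
                for r in results:
                    frames.append(r.to_frame())
                    eval_summary[f"{task}/{strategy}/{r.group}"] = {
                        m: {"mean": mu, "sd": sd}
                        for m, (mu, sd) in r.aggregate().items()
                    }
        tidy = pd.concat(frames, ignore_index=True)
        tidy.to_csv(out / "cv_results.csv", index=False)
        (out / "cv_summary.json").write_text(json.dumps(eval_summary, indent=2))
        summary["evaluation"] = eval_summary

    if "gee" in requested:
        recordings = read_cohort_csv(cohort_path)
        for model_name, contrast_fn in (
            ("phase5min", phase_contrasts), ("epoch1min", epoch_contrasts)
        ):
            table = build_long_table(recordings, model_name)
            table.to_csv(out / f"gee_{model_name}_long.csv", index=False)
            fit = fit_gee(table, model_name, cov_struct=config.gee_cov_struct)
            fit.coefficient_table().to_csv(
                out / f"gee_{model_name}_coefficients.csv", index=False
            )
            contrasts_frame(contrast_fn(fit)).to_csv(
                out / f"gee_{model_name}_contrasts.csv", index=False
            )
            summary[f"gee_{model_name}_alpha"] = fit.alpha
        logger.info("gee: coefficient and contrast tables written")

    if "report" in requested:
        summary_path = out / "cv_summary.json"
        if not summary_path.exists():
            raise MissingArtifactError(f"evaluation summary not found: {summary_path}")
        report = _markdown_report(json.loads(summary_path.read_text()))
        (out / "report.md").write_text(report)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def _markdown_report(eval_summary: Dict[str, dict]) -> str:
    lines = ["# Classification performance (mean ± SD over repetitions)", ""]
    lines.append("| task | strategy | group | accuracy | AUROC | sensitivity | specificity |")
    lines.append("|---|---|---|---|---|---|---|")
    for key in sorted(eval_summary):
        task, strategy, group = key.split("/")
        m = eval_summary[key]
        cells = " | ".join(
            f"{m[name]['mean']:.3f} ± {m[name]['sd']:.3f}"
            for name in ("accuracy", "auroc", "sensitivity", "specificity")
        )
        lines.append(f"| {task} | {strategy} | {group} | {cells} |")
    lines.append("")
    return "\n".join(lines)
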