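"""End-to-end orchestration: simulate -> segment -> label -> features ->
select -> evaluate, with a YAML-configurable entry point and a run manifest.

Each stage reads its inputs from and writes its artifact into one output
directory, so stages can be rerun individually (on simulated or externally
supplied sessions converted to the session CSV/JSON schema).  Rerunning
with the same configuration reproduces every artifact bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .evaluate import EvalReport, loocv_cross_subject, subject_specific_eval
from .features import build_feature_matrix
from .io import (
    read_feature_matrix,
    read_sessions,
    write_feature_matrix,
    write_ground_truth,
    write_session,
)
from .label import DEFAULT_HR_TOLERANCE, label_repetitions, labels_frame
from .models import ModelSpec, default_specs
from .segment import (
    DEFAULT_CHANNEL,
    DEFAULT_MIN_SEPARATION,
    DEFAULT_PROMINENCE_FRACTION,
    DEFAULT_SMOOTHING_WINDOW,
    detect_repetitions,
)
from .select import DEFAULT_ALPHA, select_features
from .simulate import GeneratorConfig, cohort_ground_truth, generate_cohort

__all__ = ["PipelineConfig", "run", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "features", "select", "evaluate")


@dataclass
class SegmentationParams:
    channel: str = DEFAULT_CHANNEL
    smoothing_window: float = DEFAULT_SMOOTHING_WINDOW
    min_separation: float = DEFAULT_MIN_SEPARATION
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    sessions_dir: str | None = None      # external recordings; skips simulate
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    label_tolerance: float = DEFAULT_HR_TOLERANCE
    selection_alpha: float = DEFAULT_ALPHA
    protocols: tuple[str, ...] = ("subject_specific", "cross_subject")
    k_folds: int = 5
    out_dir: str = "pipeline_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        protocols = tuple(raw.pop("protocols", ("subject_specific", "cross_subject")))
        return cls(generator=gen, segmentation=seg, protocols=protocols, **raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_simulate(config: PipelineConfig, out: Path) -> Path:
    gen = dataclasses.replace(config.generator, seed=config.seed)
    cohort = generate_cohort(gen)
    sessions_dir = out / "sessions"
    for session, _ in cohort:
        write_session(session, sessions_dir)
    write_ground_truth(cohort_ground_truth(cohort), out / "ground_truth.csv")
    logger.info("wrote %d sessions to %s", len(cohort), sessions_dir)
    return sessions_dir


def stage_features(config: PipelineConfig, out: Path) -> pd.DataFrame:
    sessions_dir = Path(config.sessions_dir) if config.sessions_dir else out / "sessions"
    sessions = read_sessions(sessions_dir)
    seg = config.segmentation
    items = []
    all_labeled = []
    for session in sessions:
        reps = detect_repetitions(
            session,
            channel=seg.channel,
            smoothing_window=seg.smoothing_window,
            min_separation=seg.min_separation,
            prominence_fraction=seg.prominence_fraction,
        )
        labeled = label_repetitions(session, reps, tolerance=config.label_tolerance)
        items.append((session, labeled))
        all_labeled.extend(labeled)
    labels_frame(all_labeled).to_csv(out / "labeled_repetitions.csv", index=False)
    matrix = build_feature_matrix(items)
    write_feature_matrix(matrix, out / "feature_matrix.csv")
    logger.info("feature matrix: %d repetitions x %d columns", *matrix.shape)
    return matrix


def stage_select(config: PipelineConfig, out: Path, matrix: pd.DataFrame | None = None):
    if matrix is None:
        matrix = read_feature_matrix(out / "feature_matrix.csv")
    result = select_features(matrix, alpha=config.selection_alpha)
    result.table.to_csv(out / "selection.csv")
    (out / "selected_features.json").write_text(
        json.dumps(result.selected_features, indent=2)
    )
    logger.info("selected %d of %d features", len(result.selected_features),
                len(result.table))
    return result


def stage_evaluate(
    config: PipelineConfig,
    out: Path,
    matrix: pd.DataFrame | None = None,
    selected: list[str] | None = None,
) -> dict[str, EvalReport]:
    if matrix is None:
        matrix = read_feature_matrix(out / "feature_matrix.csv")
    if selected is None:
        selected = json.loads((out / "selected_features.json").read_text())
    specs: list[ModelSpec] = default_specs(seed=config.seed)
    reports: dict[str, EvalReport] = {}
    for protocol in config.protocols:
        if protocol == "subject_specific":
            report = subject_specific_eval(
                matrix, selected, specs, k_folds=config.k_folds, seed=config.seed
            )
        elif protocol == "cross_subject":
            report = loocv_cross_subject(matrix, selected, specs)
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
        (out / f"eval_{protocol}.json").write_text(report.to_json())
        report.to_table().to_csv(out / f"eval_{protocol}.csv")
        reports[protocol] = report
        logger.info("protocol %s:\n%s", protocol, report.to_table().round(1))
    return reports


def run(config: PipelineConfig, stage: str | None = None) -> dict[str, Any]:
    """Run the pipeline (or a single stage) and write a manifest.

    Returns a dict with the artifacts produced: ``matrix``, ``selection``,
    ``reports`` (whichever apply).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Any] = {}
    stages = STAGES if stage is None else (stage,)
    if "simulate" in stages and config.sessions_dir is None:
        stage_simulate(config, out)
    if "features" in stages:
        artifacts["matrix"] = stage_features(config, out)
    if "select" in stages:
        artifacts["selection"] = stage_select(config, out, artifacts.get("matrix"))
    if "evaluate" in stages:
        selected = (
            artifacts["selection"].selected_features
            if "selection" in artifacts else None
        )
        artifacts["reports"] = stage_evaluate(
            config, out, artifacts.get("matrix"), selected
        )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(stages),
        "config": config.to_dict(),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*.*")) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return artifacts
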