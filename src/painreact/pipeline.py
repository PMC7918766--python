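"""End-to-end orchestration: simulate/load -> preprocess -> features ->
labels -> cross-validated experiments -> report bundle.

``run_pipeline`` is the programmatic entry point; the ``painreact`` CLI is a
thin wrapper around it.  Everything downstream of the configuration and the
seed is deterministic, so a repeated run writes byte-identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .classify_eval import TASKS, ClassifierSpec, CVResult, run_cv
from .core_data import (TARGET_RATES, MultimodalRecording, gaussian_smooth,
                        load_recording, resample_channel)
from .eda_decomposition import decompose_eda
from .feature_extraction import (FeatureMatrix, FramingSpec, extract_features,
                                 pool_features, zscore_by_subject)
from .pain_labeling import FrameLabels, LabelingConfig, label_frames
from .synthetic_data import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

DEFAULT_EXPERIMENTS = (
    ("multiclass", "kfold10", "adaboost"),
    ("multiclass", "one_patient_out", "adaboost"),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one experiment batch depends on."""

    source: str = "simulate"                  # "simulate" | "directory"
    input_dir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    resample_targets: dict = field(default_factory=lambda: dict(TARGET_RATES))
    framing: FramingSpec = field(default_factory=FramingSpec)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    feature_mode: str = "scattering"
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    experiments: tuple = DEFAULT_EXPERIMENTS
    runs: int = 10
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.source not in ("simulate", "directory"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "directory" and not self.input_dir:
            raise ValueError("source 'directory' requires input_dir")
        if self.feature_mode not in ("scattering", "stft"):
            raise ValueError(f"unknown feature mode {self.feature_mode!r}")
        for task, scheme, kind in self.experiments:
            if task not in TASKS:
                raise ValueError(f"unknown task {task!r}")
            if scheme not in ("kfold10", "one_patient_out"):
                raise ValueError(f"unknown scheme {scheme!r}")
            if kind not in ("adaboost", "svm"):
                raise ValueError(f"unknown classifier {kind!r}")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "simulation" in kwargs:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        if "framing" in kwargs:
            kwargs["framing"] = FramingSpec(**kwargs["framing"])
        if "labeling" in kwargs:
            kwargs["labeling"] = LabelingConfig(**kwargs["labeling"])
        if "classifier" in kwargs:
            kwargs["classifier"] = ClassifierSpec(**kwargs["classifier"])
        if "experiments" in kwargs:
            kwargs["experiments"] = tuple(tuple(e) for e in kwargs["experiments"])
        return cls(**kwargs)


def preprocess_recording(rec: MultimodalRecording,
                         targets: dict | None = None,
                         smooth_window_s: float = 1.0,
                         **eda_kwargs) -> MultimodalRecording:
    """Resample all channels to the analysis rates, smooth EDA with a 1 s
    Gaussian window, and replace it by its phasic component."""
    targets = dict(TARGET_RATES if targets is None else targets)
    for name, ch in rec.channels.items():
        rec = rec.with_channel(resample_channel(ch, targets.get(name, ch.fs)))
    eda = rec.channels["EDA"]
    eda = gaussian_smooth(eda, max(1, round(smooth_window_s * eda.fs)))
    decomp = decompose_eda(eda, **eda_kwargs)
    return rec.with_channel(replace(eda, samples=decomp.phasic))


@dataclass(frozen=True)
class SubjectResult:
    recording: MultimodalRecording
    features: FeatureMatrix
    labels: FrameLabels


@dataclass(frozen=True)
class ReportBundle:
    subjects: tuple[SubjectResult, ...]
    cv_results: tuple[CVResult, ...]
    config: PipelineConfig

    def results_json(self) -> str:
        return json.dumps([r.to_dict() for r in self.cv_results],
                          indent=1, sort_keys=True)


def load_cohort(config: PipelineConfig) -> list[MultimodalRecording]:
    if config.source == "simulate":
        sim = replace(config.simulation, seed=config.seed)
        return [rec for rec, _ in simulate_cohort(sim)]
    root = Path(config.input_dir)
    dirs = sorted(p for p in root.iterdir() if (p / "session.json").exists())
    if not dirs:
        raise FileNotFoundError(f"no recording directories under {root}")
    return [load_recording(d) for d in dirs]


def prepare_dataset(config: PipelineConfig,
                    recordings=None) -> list[SubjectResult]:
    """Preprocess, extract features, z-score per subject, and label frames."""
    if recordings is None:
        recordings = load_cohort(config)
    prepared = []
    for rec in recordings:
        logger.info("preprocessing subject %s", rec.subject_id)
        pre = preprocess_recording(rec, config.resample_targets)
        feats = extract_features(pre, config.feature_mode, config.framing)
        labels = label_frames(rec.reports, pre.duration, config.framing,
                              config.labeling)
        if len(labels) != feats.n_frames:
            raise RuntimeError(
                f"stage mismatch for subject {rec.subject_id}: "
                f"{feats.n_frames} feature frames vs {len(labels)} labels")
        prepared.append(SubjectResult(pre, feats, labels))
    normalized = zscore_by_subject([s.features for s in prepared])
    return [replace(s, features=f) for s, f in zip(prepared, normalized)]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the configured experiments and (optionally) write outputs."""
    import numpy as np

    subjects = prepare_dataset(config)
    X, subj_ids = pool_features([s.features for s in subjects])
    y = np.concatenate([s.labels.classes for s in subjects])

    results = []
    for task, scheme, kind in config.experiments:
        logger.info("experiment task=%s scheme=%s classifier=%s",
                    task, scheme, kind)
        spec = (config.classifier if config.classifier.kind == kind
                else replace(config.classifier, kind=kind))
        results.append(run_cv(X, y, subj_ids, task, scheme, spec,
                              runs=config.runs, seed=config.seed,
                              feature_mode=config.feature_mode))

    bundle = ReportBundle(subjects=tuple(subjects),
                          cv_results=tuple(results), config=config)
    if config.output_dir:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def _write_bundle(bundle: ReportBundle, out: Path) -> None:
    (out / "features").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(exist_ok=True)
    (out / "results").mkdir(exist_ok=True)
    for s in bundle.subjects:
        sid = s.features.subject_id
        s.features.to_dataframe().to_csv(out / "features" / f"{sid}.csv",
                                         index=False)
        s.labels.to_dataframe().to_csv(out / "labels" / f"{sid}.csv",
                                       index=False)
    (out / "results" / "cv_results.json").write_text(bundle.results_json())
    logger.info("report bundle written to %s", out)
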