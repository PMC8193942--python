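"""End-to-end experiment orchestration.

The two pipelines share everything up to feature extraction: load or
simulate trials, trim every trial of a dataset to one length, detect
oculomotor events.  The summary path then extracts the 76-feature vectors
and runs the classical classifiers (per-fold z-scoring and feature
selection); the ITS path builds the 12-image panels and trains a CNN; the
heatmap path is the spatial-information baseline.  One split plan per run
is shared by all classifiers so the paired Wilcoxon comparisons are valid,
and every artifact (resolved config, split plan, report) is written to the
output directory for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import clone

from .classical import CLASSIFIER_NAMES, make_classifier
from .cnn import CNNClassifier, TrainConfig
from .evaluation import (EvaluationReport, ProtocolResult, SplitPlan,
                         build_report, make_splits, run_protocol,
                         wilcoxon_one_tailed)
from .events import EventConfig, detect_events
from .features import (FEATURE_NAMES, SelectionConfig, extract_feature_table,
                       rank_features, select_best_feature_set,
                       zscore_fit_apply)
from .gaze_io import DatasetConfig, Trial, read_trials, trim_trial
from .imaging import PanelConfig, build_image_panel, gaze_heatmap
from .simulate import GeneratorConfig, generate_dataset, preset

logger = logging.getLogger("gazeits")

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "prepare_trials",
    "prepare_panel_stack",
    "summary_fold_runner",
    "its_fold_runner",
    "resolution_sweep",
]

CNN_NAMES = ("simplenet", "alexnet")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    pipeline: str = "summary"            # summary | its | heatmap
    protocol: str = "person_independent"
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    dataset_preset: str | None = "switch_like"
    data_path: str | None = None
    dataset_config: DatasetConfig | None = None
    generator: GeneratorConfig | None = None
    event_config: EventConfig = field(default_factory=EventConfig)
    panel_config: PanelConfig = field(default_factory=PanelConfig)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    selection: SelectionConfig | None = None   # None => full 14-combo grid
    k_folds: int = 5
    seed: int = 0
    output_dir: str | None = None

    def resolved(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return dataclasses.asdict(v)
            if isinstance(v, tuple):
                return list(v)
            return v
        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}


def prepare_trials(config: ExperimentConfig) -> list[Trial]:
    """Load or simulate, then trim all trials to the dataset length."""
    if config.data_path is not None:
        if config.dataset_config is None:
            raise ValueError("data_path requires dataset_config")
        trials = read_trials(config.data_path, config.dataset_config)
        target = config.dataset_config.trial_length_s
    else:
        gen = config.generator or preset(config.dataset_preset or
                                         "switch_like")
        if config.generator is None:
            gen = dataclasses.replace(gen, seed=config.seed)
        trials = generate_dataset(gen).trials
        target = gen.trial_length_s
    trials = [trim_trial(t, target) for t in trials]
    logger.info("prepared %d trials (target length %.1f s)", len(trials),
                target)
    return trials


def prepare_panel_stack(trials: Sequence[Trial],
                        event_config: EventConfig,
                        panel_config: PanelConfig,
                        heatmap: bool = False
                        ) -> tuple[np.ndarray, pd.DataFrame]:
    """(N, C, s, s) image stack + metadata frame, aligned row for row."""
    stacks, meta = [], []
    for t in trials:
        if heatmap:
            img = gaze_heatmap(t, grid=panel_config.image_size)
            stacks.append(img.matrix[None, :, :])
        else:
            ev_blinks = detect_events(t, event_config).blinks
            panel = build_image_panel(t, ev_blinks, panel_config)
            stacks.append(panel.stack())
        meta.append({"trial_id": t.trial_id,
                     "participant_id": t.participant_id,
                     "task_id": t.task_id, "condition": t.condition})
    return np.stack(stacks).astype(np.float32), pd.DataFrame(meta)


def summary_fold_runner(features: pd.DataFrame, classifier_name: str,
                        selection: SelectionConfig | None, seed: int):
    """Per-fold fit/predict closure for the summary pipeline.

    Normalization, ranking and (optionally) the full (estimator, k) grid
    are fitted inside each training fold; nothing sees test rows.
    """
    X = features[list(FEATURE_NAMES)]
    y = features["condition"].to_numpy()

    def fit_predict(tr: np.ndarray, te: np.ndarray) -> np.ndarray:
        clf = make_classifier(classifier_name, seed)
        Xtr, Xte = X.iloc[tr], X.iloc[te]
        ytr = y[tr]
        if selection is None:
            sel, _, _ = select_best_feature_set(Xtr, ytr, clf, seed=seed)
        else:
            sel = selection
        Xtr_z, Xte_z, _ = zscore_fit_apply(Xtr, Xte)
        names, _ = rank_features(Xtr_z, ytr, sel.estimator, seed=seed)
        cols = names[:sel.k]
        model = clone(clf)
        model.fit(Xtr_z[cols].to_numpy(), ytr)
        return model.predict(Xte_z[cols].to_numpy())

    return fit_predict


def its_fold_runner(stack: np.ndarray, labels: np.ndarray,
                    architecture: str, train_config: TrainConfig, seed: int):
    """Per-fold fit/predict closure for the ITS / heatmap pipeline."""

    def fit_predict(tr: np.ndarray, te: np.ndarray) -> np.ndarray:
        clf = CNNClassifier(architecture=architecture,
                            train_config=train_config, seed=seed)
        clf.fit(stack[tr], labels[tr])
        return clf.predict(stack[te])

    return fit_predict


def run_experiment(config: ExperimentConfig
                   ) -> tuple[EvaluationReport | ProtocolResult, dict]:
    """Execute one full pipeline run; returns (report, artifacts dict).

    With a single classifier a ``ProtocolResult`` is returned instead of a
    pairwise report.
    """
    trials = prepare_trials(config)
    ec, pc, tc = config.event_config, config.panel_config, config.train_config
    logger.info("thresholds: blink %.0f ms, dispersion %.2f deg, "
                "min fixation %.0f ms, image size %d, mtf bins %d",
                ec.blink_min_duration_ms, ec.dispersion_threshold_deg,
                ec.fixation_min_duration_ms, pc.image_size, pc.mtf_bins)

    if config.pipeline == "summary":
        features = extract_feature_table(trials, event_config=ec)
        plan = make_splits(features, config.protocol, k=config.k_folds,
                           seed=config.seed)
        runners = {name: summary_fold_runner(features, name,
                                             config.selection, config.seed)
                   for name in config.classifiers}
        labels = features["condition"].to_numpy()
    elif config.pipeline in ("its", "heatmap"):
        stack, meta = prepare_panel_stack(trials, ec, pc,
                                          heatmap=config.pipeline == "heatmap")
        plan = make_splits(meta, config.protocol, k=config.k_folds,
                           seed=config.seed)
        labels = meta["condition"].to_numpy()
        runners = {name: its_fold_runner(stack, labels, name, tc, config.seed)
                   for name in config.classifiers}
    else:
        raise ValueError(f"unknown pipeline {config.pipeline!r}")

    results = {name: run_protocol(plan, fn, labels)
               for name, fn in runners.items()}
    report = (build_report(results) if len(results) > 1
              else next(iter(results.values())))

    artifacts = {"config": config.resolved(),
                 "splits": plan.assignments,
                 "results": results}
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.resolved(), fh)
        plan.assignments.to_csv(out / "splits.csv", index=False)
        if isinstance(report, EvaluationReport):
            with open(out / "report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            (out / "report.md").write_text(report.rendered_table() + "\n")
        else:
            report.fold_accuracies.to_csv(out / "fold_accuracies.csv",
                                          index=False)
        logger.info("artifacts written to %s", out)
    return report, artifacts


def resolution_sweep(trials: Sequence[Trial], plan: SplitPlan,
                     sizes: Sequence[int] = (12, 24, 36, 48),
                     architecture: str = "simplenet",
                     event_config: EventConfig | None = None,
                     train_config: TrainConfig | None = None,
                     mtf_bins: int = 8, seed: int = 0):
    """Rerun the ITS pipeline at several image sizes with identical splits.

    Returns ``(accuracies, p_values)``: mean accuracy per size and the
    pairwise one-tailed Wilcoxon matrix over the paired per-fold results.
    """
    event_config = event_config or EventConfig()
    train_config = train_config or TrainConfig()
    results: dict[int, ProtocolResult] = {}
    for s in sizes:
        stack, meta = prepare_panel_stack(trials, event_config,
                                          PanelConfig(image_size=s,
                                                      mtf_bins=mtf_bins))
        labels = meta["condition"].to_numpy()
        fn = its_fold_runner(stack, labels, architecture, train_config, seed)
        results[s] = run_protocol(plan, fn, labels)
    accs = {s: r.mean_accuracy for s, r in results.items()}
    p = pd.DataFrame(np.ones((len(sizes), len(sizes))), index=list(sizes),
                     columns=list(sizes))
    for a in sizes:
        for b in sizes:
            if a != b:
                p.loc[a, b] = wilcoxon_one_tailed(
                    results[a].comparison_units,
                    results[b].comparison_units)[0]
    return accs, p
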