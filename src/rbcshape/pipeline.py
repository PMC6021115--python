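"""End-to-end pipeline: generate -> preprocess -> train -> score ->
calibrate -> classify -> report.

Each stage is a thin call into the corresponding module; the pipeline's
job is ordering, seeding and artifact bookkeeping.  All artifacts (loss
log, calibration report, phase diagram, confusion matrix, checkpoint)
embed the config snapshot so a run is reproducible from any of them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibrate as cal
from . import report as rep
from .config import PipelineConfig, stage_seed
from .model import Model, build_model
from .preprocess import mirror_augment, preprocess_images
from .synthetic import (LabeledDataset, ShapeClass, generate_dataset,
                        generate_phase_sweep)
from .trainer import LossTrace, TrainingConfig, rmse, train

__all__ = ["PipelineResult", "run_pipeline", "score_dataset"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    config: PipelineConfig
    model: Model
    trace: LossTrace
    mixture: cal.MixtureFit
    thresholds_sigma: cal.ThresholdSet
    thresholds_adapted: cal.ThresholdSet
    adapted_costs: dict
    eval_scores: np.ndarray
    eval_dataset: LabeledDataset
    phase: rep.PhaseDiagram
    confusion: rep.ConfusionMatrix

    def save(self, out_dir: Path | str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = self.config.to_dict()
        self.model.save(out / "checkpoint.npz", extra={
            "config": cfg,
            "thresholds": self.thresholds_adapted.to_dict()})
        pd.DataFrame(self.trace.iterations,
                     columns=["iteration", "train_rmse"]).merge(
            pd.DataFrame(self.trace.validations,
                         columns=["iteration", "val_rmse"]),
            on="iteration", how="left").to_csv(out / "loss_log.csv",
                                               index=False)
        (out / "calibration.json").write_text(json.dumps({
            "config": cfg,
            "mixture": self.mixture.to_dict(),
            "fit_residual": self.mixture.fit_residual,
            "thresholds_sigma": self.thresholds_sigma.to_dict(),
            "thresholds_adapted": self.thresholds_adapted.to_dict(),
            "adapted_costs": self.adapted_costs,
        }, indent=2))
        self.phase.to_csv(out / "phase_diagram.csv")
        self.confusion.counts.to_csv(out / "confusion_counts.csv")
        self.confusion.percentages.to_csv(out / "confusion_percent.csv")
        (out / "misclassified.json").write_text(json.dumps({
            "false_positives": self.confusion.false_positives,
            "false_negatives": self.confusion.false_negatives}, indent=2))


def score_dataset(model: Model, ds: LabeledDataset, alpha: float = 0.25,
                  sat_frac: float = 0.01, batch: int = 256) -> np.ndarray:
    """Preprocess and score every image of a dataset."""
    X = preprocess_images(ds.images, alpha=alpha, sat_frac=sat_frac)
    return np.concatenate([np.atleast_1d(model.forward(X[i:i + batch]))
                           for i in range(0, len(X), batch)])


def run_pipeline(cfg: PipelineConfig | None = None,
                 out_dir: Path | str | None = None) -> PipelineResult:
    """Run every stage on synthetic data and return/save all artifacts.

    Stages: (1) render the labeled training mix and the pressure sweep with
    the planted croissant-to-slipper transition; (2) contrast-stretch,
    mirror-augment and Tukey-window the training crops; (3) train the
    regression CNN; (4) score the sweep; (5) fit the four-Gaussian mixture
    and derive k-sigma plus adapted thresholds; (6) classify and build the
    phase diagram and, on a held-out balanced test set, the confusion
    matrix.
    """
    if cfg is None:
        cfg = PipelineConfig()
    stage = "generate"
    try:
        train_ds = generate_dataset(cfg.train_counts, cfg.render,
                                    seed=stage_seed(cfg.seed, "generate"))
        sweep = generate_phase_sweep(
            n_per_condition=cfg.sweep_n_per_condition,
            transition_mbar=cfg.sweep_transition_mbar,
            other_fraction=cfg.sweep_other_fraction,
            sheared_peak_fraction=cfg.sweep_sheared_peak,
            params=cfg.render, seed=stage_seed(cfg.seed, "evaluate"))
        log.info("generated %d training and %d sweep images",
                 len(train_ds), len(sweep))

        stage = "preprocess"
        aug = mirror_augment(train_ds)
        X = preprocess_images(aug.images, cfg.tukey_alpha, cfg.sat_frac)
        prepped = LabeledDataset(X, aug.labels, aug.pressures_mbar)

        stage = "train"
        model = build_model(cfg.model_spec(),
                            init_seed=stage_seed(cfg.seed, "init"))
        model, trace = train(model, prepped, cfg.training)
        log.info("training stopped (%s) after %d iterations",
                 trace.stop_reason, len(trace.iterations))

        stage = "score"
        scores = score_dataset(model, sweep, cfg.tukey_alpha, cfg.sat_frac)

        stage = "calibrate"
        hist = cal.score_histogram(scores, cfg.bin_width)
        mixture = cal.fit_four_gaussians(hist)
        th_sigma = cal.thresholds_from_sigma(mixture, cfg.sigma_k)
        grid = cal.default_search_grid(mixture)
        th_adapt, costs = cal.adapt_thresholds(scores, sweep.labels, grid)

        stage = "classify"
        cells = rep.classify_all(scores, th_adapt, references=sweep.labels,
                                 pressures=sweep.pressures_mbar)
        phase = rep.phase_diagram(cells)
        confusion = rep.confusion_matrix(cells)
    except Exception:
        log.exception("pipeline aborted in stage %r", stage)
        raise
    result = PipelineResult(cfg, model, trace, mixture, th_sigma, th_adapt,
                            costs, np.asarray(scores), sweep, phase, confusion)
    if out_dir is not None:
        result.save(out_dir)
    return result
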