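"""End-to-end pipeline: the three experimental series on synthetic data.

Series 1 builds the optimal-punch model: an elite cohort's sessions are
simulated, punches detected and characterized, the top 5 % by punch quality
labeled best, per-hand MLP models trained and cross-validated.  Series 2
scores a novice cohort against the model and fits relative punch quality
against the conformance score.  Series 3 runs the feedback-vs-control
training simulation.

All randomness flows from one global seed through stage-name-derived
substreams, so every stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import classifier, feedback, io, metrics, synthetic
from .signals import (
    SAMPLES_PER_CHANNEL,
    detect_punches,
    estimate_impact_velocity,
    extract_window,
)

logger = logging.getLogger(__name__)

HANDS = ("left", "right")


class GeneratorConfig(BaseModel):
    n_boxers: int = 4
    elite_skill: tuple[float, float] = (0.8, 1.0)
    # second-series cohort spans novice-to-intermediate technique so the
    # conformance axis is exercised across its range
    novice_skill: tuple[float, float] = (0.3, 0.8)
    train_punches: int = 50  # per hand; the full-scale study value is 500
    test_punches: int = 30  # per hand; full-scale 300
    rate: float = synthetic.DEFAULT_RATE
    accel_noise_g: float = synthetic.ACCEL_NOISE_G
    gyro_noise_dps: float = synthetic.GYRO_NOISE_DPS
    force_noise_frac: float = synthetic.FORCE_NOISE_FRAC


class DetectionConfig(BaseModel):
    onset_frac: float = 0.05
    impact_frac: float = 0.5


class ClassifierConfig(BaseModel):
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 0.001
    beta_1: float = 0.9
    beta_2: float = 0.999
    k: int = 10


class FeedbackConfig(BaseModel):
    n_boxers_per_arm: int = 10
    n_sessions: int = 12
    punches_per_session: int = 20
    base_learning_rate: float = 0.0065
    feedback_gain: float = 3.5
    start_skill: float = 0.30


class RunConfig(BaseModel):
    """Full pipeline configuration; round-trips losslessly through JSON."""

    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    feedback: FeedbackConfig = Field(default_factory=FeedbackConfig)
    labeling_fraction: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def hash(self) -> str:
        # out_dir does not affect any computed number
        return io.config_hash(self.model_dump(mode="json", exclude={"out_dir"}))


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % 2**31)


def _mlp_config(cfg: RunConfig, seed: int) -> classifier.MlpConfig:
    c = cfg.classifier
    return classifier.MlpConfig(
        learning_rate=c.learning_rate,
        beta_1=c.beta_1,
        beta_2=c.beta_2,
        epochs=c.epochs,
        batch_size=c.batch_size,
        seed=seed,
    )


def build_events(
    datasets: list[synthetic.PunchDataset],
    detection: DetectionConfig | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Detect and characterize every punch of the given sessions.

    Each punch's force curve is run through the detector; the impact speed
    is integrated from the punch-axis acceleration and the 600-value
    classifier window extracted at the detected impact.  Returns the pooled
    event table and the window matrix (one row per event, aligned with the
    table).  Undetected punches are logged and skipped.
    """
    det = detection or DetectionConfig()
    rows, windows = [], []
    for ds in datasets:
        for i, punch in enumerate(ds.punches):
            events = detect_punches(
                punch.force, det.onset_frac, det.impact_frac
            )
            if not events:
                logger.warning("punch %d of %s: no event detected", i, ds.boxer_id)
                continue
            ev = events[0]
            v = estimate_impact_velocity(punch.segment, ev.onset_time, ev.impact_time)
            windows.append(
                extract_window(punch.segment, ev.impact_time, SAMPLES_PER_CHANNEL)
            )
            rows.append(
                {
                    "punch_id": len(rows),
                    "boxer": ds.boxer_id,
                    "hand": ds.hand,
                    "onset_s": ev.onset_time,
                    "impact_s": ev.impact_time,
                    "peak_s": ev.peak_time,
                    "F_N": ev.F,
                    "t_s": ev.t,
                    "v_mps": v,
                }
            )
    return pd.DataFrame(rows), np.array(windows)


def _one_hot(labels: pd.Series) -> np.ndarray:
    y = np.zeros((len(labels), 2))
    best = (labels == "best").to_numpy()
    y[best, 1] = 1.0
    y[~best, 0] = 1.0
    return y


def _simulate_cohort_sessions(
    cohort, n_punches, hand, seed, gen: GeneratorConfig
) -> list[synthetic.PunchDataset]:
    noise = dict(
        accel_noise_g=gen.accel_noise_g,
        gyro_noise_dps=gen.gyro_noise_dps,
        force_noise_frac=gen.force_noise_frac,
    )
    return [
        synthetic.simulate_session(
            p, n_punches, seed, hand=hand, rate=gen.rate, **noise
        )
        for p in cohort
    ]


@dataclass
class Series1Result:
    events: dict[str, pd.DataFrame]
    windows: dict[str, np.ndarray]
    models: dict[str, classifier.TrainedModel]
    histories: dict[str, classifier.TrainingHistory]
    cv_results: dict[str, classifier.CvResult]
    test_scores: dict[str, classifier.ClassificationScores]
    best_punch_tables: dict[str, pd.DataFrame]


def run_series1(config: RunConfig) -> Series1Result:
    """Collect the optimal-punch dataset and train the per-hand models.

    Generates the elite cohort, simulates training (and held-out test)
    sessions per hand, detects punches, computes quality metrics, labels the
    pooled top fraction as best, trains a model per hand and evaluates it on
    the test sessions, and runs the k-fold cross-validation.
    """
    gen = config.generator
    cohort = synthetic.make_cohort(
        gen.n_boxers, gen.elite_skill, stage_seed(config.seed, "cohort")
    )
    result = Series1Result({}, {}, {}, {}, {}, {}, {})
    for hand in HANDS:
        train_sets = _simulate_cohort_sessions(
            cohort, gen.train_punches, hand,
            stage_seed(config.seed, f"train-{hand}"), gen,
        )
        test_sets = _simulate_cohort_sessions(
            cohort, gen.test_punches, hand,
            stage_seed(config.seed, f"test-{hand}"), gen,
        )
        ev_train, X_train = build_events(train_sets, config.detection)
        ev_test, X_test = build_events(test_sets, config.detection)
        ev_train = metrics.label_best(
            metrics.add_metrics(ev_train), config.labeling_fraction
        )
        ev_test = metrics.label_best(
            metrics.add_metrics(ev_test), config.labeling_fraction
        )
        y_train, y_test = _one_hot(ev_train["label"]), _one_hot(ev_test["label"])

        mlp_cfg = _mlp_config(config, stage_seed(config.seed, f"model-{hand}"))
        model = classifier.build_model(mlp_cfg)
        history = classifier.train(model, X_train, y_train, mlp_cfg)
        scores = classifier.evaluate(model, X_test, y_test)
        cv = classifier.kfold_cv(
            X_train, y_train, config.classifier.k, mlp_cfg,
            seed=stage_seed(config.seed, f"cv-{hand}"),
        )

        # per-boxer best-punch summary, mirroring the published elite tables
        best = (
            ev_train.sort_values("q_p", ascending=False)
            .groupby("boxer")
            .head(1)
            .sort_values("boxer")[["boxer", "F_N", "t_s", "F_eff", "v_mps", "q_p"]]
            .reset_index(drop=True)
        )
        result.events[hand] = ev_train
        result.windows[hand] = X_train
        result.models[hand] = model
        result.histories[hand] = history
        result.cv_results[hand] = cv
        result.test_scores[hand] = scores
        result.best_punch_tables[hand] = best

        if config.out_dir:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            h = config.hash()
            io.write_table_csv(
                out / f"events_{hand}.csv", ev_train, seed=config.seed, cfg_hash=h
            )
            io.write_table_csv(
                out / f"best_punches_{hand}.csv", best, seed=config.seed, cfg_hash=h
            )
            cv_report = {
                "sample": list(range(1, cv.k + 1)),
                "loss": cv.fold_losses,
                "accuracy_pct": [100.0 * a for a in cv.fold_accuracies],
                "summary": cv.summary,
            }
            (out / f"cv_{hand}.json").write_text(json.dumps(cv_report, indent=2))
            (out / f"test_scores_{hand}.json").write_text(
                json.dumps(vars(result.test_scores[hand]), indent=2)
            )
    return result


@dataclass
class Series2Result:
    fit: metrics.QualityFit
    scatter: pd.DataFrame


def run_series2(
    config: RunConfig,
    models: dict[str, classifier.TrainedModel],
    hand: str = "right",
) -> Series2Result:
    """Score a novice cohort against the trained model.

    Computes per-boxer relative punch quality, the conformance score of each
    punch, the degree-2 polynomial fit of q_rp against conformance and their
    Pearson correlation r.
    """
    gen = config.generator
    cohort = synthetic.make_cohort(
        gen.n_boxers, gen.novice_skill, stage_seed(config.seed, "novice-cohort")
    )
    sessions = _simulate_cohort_sessions(
        cohort, gen.train_punches, hand,
        stage_seed(config.seed, f"series2-{hand}"), gen,
    )
    events, X = build_events(sessions, config.detection)
    events = metrics.add_metrics(events, per_boxer=True)
    model = models[hand]
    events["conformance"] = classifier.conformance_score(model, X)
    fit = metrics.fit_quality_vs_conformance(
        events["conformance"], events["q_rp"], max_degree=2
    )
    scatter = events[["boxer", "punch_id", "conformance", "q_rp"]].copy()
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_table_csv(
            out / f"quality_vs_conformance_{hand}.csv",
            scatter,
            seed=config.seed,
            cfg_hash=config.hash(),
        )
        (out / f"quality_fit_{hand}.json").write_text(
            json.dumps(
                {"coefficients": fit.coefficients.tolist(), "r": fit.r}, indent=2
            )
        )
    return Series2Result(fit=fit, scatter=scatter)


def run_series3(
    config: RunConfig,
    models: dict[str, classifier.TrainedModel] | None = None,
    hand: str = "right",
) -> feedback.GroupComparison:
    """Feedback-vs-control training comparison with matched learning configs.

    Two novice cohorts train for a month of sessions: one with the LED
    feedback on, one without.  Scores come from the trained model's
    conformance when models are given, else from relative punch quality.
    """
    fb = config.feedback
    lc = feedback.LearningConfig(
        n_sessions=fb.n_sessions,
        punches_per_session=fb.punches_per_session,
        base_learning_rate=fb.base_learning_rate,
        feedback_gain=fb.feedback_gain,
        start_skill=fb.start_skill,
        seed=stage_seed(config.seed, "series3"),
    )
    model = models[hand] if models else None
    arms = {}
    for arm, feedback_on in (("feedback", True), ("control", False)):
        cohort = synthetic.make_cohort(
            fb.n_boxers_per_arm,
            config.generator.novice_skill,
            stage_seed(config.seed, f"arm-{arm}"),
        )
        arms[arm] = feedback.simulate_training(
            cohort, lc, feedback_on, model=model, hand=hand, group=arm
        )
    comparison = feedback.compare_groups(arms["feedback"], arms["control"])
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        traj = pd.concat([a.to_frame() for a in arms.values()], ignore_index=True)
        io.write_table_csv(
            out / "training_trajectories.csv",
            traj,
            seed=config.seed,
            cfg_hash=config.hash(),
        )
        report = {
            "feedback": comparison.feedback_stats,
            "control": comparison.control_stats,
            "mean_ratio": comparison.mean_ratio,
        }
        (out / "group_comparison.json").write_text(json.dumps(report, indent=2))
    return comparison
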