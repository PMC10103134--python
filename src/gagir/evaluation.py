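"""Evaluation harness: tasks, training-set families, and prediction scores.

Five binary tasks are evaluated — GAG class (HS vs CS) and the presence of
N-, 2-O-, 4-O-, and 6-O-sulfation.  Training sets come in families:

 - leave-one-out over the disaccharide base set (n sets of size n−1),
 - combinatorial augmentation: all size-k subsets of the tetrasaccharides
   added to the full base set (family tag ``X_m=<base+k>``), the remaining
   tetrasaccharides being the evaluation targets,
 - hold-out validation, where one sample (the hexasaccharide) is predicted
   from every training set of a family.

For each (training set, task) a model is trained: evolutionary feature
selection on the training rows only, then a forest on the selected
features.  The *prediction score* is the fraction of correctly classified
excluded samples; the overall score micro-averages all excluded-sample
predictions.  Min–max scaling is per spectrum and selection sees only
training rows, so excluded samples never influence a trained model.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .feature_selection import GAConfig, GAResult, evolve
from .forest import ForestConfig, train_forest
from .spectra import (
    BinningConfig,
    FeatureMatrix,
    SampleMetadata,
    SpectrumLibrary,
    assemble_features,
)

__all__ = [
    "TaskSpec",
    "TrainingSetSpec",
    "SamplePrediction",
    "EvaluationOutcome",
    "EvaluationReport",
    "PipelineConfig",
    "LeakageError",
    "canonical_tasks",
    "loo_sets",
    "augmented_sets",
    "holdout_sets",
    "prediction_score",
    "run_experiment",
    "validate_holdout",
]

logger = logging.getLogger(__name__)


class LeakageError(ValueError):
    """A hold-out sample appears inside a training set."""


@dataclass(frozen=True)
class TaskSpec:
    """One binary classification task; ``label_fn`` yields the positive flag."""

    task_id: str
    description: str
    label_fn: Callable[[SampleMetadata], bool]


def canonical_tasks() -> list[TaskSpec]:
    """The five canonical tasks (class plus four sulfation positions)."""
    return [
        TaskSpec("class_hs_cs", "GAG class (positive = HS)", lambda m: m.gag_class == "HS"),
        TaskSpec("ns", "N-sulfation present", lambda m: m.ns_flag),
        TaskSpec("s2", "2-O-sulfation present", lambda m: m.s2_flag),
        TaskSpec("s4", "4-O-sulfation present", lambda m: m.s4_flag),
        TaskSpec("s6", "6-O-sulfation present", lambda m: m.s6_flag),
    ]


@dataclass(frozen=True)
class TrainingSetSpec:
    included_sample_ids: tuple[str, ...]
    excluded_sample_ids: tuple[str, ...]
    family_tag: str

    def __post_init__(self) -> None:
        if set(self.included_sample_ids) & set(self.excluded_sample_ids):
            raise ValueError("included and excluded sample sets overlap")

    @property
    def m(self) -> int:
        return len(self.included_sample_ids)


def loo_sets(sample_ids: Sequence[str]) -> list[TrainingSetSpec]:
    """One training set per sample, excluding exactly that sample."""
    ids = list(sample_ids)
    if len(ids) < 3:
        raise ValueError("leave-one-out requires at least 3 samples")
    tag = f"X_m={len(ids) - 1}"
    return [
        TrainingSetSpec(
            included_sample_ids=tuple(s for s in ids if s != ex),
            excluded_sample_ids=(ex,),
            family_tag=tag,
        )
        for ex in ids
    ]


def augmented_sets(
    base_ids: Sequence[str],
    addable_ids: Sequence[str],
    k_values: Sequence[int],
) -> list[TrainingSetSpec]:
    """All base ∪ (size-k subset of addables) training sets, for each k.

    The samples excluded from a set are the addables not included; the
    family tag ``X_m=<|base|+k>`` records the training-set size.
    """
    base = tuple(base_ids)
    addable = tuple(addable_ids)
    if set(base) & set(addable):
        raise ValueError("addable_ids must be disjoint from base_ids")
    sets = []
    for k in k_values:
        if k < 0 or k > len(addable):
            raise ValueError(f"cannot choose {k} of {len(addable)} addable samples")
        for subset in combinations(addable, k):
            sets.append(
                TrainingSetSpec(
                    included_sample_ids=base + subset,
                    excluded_sample_ids=tuple(a for a in addable if a not in subset),
                    family_tag=f"X_m={len(base) + k}",
                )
            )
    return sets


def holdout_sets(
    base_ids: Sequence[str], addable_ids: Sequence[str], holdout_id: str
) -> list[TrainingSetSpec]:
    """The largest-m families used for hold-out validation: all sets with
    |addable|−1 addables (one left out each) plus the complete set, each
    evaluated against the single hold-out sample."""
    a = len(addable_ids)
    sets = augmented_sets(base_ids, addable_ids, [a - 1, a])
    return [replace(s, excluded_sample_ids=(holdout_id,)) for s in sets]


@dataclass(frozen=True)
class SamplePrediction:
    sample_id: str
    predicted: bool
    truth: bool
    confidence: float

    @property
    def correct(self) -> bool:
        return self.predicted == self.truth


@dataclass
class EvaluationOutcome:
    """Predictions of one trained model on its excluded samples."""

    training_set: TrainingSetSpec
    task_id: str
    predictions: list[SamplePrediction]
    selected_features: list[str]
    model_digest: str


@dataclass
class EvaluationReport:
    outcomes: list[EvaluationOutcome]
    skipped: list[tuple[TrainingSetSpec, str]]
    n_training_sets: int
    n_tasks: int

    @property
    def model_count(self) -> int:
        return self.n_training_sets * self.n_tasks

    @property
    def trained_count(self) -> int:
        return len(self.outcomes)

    @property
    def set_family_counts(self) -> dict[str, int]:
        seen: dict[TrainingSetSpec, str] = {}
        for o in self.outcomes:
            seen[o.training_set] = o.training_set.family_tag
        for ts, _ in self.skipped:
            seen.setdefault(ts, ts.family_tag)
        return dict(Counter(seen.values()))

    def per_task_scores(self) -> dict[str, float]:
        pools: dict[str, list[SamplePrediction]] = {}
        for o in self.outcomes:
            pools.setdefault(o.task_id, []).extend(o.predictions)
        return {
            t: prediction_score([(p.predicted, p.truth) for p in preds])
            for t, preds in pools.items()
        }

    def overall_score(self) -> float:
        pool = [
            (p.predicted, p.truth) for o in self.outcomes for p in o.predictions
        ]
        return prediction_score(pool)

    def family_scores(self) -> dict[str, float]:
        """Micro-averaged prediction score per training-set family."""
        pools: dict[str, list[tuple[bool, bool]]] = {}
        for o in self.outcomes:
            pools.setdefault(o.training_set.family_tag, []).extend(
                (p.predicted, p.truth) for p in o.predictions
            )
        return {tag: prediction_score(pool) for tag, pool in pools.items()}

    # -- export --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model_count": self.model_count,
            "trained_count": self.trained_count,
            "set_family_counts": self.set_family_counts,
            "per_task_scores": self.per_task_scores(),
            "overall_score": self.overall_score() if self.outcomes else None,
            "family_scores": self.family_scores(),
            "skipped": [
                {"family_tag": ts.family_tag, "excluded": list(ts.excluded_sample_ids), "task_id": t}
                for ts, t in self.skipped
            ],
            "outcomes": [
                {
                    "family_tag": o.training_set.family_tag,
                    "included": list(o.training_set.included_sample_ids),
                    "excluded": list(o.training_set.excluded_sample_ids),
                    "task_id": o.task_id,
                    "selected_features": o.selected_features,
                    "model_digest": o.model_digest,
                    "predictions": [
                        {
                            "sample_id": p.sample_id,
                            "predicted": p.predicted,
                            "truth": p.truth,
                            "confidence": p.confidence,
                        }
                        for p in o.predictions
                    ],
                }
                for o in self.outcomes
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    def to_csv(self, path) -> None:
        rows = [
            {
                "family_tag": o.training_set.family_tag,
                "task_id": o.task_id,
                "excluded_sample": p.sample_id,
                "predicted": int(p.predicted),
                "truth": int(p.truth),
                "correct": int(p.correct),
                "confidence": p.confidence,
            }
            for o in self.outcomes
            for p in o.predictions
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def summary(self) -> str:
        lines = [
            f"models: {self.model_count} ({self.trained_count} trained)",
            f"training-set families: {self.set_family_counts}",
        ]
        for task, score in sorted(self.per_task_scores().items()):
            lines.append(f"prediction score [{task}]: {score:.3f}")
        if self.outcomes:
            lines.append(f"overall prediction score: {self.overall_score():.3f}")
        return "\n".join(lines)


def prediction_score(outcomes: Sequence[tuple[bool, bool]]) -> float:
    """Fraction of correct (predicted, truth) pairs."""
    if not outcomes:
        raise ValueError("prediction score undefined for no outcomes")
    return sum(int(p == t) for p, t in outcomes) / len(outcomes)


@dataclass
class PipelineConfig:
    """End-to-end settings for one experiment battery.

    ``ga`` of ``None`` disables feature selection (all features are used);
    ``fitness_forest`` is the (cheaper) forest used inside the GA fitness,
    ``final_forest`` the one trained per model for the actual predictions.
    Per-model seeds are spawned deterministically from ``seed``.
    """

    seed: int = 0
    binning: BinningConfig = field(default_factory=BinningConfig)
    ga: GAConfig | None = field(default_factory=GAConfig)
    fitness_forest: ForestConfig = field(default_factory=lambda: ForestConfig(n_trees=12))
    final_forest: ForestConfig = field(default_factory=lambda: ForestConfig(n_trees=100))

    @classmethod
    def reduced(cls, seed: int = 0) -> "PipelineConfig":
        """Desk-scale settings: μ=20, λ=40, 20 generations, LOO fitness on a
        15-tree surrogate forest."""
        return cls(
            seed=seed,
            ga=GAConfig(mu=20, lambda_=40, generations=20, cv="loo"),
            fitness_forest=ForestConfig(n_trees=15),
            final_forest=ForestConfig(n_trees=100),
        )


def run_experiment(
    library: SpectrumLibrary,
    training_sets: Sequence[TrainingSetSpec],
    tasks: Sequence[TaskSpec],
    config: PipelineConfig | None = None,
) -> EvaluationReport:
    """Train one model per (training set, task) and score excluded samples."""
    config = config or PipelineConfig()
    features = assemble_features(library, config.binning)
    row_of = {sid: i for i, sid in enumerate(features.sample_ids)}
    meta_of = {m.sample_id: m for _, m in library.samples}
    for ts in training_sets:
        for sid in (*ts.included_sample_ids, *ts.excluded_sample_ids):
            if sid not in row_of:
                raise KeyError(f"sample id {sid!r} not in library")

    outcomes: list[EvaluationOutcome] = []
    skipped: list[tuple[TrainingSetSpec, str]] = []
    for si, ts in enumerate(training_sets):
        rows_in = np.array([row_of[s] for s in ts.included_sample_ids])
        X_in = features.values[rows_in]
        for ti, task in enumerate(tasks):
            y_in = np.array([task.label_fn(meta_of[s]) for s in ts.included_sample_ids])
            if len(set(y_in.tolist())) < 2:
                logger.warning(
                    "skipping task %s on %s: single-class training labels",
                    task.task_id,
                    ts.family_tag,
                )
                skipped.append((ts, task.task_id))
                continue
            s_ga, s_forest = (
                int(v) % 2**31
                for v in np.random.SeedSequence([config.seed, si, ti]).generate_state(2)
            )
            if config.ga is not None:
                ga_cfg = replace(config.ga, seed=s_ga)
                sub = FeatureMatrix(
                    values=X_in,
                    feature_names=features.feature_names,
                    sample_ids=list(ts.included_sample_ids),
                    spectral_bin_count=features.spectral_bin_count,
                    bin_centers=features.bin_centers,
                )
                ga_result = evolve(sub, y_in, ga_cfg, config.fitness_forest)
                active = ga_result.best_mask.active_indices()
                selected = ga_result.selected_feature_names
            else:
                active = np.arange(features.k)
                selected = list(features.feature_names)
            model = train_forest(
                X_in[:, active], y_in, replace(config.final_forest, seed=s_forest)
            )
            predictions = []
            for sid in ts.excluded_sample_ids:
                x = features.values[row_of[sid]][active]
                pred = model.predict_one(x)
                predictions.append(
                    SamplePrediction(
                        sample_id=sid,
                        predicted=bool(pred.label),
                        truth=bool(task.label_fn(meta_of[sid])),
                        confidence=pred.confidence,
                    )
                )
            outcomes.append(
                EvaluationOutcome(
                    training_set=ts,
                    task_id=task.task_id,
                    predictions=predictions,
                    selected_features=selected,
                    model_digest=model.digest(),
                )
            )
    return EvaluationReport(
        outcomes=outcomes,
        skipped=skipped,
        n_training_sets=len(training_sets),
        n_tasks=len(tasks),
    )


def validate_holdout(
    library: SpectrumLibrary,
    training_sets: Sequence[TrainingSetSpec],
    holdout_id: str,
    tasks: Sequence[TaskSpec],
    config: PipelineConfig | None = None,
) -> EvaluationReport:
    """Predict a single hold-out sample from every training set.

    Raises :class:`LeakageError` if the hold-out appears in any training
    set; every outcome has the hold-out as its sole excluded sample.
    """
    for ts in training_sets:
        if holdout_id in ts.included_sample_ids:
            raise LeakageError(
                f"hold-out sample {holdout_id!r} is inside training set "
                f"{ts.family_tag}"
            )
    sets = [replace(ts, excluded_sample_ids=(holdout_id,)) for ts in training_sets]
    return run_experiment(library, sets, tasks, config)
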