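"""End-to-end experiment driver: simulate → features → dataset → models →
reports.

`run_experiment` reproduces the full study design on a synthetic cohort:
generate raw streams, summarize each activity, drop low-activity games,
attach clinician labels, 80/20 stratified split with train-fitted
z-scoring, 10-fold cross-validation for model selection, and holdout
confusion-matrix metrics for the final comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dataset import (
    MIN_MOVEMENTS,
    SplitDataset,
    attach_labels,
    filter_low_activity,
    split_dataset,
)
from .evaluate import (
    ComparisonTables,
    ConfusionMatrix,
    MetricsReport,
    compare_models,
    evaluate_holdout,
)
from .features import CleaningParams, extract_features
from .models import MODEL_KINDS, CVResult, FittedModel, cross_validate, default_spec, train_model
from .simulate import SimulationConfig, iter_streams, simulate_truth_and_assessments


def generate_labeled_features(
    config: SimulationConfig, params: CleaningParams = CleaningParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and return (feature table, assessment table).

    Streams are generated and summarized one at a time, so arbitrarily
    large cohorts fit in memory.
    """
    _, assessments = simulate_truth_and_assessments(config)
    features = extract_features(iter_streams(config), params)
    rows = [
        {
            "patient_id": a.patient_id,
            "max_angle_deg": a.max_angle_deg,
            "min_angle_deg": a.min_angle_deg,
            "assessment": a.assessment,
            "label": a.label,
        }
        for a in assessments
    ]
    return features, pd.DataFrame(
        rows, columns=["patient_id", "max_angle_deg", "min_angle_deg", "assessment", "label"]
    )


@dataclass
class ExperimentResult:
    features: pd.DataFrame
    labeled: pd.DataFrame
    split: SplitDataset
    fitted: dict[str, FittedModel] = field(default_factory=dict)
    cv: dict[str, CVResult] = field(default_factory=dict)
    holdout: dict[str, tuple[MetricsReport, ConfusionMatrix]] = field(default_factory=dict)
    comparison: ComparisonTables | None = None


def run_experiment(
    config: SimulationConfig | None = None,
    params: CleaningParams = CleaningParams(),
    train_fraction: float = 0.8,
    cv_folds: int = 10,
    seed: int = 0,
    model_kinds: tuple[str, ...] = MODEL_KINDS,
    run_cv: bool = True,
    min_movements: int = MIN_MOVEMENTS,
) -> ExperimentResult:
    """Run the whole pipeline on a synthetic cohort.

    One experiment seed derives the cohort, the split, the CV folds and
    every model seed, so a run is fully reproducible.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    features, assessments = generate_labeled_features(config, params)
    labeled = attach_labels(filter_low_activity(features, min_movements), assessments)
    split = split_dataset(labeled, train_fraction=train_fraction, seed=seed, stratified=True)
    train_n = split.train_normalized
    test_n = split.test_normalized

    result = ExperimentResult(features=features, labeled=labeled, split=split)
    for kind in model_kinds:
        spec = default_spec(kind, seed=seed)
        if run_cv:
            result.cv[kind] = cross_validate(spec, train_n, k=cv_folds, seed=seed)
        fitted = train_model(spec, train_n)
        result.fitted[kind] = fitted
        result.holdout[kind] = evaluate_holdout(fitted, test_n)
    result.comparison = compare_models(
        {k: rep for k, (rep, _) in result.holdout.items()},
        result.cv if run_cv else None,
    )
    return result
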