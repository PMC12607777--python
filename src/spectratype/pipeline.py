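"""End-to-end drivers enforcing the stage ordering and leakage contracts.

Training path: spectra → drop_unlabeled → (optional stratified split) →
SMOTE balancing (training portion only) → top-k selection (fit on training
only) → network training.  Prediction path: spectra → align to the frozen
selection → predict; validation data never pass through balancing and are
never re-scored for selection.  Every stage is logged with input/output
shapes so the contracts are auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from . import data_io
from .balancing import LabeledDataset, drop_unlabeled, smote_balance
from .classifier import (
    ModelConfig,
    PredictionResult,
    TrainedModel,
    build_model,
    predict,
    train,
)
from .data_io import (
    EnrichmentMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    LabelMap,
)
from .enrichment import EnrichmentParams, functional_spectra
from .evaluation import MetricsReport, evaluate_dataset
from .feature_selection import SelectedFeatures, align_features, select_top_k

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the training driver needs, with the pipeline's standard defaults."""

    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    smote_k_neighbors: int = 5
    smote_enabled: bool = True
    n_features: int = 2000
    selection_method: str = "regression_f"
    model: ModelConfig = field(default_factory=ModelConfig)
    split: float | None = None  # e.g. 0.70 train fraction in single-cohort mode
    balance_before_split: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.split is not None and not 0.0 < self.split < 1.0:
            raise ValueError("split must lie in (0, 1)")


@dataclass
class TrainResult:
    model: TrainedModel
    selected: SelectedFeatures
    stage_log: list[tuple[str, str]]
    holdout_report: MetricsReport | None = None
    holdout_prediction: PredictionResult | None = None


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _run_stage(log: list, stage: str, fn, *args, **kwargs):
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return result


def _shape_note(obj) -> str:
    if isinstance(obj, EnrichmentMatrix):
        return f"{len(obj.sample_ids)}x{len(obj.set_names)}"
    if isinstance(obj, LabeledDataset):
        return f"{obj.n_samples}x{obj.features.shape[1]}"
    return str(obj)


def _stratified_split(
    data: LabeledDataset, train_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    idx = np.arange(data.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=data.labels,
        random_state=seed,
    )
    def subset(which):
        which = np.sort(which)
        return LabeledDataset(
            sample_ids=[data.sample_ids[i] for i in which],
            features=data.features[which],
            labels=[data.labels[i] for i in which],
            class_order=list(data.class_order),
        )
    return subset(train_idx), subset(test_idx)


def run_train(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    labels: LabelMap,
    config: PipelineConfig | None = None,
) -> TrainResult:
    """Execute the full training pipeline on one cohort."""
    config = config or PipelineConfig()
    log: list[tuple[str, str]] = []

    spectra = _run_stage(log, "enrichment", functional_spectra, expr, sets, config.enrichment)
    log.append(("enrichment", _shape_note(spectra)))

    data = _run_stage(log, "drop_unlabeled", drop_unlabeled, spectra, labels)
    log.append(("drop_unlabeled", _shape_note(data)))

    holdout: LabeledDataset | None = None
    if config.split is not None and not config.balance_before_split:
        data, holdout = _run_stage(log, "split", _stratified_split, data, config.split, config.seed)
        log.append(("split", f"train={data.n_samples} test={holdout.n_samples}"))

    if config.smote_enabled:
        data = _run_stage(
            log, "balance", smote_balance, data,
            k_neighbors=config.smote_k_neighbors, seed=config.seed,
        )
        log.append(("balance", _shape_note(data)))

    if config.split is not None and config.balance_before_split:
        # the order used by the original two-class case study; synthetic
        # neighbours of test points can leak into training under this order
        data, holdout = _run_stage(log, "split", _stratified_split, data, config.split, config.seed)
        log.append(("split", f"train={data.n_samples} test={holdout.n_samples}"))

    k = min(config.n_features, data.features.shape[1])
    if k < config.n_features:
        logger.info("n_features clipped from %d to %d", config.n_features, k)
    train_em = EnrichmentMatrix(
        sample_ids=list(data.sample_ids),
        set_names=list(spectra.set_names),
        scores=data.features,
    )
    selected, reduced = _run_stage(
        log, "select", select_top_k, train_em, data.labels, k, config.selection_method
    )
    log.append(("select", f"k={k}"))

    model_cfg = config.model
    model = _run_stage(
        log, "build", build_model, model_cfg, k, len(data.class_order)
    )
    model.feature_names = list(selected.names)
    train_data = LabeledDataset(
        sample_ids=list(data.sample_ids),
        features=reduced.scores,
        labels=list(data.labels),
        class_order=list(data.class_order),
    )
    if model_cfg.epochs > 0:
        model = _run_stage(log, "train", train, model, train_data, model_cfg)
    else:
        model.class_order = list(data.class_order)
    log.append(("train", f"epochs_run={len(model.training_log)}"))

    holdout_report = holdout_pred = None
    if holdout is not None and holdout.n_samples:
        holdout_em = EnrichmentMatrix(
            sample_ids=list(holdout.sample_ids),
            set_names=list(spectra.set_names),
            scores=holdout.features,
        )
        aligned = align_features(holdout_em, selected)
        holdout_pred = predict(model, aligned)
        holdout_report = evaluate_dataset(
            holdout_pred, dict(zip(holdout.sample_ids, holdout.labels))
        )
        log.append(("evaluate_holdout", f"n={holdout.n_samples}"))

    return TrainResult(
        model=model,
        selected=selected,
        stage_log=log,
        holdout_report=holdout_report,
        holdout_prediction=holdout_pred,
    )


def run_predict(
    model: TrainedModel,
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    labels: LabelMap | None = None,
    enrichment_params: EnrichmentParams | None = None,
) -> tuple[PredictionResult, MetricsReport | None, list[tuple[str, str]]]:
    """Score a new cohort with a trained model.

    The cohort is enriched, aligned to the bundle's frozen feature list
    (no re-selection, no balancing), and predicted; with labels supplied,
    a MetricsReport is computed as well.
    """
    log: list[tuple[str, str]] = []
    missing = [s for s in model.feature_names if s not in sets]
    if missing:
        raise data_io.IncompatibilityError(
            f"gene sets required by the model are absent from the GMT: {missing[:5]}"
        )
    params = enrichment_params or EnrichmentParams()
    spectra = _run_stage(log, "enrichment", functional_spectra, expr, sets, params)
    log.append(("enrichment", _shape_note(spectra)))
    aligned = _run_stage(
        log, "align", align_features, spectra,
        SelectedFeatures(list(model.feature_names), len(model.feature_names)),
    )
    log.append(("align", f"k={len(model.feature_names)}"))
    pred = _run_stage(log, "predict", predict, model, aligned)
    log.append(("predict", f"n={len(pred.sample_ids)}"))
    report = None
    if labels is not None:
        truth = {s: labels.labels[s] for s in pred.sample_ids}
        report = _run_stage(log, "evaluate", evaluate_dataset, pred, truth)
        log.append(("evaluate", f"n={len(pred.sample_ids)}"))
    return pred, report, log
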