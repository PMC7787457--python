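"""Decision thresholds, next-step and per-year trajectory metrics, and
first-layer weight inspection.

Risk scores only become clinical alarms once thresholded. Four rules are
provided, all computed from pooled per-time-step scores on the training
split (the optimized rule additionally needs a validation split):

* frequency — the positive rate k/(m+k) over all training time steps;
* conservative — the mean score p̄ of the true positive-event steps;
* balanced — the midpoint (p̄+n̄)/2 of the positive- and negative-step means;
* optimized — the grid-search threshold (step 0.001 on [0,1], ties to the
  smallest) maximizing F1 on the validation split.

Ranking metrics are AUROC (equal to the Mann–Whitney pairwise statistic,
ties counted half) and AUPRC in the step-function / average-precision
convention, both over pooled (patient, time-step) predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .cohort import Cohort, encode_inputs
from .networks import ContractError, TrainedModel, dhtm_forward, dhtmc_forward
from .rollout import TrajectoryForecast

OPTIMIZED_GRID = np.round(np.arange(0, 1001) * 0.001, 3)


class UndefinedMetricError(ValueError):
    """The metric needs both classes (or at least one positive) present."""


@dataclass
class ThresholdSet:
    """The four decision thresholds plus provenance of how each was computed."""

    frequency: float
    conservative: float
    balanced: float
    optimized: float | None = None
    provenance: dict = field(default_factory=dict)

    def get(self, kind: str) -> float:
        value = getattr(self, kind)
        if value is None:
            raise ContractError(f"threshold {kind!r} was not computed")
        return value


@dataclass
class EvaluationReport:
    auroc: float
    auprc: float
    per_year: pd.DataFrame | None = None
    threshold_kind: str | None = None
    threshold_value: float | None = None

    def to_dict(self) -> dict:
        out = {"auroc": self.auroc, "auprc": self.auprc}
        if self.threshold_kind is not None:
            out["threshold_kind"] = self.threshold_kind
            out["threshold_value"] = self.threshold_value
        if self.per_year is not None:
            out["per_year"] = self.per_year.to_dict(orient="records")
        return out


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def f1_score(labels, predictions) -> float:
    """Harmonic mean of precision and recall; 0 when undefined."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def precision_recall(labels, predictions) -> tuple[float, float]:
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def _check_two_classes(labels) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("metric undefined: only one class present")
    return labels


def auroc(labels, scores) -> float:
    """Area under the ROC curve (Mann–Whitney statistic; ties count half)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(labels, scores) -> float:
    """Area under the precision-recall curve, step-function convention."""
    labels = _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def optimized_threshold(scores, labels, grid=OPTIMIZED_GRID) -> float:
    """Grid-search threshold maximizing F1; ties break to the smallest."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    preds = scores[None, :] >= grid[:, None]
    tp = (preds & (labels == 1)).sum(axis=1)
    fp = (preds & (labels == 0)).sum(axis=1)
    fn = (~preds & (labels == 1)).sum(axis=1)
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    return float(grid[int(np.argmax(f1))])  # argmax returns the first (smallest)


def compute_thresholds(
    train_scores,
    train_labels,
    validation_scores=None,
    validation_labels=None,
    provenance: dict | None = None,
) -> ThresholdSet:
    """All four threshold rules from pooled per-step scores and labels."""
    scores = np.asarray(train_scores, dtype=float)
    labels = np.asarray(train_labels).astype(int)
    k = int(labels.sum())
    m = int(labels.size - k)
    if k == 0:
        raise UndefinedMetricError("no positive time steps: p̄ undefined")
    if m == 0:
        raise UndefinedMetricError("no negative time steps: n̄ undefined")
    p_bar = float(scores[labels == 1].mean())
    n_bar = float(scores[labels == 0].mean())
    optimized = None
    if validation_scores is not None:
        if validation_labels is None:
            raise ValueError("validation labels required with validation scores")
        optimized = optimized_threshold(validation_scores, validation_labels)
    prov = dict(provenance or {})
    prov.setdefault("frequency", "train split, positive steps / all steps")
    prov.setdefault("conservative", "train split, mean score of positive steps")
    prov.setdefault("balanced", "train split, midpoint of class mean scores")
    if optimized is not None:
        prov.setdefault("optimized", "validation split, F1 grid search (step 0.001)")
    return ThresholdSet(
        frequency=k / (m + k),
        conservative=p_bar,
        balanced=(p_bar + n_bar) / 2.0,
        optimized=optimized,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def pooled_next_step_scores(
    model: TrainedModel, cohort: Cohort, split: str | None = "test",
    chunk: int = 256,
):
    """Next-step scores and labels pooled over all (patient, step) pairs."""
    patients = (
        cohort.patients if split is None
        else [p for p in cohort.patients if cohort.split.get(p.patient_id) == split]
    )
    if not patients:
        raise ContractError(f"no patients in split {split!r}")
    all_scores, all_labels = [], []
    for start in range(0, len(patients), chunk):
        group = patients[start : start + chunk]
        encoded = [encode_inputs(p) for p in group]
        lengths = [e[0].shape[0] for e in encoded]
        T = max(lengths)
        X = np.zeros((len(group), T, model.spec.input_width))
        for i, (Xi, _) in enumerate(encoded):
            X[i, : lengths[i]] = Xi
        if model.spec.variant == "dhtm_c":
            _, probs = dhtmc_forward(model, X)
        else:
            probs = dhtm_forward(model, X)
        for i, (_, yi) in enumerate(encoded):
            all_scores.append(probs[i, : lengths[i]])
            all_labels.append(yi)
    return np.concatenate(all_labels), np.concatenate(all_scores)


def evaluate_next_step(
    model: TrainedModel, cohort: Cohort, split: str | None = "test"
) -> EvaluationReport:
    """Task-1 evaluation: AUROC/AUPRC over pooled next-step predictions."""
    labels, scores = pooled_next_step_scores(model, cohort, split)
    return EvaluationReport(auroc=auroc(labels, scores), auprc=auprc(labels, scores))


def evaluate_trajectory(
    forecasts: list[TrajectoryForecast],
    cohort: Cohort,
    threshold_set: ThresholdSet,
    threshold_kind: str = "conservative",
    n_years: int = 10,
    cumulative: bool = False,
) -> EvaluationReport:
    """Per-year trajectory metrics against the true future labels.

    Year y (1-based) pools horizon steps 2y−1 and 2y across patients; the
    chosen threshold binarizes the forecast probabilities for F1, precision
    and recall, while AUROC/AUPRC per year use the raw scores (NaN when the
    year is single-class). ``cumulative`` instead pools years 1..y.
    """
    threshold = threshold_set.get(threshold_kind)
    timelines = {p.patient_id: p for p in cohort.patients}
    year_scores: list[list[float]] = [[] for _ in range(n_years)]
    year_labels: list[list[int]] = [[] for _ in range(n_years)]
    for fc in forecasts:
        if fc.horizon < 2 * n_years:
            raise ContractError(
                f"patient {fc.patient_id}: horizon {fc.horizon} shorter than "
                f"{n_years} years ({2 * n_years} steps)"
            )
        tl = timelines[fc.patient_id]
        hf = tl.hf
        for year in range(1, n_years + 1):
            for step in (2 * year - 2, 2 * year - 1):  # 0-based horizon steps
                t_abs = fc.observed_steps + step
                if t_abs >= len(hf):
                    raise ContractError(
                        f"patient {fc.patient_id}: no true label at step {t_abs}"
                    )
                year_scores[year - 1].append(float(fc.hf_probs[step]))
                year_labels[year - 1].append(int(hf[t_abs]))

    rows = []
    pooled_scores: list[float] = []
    pooled_labels: list[int] = []
    for year in range(1, n_years + 1):
        if cumulative:
            pooled_scores += year_scores[year - 1]
            pooled_labels += year_labels[year - 1]
            s = np.asarray(pooled_scores)
            l = np.asarray(pooled_labels)
        else:
            s = np.asarray(year_scores[year - 1])
            l = np.asarray(year_labels[year - 1])
        preds = (s >= threshold).astype(int)
        precision, recall = precision_recall(l, preds)
        single_class = len(np.unique(l)) < 2
        rows.append(
            {
                "year": year,
                "f1": f1_score(l, preds),
                "precision": precision,
                "recall": recall,
                "auroc": np.nan if single_class else auroc(l, s),
                "auprc": np.nan if single_class else auprc(l, s),
            }
        )
    per_year = pd.DataFrame(rows)
    all_s = np.concatenate([np.asarray(v) for v in year_scores])
    all_l = np.concatenate([np.asarray(v) for v in year_labels])
    single = len(np.unique(all_l)) < 2
    return EvaluationReport(
        auroc=np.nan if single else auroc(all_l, all_s),
        auprc=np.nan if single else auprc(all_l, all_s),
        per_year=per_year,
        threshold_kind=threshold_kind,
        threshold_value=threshold,
    )


def inspect_input_weights(model: TrainedModel) -> pd.DataFrame:
    """Signed first-dense-layer weights, one row per input variable.

    The returned frame has shape (input_width, hidden_width); take
    ``.abs()`` for the magnitudes used in Hinton-style plots. Rows are
    labeled with the model's feature-encoding contract when available.
    """
    W = model.network.dense_in.W.data
    names = (
        model.feature_names
        if len(model.feature_names) == W.shape[0]
        else [f"input_{i}" for i in range(W.shape[0])]
    )
    return pd.DataFrame(
        W, index=names, columns=[f"h{j}" for j in range(W.shape[1])]
    )
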