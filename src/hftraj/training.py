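"""Objectives, patient-level splits, the training loop and static baselines.

The event label is heavily imbalanced — a patient hospitalizes for heart
failure at only a few of their (up to hundreds of) time steps — so the
default objective is the α-weighted focal loss

    F(y, ŷ) = Σ −α (1−ŷ)^β y log ŷ − (1−α) ŷ^β (1−y) log(1−ŷ)

with α = 0.25 and β = 2, which down-weights well-classified (mostly
negative) steps. β = 0 recovers the α-weighted cross-entropy exactly. For
the multi-task variant the heart-failure channel and the three acute
co-morbidity channels are summed with equal weight, so the total decomposes
exactly into an HF term plus a CM term.

Sequences of unequal length are padded to the batch maximum with a
step-level mask; masked steps contribute zero loss. The per-batch reduction
is sum over time steps, mean over patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .cohort import Cohort, INPUT_COLUMNS, encode_inputs
from .networks import ModelSpec, TrainedModel, build_network

PROB_EPS = 1e-7  # probabilities are clamped to [eps, 1-eps] before logs


class TrainingError(RuntimeError):
    """Training diverged or preconditions were violated."""


@dataclass
class LossConfig:
    kind: str = "focal"  # "focal" or "cross_entropy"
    alpha: float = 0.25
    beta: float = 2.0
    reduction: str = "sum"

    def __post_init__(self):
        if self.kind not in ("focal", "cross_entropy"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0,1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.reduction not in ("sum", "mean"):
            raise ValueError(f"unknown reduction {self.reduction!r}")


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.6375, 0.1125, 0.25)

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _ce_elem(y, p):
    p = ad.clip(ad.as_tensor(p), PROB_EPS, 1.0 - PROB_EPS)
    y = ad.as_tensor(y)
    return -1.0 * (y * ad.log(p)) - (1.0 - y) * ad.log(1.0 - p)


def _focal_elem(y, p, alpha: float, beta: float):
    p = ad.clip(ad.as_tensor(p), PROB_EPS, 1.0 - PROB_EPS)
    y = ad.as_tensor(y)
    pos = -alpha * ((1.0 - p) ** beta) * y * ad.log(p)
    neg = -(1.0 - alpha) * (p ** beta) * (1.0 - y) * ad.log(1.0 - p)
    return pos + neg


def _loss_elem(y, p, config: LossConfig):
    if config.kind == "cross_entropy":
        return _ce_elem(y, p)
    return _focal_elem(y, p, config.alpha, config.beta)


def _reduce(elem, reduction: str):
    return elem.mean() if reduction == "mean" else elem.sum()


def cross_entropy(y, yhat, reduction: str = "sum") -> float:
    """Binary cross-entropy Σ −y log ŷ − (1−y) log(1−ŷ)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {yhat.shape}")
    return float(_reduce(_ce_elem(y, yhat), reduction).data)


def focal_loss(y, yhat, alpha: float = 0.25, beta: float = 2.0,
               reduction: str = "sum") -> float:
    """α-weighted focal loss; reduces to α-weighted cross-entropy at β=0."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {yhat.shape}")
    return float(_reduce(_focal_elem(y, yhat, alpha, beta), reduction).data)


def multi_task_loss(targets, outputs, config: LossConfig | None = None,
                    return_components: bool = False):
    """Equal-weight sum of per-channel losses; channel 0 is heart failure.

    ``targets`` and ``outputs`` are (n, channels) with the HF channel first
    and the acute-CM channels after; the total decomposes exactly as
    HF-loss + CM-loss.
    """
    config = config or LossConfig()
    targets = np.asarray(targets, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if targets.shape != outputs.shape or targets.ndim != 2:
        raise ValueError(
            f"expected matching (n, channels) arrays, got {targets.shape} vs {outputs.shape}"
        )
    per_channel = [
        float(_reduce(_loss_elem(targets[:, j], outputs[:, j], config),
                      config.reduction).data)
        for j in range(targets.shape[1])
    ]
    hf = per_channel[0]
    cm = float(sum(per_channel[1:]))
    return (hf + cm, hf, cm) if return_components else hf + cm


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_cohort(cohort: Cohort,
                 fractions: tuple[float, float, float] = (0.6375, 0.1125, 0.25),
                 seed: int = 0) -> Cohort:
    """Patient-level random train/validation/test partition.

    Validation and test sizes are floored; the remainder goes to train.
    Deterministic under ``seed``; every time step of a patient lands in that
    patient's split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = sorted(cohort.patient_ids())
    n = len(ids)
    n_splits = sum(1 for f in fractions if f > 0)
    if n < n_splits:
        raise TrainingError(f"{n} patients cannot fill {n_splits} splits")
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    order = np.random.default_rng(seed).permutation(n)
    split: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            split[ids[idx]] = "train"
        elif rank < n_train + n_val:
            split[ids[idx]] = "validation"
        else:
            split[ids[idx]] = "test"
    return Cohort(cohort.patients, split)


# ---------------------------------------------------------------------------
# sequence batching
# ---------------------------------------------------------------------------

def build_training_arrays(cohort: Cohort, split: str | None = "train",
                          with_cm: bool = False):
    """Padded next-step arrays for a split: X (B,T,20), y (B,T), mask (B,T)
    and, when ``with_cm``, the acute-CM targets c (B,T,3)."""
    patients = (
        cohort.patients if split is None
        else [p for p in cohort.patients if cohort.split.get(p.patient_id) == split]
    )
    if not patients:
        raise TrainingError(f"no patients in split {split!r}")
    encoded = [encode_inputs(p, with_cm_targets=with_cm) for p in patients]
    lengths = [e[0].shape[0] for e in encoded]
    B, T = len(encoded), max(lengths)
    X = np.zeros((B, T, len(INPUT_COLUMNS)))
    y = np.zeros((B, T))
    mask = np.zeros((B, T))
    c = np.zeros((B, T, 3)) if with_cm else None
    for i, enc in enumerate(encoded):
        t = lengths[i]
        X[i, :t] = enc[0]
        y[i, :t] = enc[1]
        mask[i, :t] = 1.0
        if with_cm:
            c[i, :t] = enc[2]
    ids = [p.patient_id for p in patients]
    return (X, y, c, mask, ids) if with_cm else (X, y, mask, ids)


def _fit_normalization(X: np.ndarray, mask: np.ndarray):
    """Center every input column; scale only columns with spread above 1.

    Binary indicators keep their natural unit scale, while age (tens of
    years) is brought to unit order so the fan-in-scaled initial weights
    start the gates in their sensitive range.
    """
    w = mask[:, :, None]
    total = w.sum()
    mean = (X * w).sum(axis=(0, 1)) / total
    var = (((X - mean) ** 2) * w).sum(axis=(0, 1)) / total
    std = np.maximum(np.sqrt(var), 1.0)
    return mean, std


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(model_spec: ModelSpec, cohort: Cohort,
          loss_config: LossConfig | None = None,
          train_config: TrainConfig | None = None):
    """Teacher-forced gradient training on the cohort's train split.

    Observed heart-failure and acute-CM indicators are used as next-step
    inputs; the objective is the configured loss on the next-step targets
    (HF only for dhtm/lstm; HF plus the three acute CMs for dhtm_c).
    Returns ``(TrainedModel, history)`` where ``history`` is a per-epoch
    DataFrame with columns epoch, total_loss, hf_loss, cm_loss (per-patient
    means over the epoch). Deterministic under a fixed seed.
    """
    loss_config = loss_config or LossConfig()
    train_config = train_config or TrainConfig()
    multi_task = model_spec.variant == "dhtm_c"

    if multi_task:
        X, y, c, mask, _ = build_training_arrays(cohort, "train", with_cm=True)
    else:
        X, y, mask, _ = build_training_arrays(cohort, "train", with_cm=False)
        c = None

    mean, std = _fit_normalization(X, mask)
    Xn = (X - mean) / std

    network = build_network(model_spec, seed=train_config.seed)
    params = network.params()
    opt = Adam(params, lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)

    n = X.shape[0]
    history = []
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        hf_total = 0.0
        cm_total = 0.0
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            xb, yb, mb = Xn[idx], y[idx], mask[idx]
            cb = c[idx] if multi_task else None
            B, T, _ = xb.shape
            # drop all-padding trailing steps for this batch
            T_eff = int(mb.any(axis=0).sum())

            state = network.init_state(B)
            hf_loss_sum = None
            cm_loss_sum = None
            for t in range(T_eff):
                state, out = network.step(state, Tensor(xb[:, t, :]))
                m_t = mb[:, t : t + 1]
                p_hf = ad.sigmoid(out["hf_logit"])
                elem = _loss_elem(yb[:, t : t + 1], p_hf, loss_config) * m_t
                s = elem.sum()
                hf_loss_sum = s if hf_loss_sum is None else hf_loss_sum + s
                if multi_task:
                    p_cm = out["cm_probs"]
                    elem_cm = _loss_elem(cb[:, t, :], p_cm, loss_config) * m_t
                    s_cm = elem_cm.sum()
                    cm_loss_sum = s_cm if cm_loss_sum is None else cm_loss_sum + s_cm

            batch_loss = hf_loss_sum if cm_loss_sum is None else hf_loss_sum + cm_loss_sum
            batch_loss = batch_loss * (1.0 / B)
            if not np.isfinite(batch_loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            ad.backward(batch_loss)
            opt.step()

            hf_total += float(hf_loss_sum.data)
            if multi_task:
                cm_total += float(cm_loss_sum.data)

        history.append(
            {
                "epoch": epoch,
                "total_loss": (hf_total + cm_total) / n,
                "hf_loss": hf_total / n,
                "cm_loss": cm_total / n,
            }
        )

    model = TrainedModel(
        spec=model_spec,
        network=network,
        feature_names=list(INPUT_COLUMNS),
        input_mean=mean,
        input_std=std,
    )
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# static baselines
# ---------------------------------------------------------------------------

@dataclass
class BaselineModel:
    """A static next-step model over flattened (input at t-1 → label at t) rows."""

    kind: str
    estimator: object
    calibrator: object | None = None
    feature_names: list[str] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kind == "logreg_l2":
            return self.estimator.predict_proba(X)[:, 1]
        decision = self.estimator.decision_function(X)
        return self.calibrator.predict_proba(decision[:, None])[:, 1]


def flatten_rows(cohort: Cohort, split: str | None = "train"):
    """Independent (input, next-step label) rows pooled over the split."""
    patients = (
        cohort.patients if split is None
        else [p for p in cohort.patients if cohort.split.get(p.patient_id) == split]
    )
    if not patients:
        raise TrainingError(f"no patients in split {split!r}")
    Xs, ys = [], []
    for p in patients:
        X, y = encode_inputs(p)
        Xs.append(X)
        ys.append(y)
    return np.vstack(Xs), np.concatenate(ys)


def fit_static_baseline(kind: str, cohort: Cohort, C: float = 1.0,
                        seed: int = 0) -> BaselineModel:
    """Fit a logistic-regression (L2) or linear-SVM next-step baseline.

    The SVM's decision values are mapped to probabilities through a
    Platt-style sigmoid fitted on the training rows.
    """
    if kind not in ("logreg_l2", "linear_svm"):
        raise ValueError(f"unknown baseline kind {kind!r}")
    X, y = flatten_rows(cohort, "train")
    if len(np.unique(y)) < 2:
        raise TrainingError("degenerate fit: training labels contain one class")
    if kind == "logreg_l2":
        # default penalty is the L2 norm
        est = LogisticRegression(C=C, max_iter=2000, random_state=seed)
        est.fit(X, y)
        return BaselineModel(kind, est, feature_names=list(INPUT_COLUMNS))
    est = LinearSVC(C=C, random_state=seed)
    est.fit(X, y)
    decision = est.decision_function(X)
    calibrator = LogisticRegression(max_iter=2000)
    calibrator.fit(decision[:, None], y)
    return BaselineModel(kind, est, calibrator, list(INPUT_COLUMNS))
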