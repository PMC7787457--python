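"""Auto-regressive multi-year heart-failure trajectory forecasting.

A trained recurrent model first builds hidden state over a patient's
observed 6-month steps (teacher-forced with the observed inputs). For each
future step the covariates are frozen at their last observed values and the
model's own predicted heart-failure probability replaces the observed HFH
input channel; the multi-task variant also feeds back its three predicted
acute co-morbidity probabilities. The process can continue for an arbitrary
horizon, yielding a per-step risk trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, sigmoid
from .cohort import (
    ACUTE_CM_COLUMNS,
    INPUT_COLUMNS,
    Cohort,
    PatientTimeline,
    STEP_YEARS,
)
from .networks import ContractError, TrainedModel

HF_IDX = INPUT_COLUMNS.index("hf")
AGE_IDX = INPUT_COLUMNS.index("age")
ACUTE_IDX = [INPUT_COLUMNS.index(c) for c in ACUTE_CM_COLUMNS]


@dataclass
class TrajectoryForecast:
    """Predicted risk trajectory for one patient.

    ``observed_steps`` is the timeline index of the first forecast step, so
    ``hf_probs[j]`` is the predicted probability of HFH at timeline step
    ``observed_steps + j``. ``cm_probs`` is present only for the multi-task
    variant.
    """

    patient_id: str
    observed_steps: int
    horizon: int
    hf_probs: np.ndarray
    cm_probs: np.ndarray | None = None


def _step_probs(model: TrainedModel, state, x_raw: np.ndarray):
    """One stateful forward step on a raw (unnormalized) input vector."""
    x = model.encode(x_raw[None, :])
    state, out = model.network.step(state, Tensor(x))
    hf = float(sigmoid(out["hf_logit"]).data[0, 0])
    cm = out["cm_probs"].data[0] if "cm_probs" in out else None
    return state, hf, cm


def rollout(
    model: TrainedModel,
    observed: PatientTimeline,
    horizon: int,
    feedback: str = "probability",
    feedback_threshold: float = 0.5,
    advance_age: bool = False,
    cadence: int = 1,
) -> TrajectoryForecast:
    """Forecast ``horizon`` future steps after an observed timeline prefix.

    ``feedback`` chooses whether the raw predicted probability or a value
    binarized at ``feedback_threshold`` is fed back as the next HFH (and
    acute-CM) input. Ages are frozen at the last observed value by default;
    ``advance_age`` instead advances them half a year per future step.
    ``cadence`` controls how often fed-back inputs are refreshed (1 = every
    step). Deterministic given the model and inputs.
    """
    if horizon < 0:
        raise ContractError(f"horizon must be >= 0, got {horizon}")
    if len(observed.data) < 1:
        raise ContractError("observed window must contain at least one step")
    if feedback not in ("probability", "binary"):
        raise ContractError(f"unknown feedback mode {feedback!r}")
    if cadence < 1:
        raise ContractError("cadence must be >= 1")

    X_obs = observed.data[INPUT_COLUMNS].to_numpy(dtype=float)
    multi_task = model.spec.variant == "dhtm_c"

    state = model.network.init_state(1)
    hf_pred = cm_pred = None
    for i in range(len(X_obs)):
        state, hf_pred, cm_pred = _step_probs(model, state, X_obs[i])

    hf_probs = np.empty(horizon)
    cm_probs = np.empty((horizon, len(ACUTE_IDX))) if multi_task else None
    x = X_obs[-1].copy()  # covariates frozen at the last observed step
    for j in range(horizon):
        # prediction emitted at the previous step is the risk for this step
        hf_probs[j] = hf_pred
        if multi_task:
            cm_probs[j] = cm_pred
        if j == horizon - 1:
            break
        if j % cadence == 0:
            fb_hf = hf_pred if feedback == "probability" else float(
                hf_pred >= feedback_threshold
            )
            x[HF_IDX] = fb_hf
            if multi_task:
                fb_cm = cm_pred if feedback == "probability" else (
                    cm_pred >= feedback_threshold
                ).astype(float)
                x[ACUTE_IDX] = fb_cm
        if advance_age:
            x[AGE_IDX] += STEP_YEARS
        state, hf_pred, cm_pred = _step_probs(model, state, x)

    return TrajectoryForecast(
        patient_id=observed.patient_id,
        observed_steps=len(X_obs),
        horizon=horizon,
        hf_probs=hf_probs,
        cm_probs=cm_probs,
    )


def batch_rollout(
    model: TrainedModel,
    cohort: Cohort,
    observed_years: float = 15.0,
    horizon_years: float = 10.0,
    start_age: float = 40.0,
    **rollout_kwargs,
):
    """Roll out every eligible patient: the observed window is the first
    ``observed_years`` of 6-month steps at or above ``start_age``.

    Returns ``(forecasts, skipped)``; patients with fewer observed steps
    than the window are skipped and listed with the reason. Each forecast's
    ``observed_steps`` is the absolute timeline index of its first future
    step, so true labels align as ``timeline.hf[observed_steps + j]``.
    """
    n_obs = int(round(observed_years / STEP_YEARS))
    horizon = int(round(horizon_years / STEP_YEARS))
    forecasts: list[TrajectoryForecast] = []
    skipped: list[dict] = []
    for p in cohort.patients:
        eligible = np.flatnonzero(p.ages >= start_age - 1e-9)
        if eligible.size < n_obs:
            skipped.append(
                {
                    "patient_id": p.patient_id,
                    "reason": f"only {eligible.size} steps at age >= {start_age}, "
                              f"need {n_obs}",
                }
            )
            continue
        base = int(eligible[0])
        prefix = PatientTimeline(
            p.patient_id,
            p.data.iloc[base : base + n_obs].reset_index(drop=True),
        )
        fc = rollout(model, prefix, horizon, **rollout_kwargs)
        fc.observed_steps = base + n_obs  # absolute index of first future step
        forecasts.append(fc)
    return forecasts, skipped
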