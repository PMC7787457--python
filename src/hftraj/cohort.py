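"""Longitudinal cohort data model for recurrent heart-failure prediction.

Patient records are discretized into 6-month time steps. Each step carries a
19-number covariate vector — age in years, two one-hot sex indicators, four
one-hot congenital-lesion-type indicators, 11 binary co-morbidity (CM)
indicators and a cumulative surgery count — plus the binary heart-failure
hospitalization (HFH) label for that step. The model input at step i is the
covariate vector together with the step-i HFH indicator (20 numbers); the
training target is the HFH indicator at step i+1, optionally joined by the
three acute CM indicators (acute myocardial infarction, infective
endocarditis, sepsis) at i+1 for the multi-task variant.

This module also implements the cohort-comparison statistics used to contrast
HF-positive and HF-negative patients: the base-2 log proportion ratio and a
binomial enrichment test against a fixed background rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

STEP_YEARS = 0.5  # width of one time bin

#: covariate column order; the on-disk CSV carries patient_id, step, these, hf
COVARIATE_COLUMNS = [
    "age",
    "sex_m",
    "sex_f",
    "lesion_severe",
    "lesion_shunt",
    "lesion_valve",
    "lesion_other",
    "cm_acute_mi",
    "cm_cad",
    "cm_arrhythmia",
    "cm_vent_arrhythmia",
    "cm_pulm_htn",
    "cm_endocarditis",
    "cm_diabetes",
    "cm_stroke",
    "cm_liver",
    "cm_kidney",
    "cm_sepsis",
    "surgery",
]

CM_COLUMNS = [c for c in COVARIATE_COLUMNS if c.startswith("cm_")]
ACUTE_CM_COLUMNS = ["cm_acute_mi", "cm_endocarditis", "cm_sepsis"]
STATIC_CM_COLUMNS = [c for c in CM_COLUMNS if c not in ACUTE_CM_COLUMNS]
SEX_COLUMNS = ["sex_m", "sex_f"]
LESION_COLUMNS = ["lesion_severe", "lesion_shunt", "lesion_valve", "lesion_other"]
BINARY_COLUMNS = SEX_COLUMNS + LESION_COLUMNS + CM_COLUMNS

#: full model input layout: 19 covariates plus the current-step HFH indicator
INPUT_COLUMNS = COVARIATE_COLUMNS + ["hf"]
CSV_COLUMNS = ["patient_id", "step"] + COVARIATE_COLUMNS + ["hf"]

N_INPUTS = len(INPUT_COLUMNS)  # 20
N_ACUTE_CM = len(ACUTE_CM_COLUMNS)  # 3


class SchemaError(ValueError):
    """A required column is missing from a cohort file."""


class ValidationError(ValueError):
    """A timeline violates the cohort data-model invariants."""


@dataclass
class PatientTimeline:
    """Ordered 6-month time steps for one patient.

    ``data`` holds one row per step with columns COVARIATE_COLUMNS + ['hf'],
    indexed 0..T-1 by step.
    """

    patient_id: str
    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ages(self) -> np.ndarray:
        return self.data["age"].to_numpy(dtype=float)

    @property
    def hf(self) -> np.ndarray:
        return self.data["hf"].to_numpy(dtype=int)

    def validate(self) -> None:
        df = self.data
        missing = [c for c in COVARIATE_COLUMNS + ["hf"] if c not in df.columns]
        if missing:
            raise SchemaError(
                f"patient {self.patient_id}: missing columns {missing}"
            )
        if len(df) < 2:
            raise ValidationError(
                f"patient {self.patient_id}: timeline needs >= 2 steps, got {len(df)}"
            )
        for col in BINARY_COLUMNS + ["hf"]:
            vals = df[col].to_numpy()
            bad = ~np.isin(vals, (0, 1))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"patient {self.patient_id}, step {row}: non-binary value "
                    f"{vals[bad][0]!r} in column {col!r}"
                )
        if not (df[SEX_COLUMNS].sum(axis=1) == 1).all():
            raise ValidationError(
                f"patient {self.patient_id}: sex one-hot must sum to 1"
            )
        lesion_sum = df[LESION_COLUMNS].sum(axis=1)
        if not lesion_sum.isin([1, 2]).all():
            raise ValidationError(
                f"patient {self.patient_id}: lesion indicators must sum to 1 or 2"
            )
        for col in STATIC_CM_COLUMNS:
            v = df[col].to_numpy()
            if (np.diff(v) < 0).any():
                raise ValidationError(
                    f"patient {self.patient_id}: static CM {col!r} must be "
                    "absorbing (never reverts to 0)"
                )
        if (df["surgery"].to_numpy() < 0).any() or (np.diff(df["surgery"].to_numpy()) < 0).any():
            raise ValidationError(
                f"patient {self.patient_id}: surgery count must be a "
                "non-decreasing non-negative integer"
            )
        ages = self.ages
        if not np.allclose(np.diff(ages), STEP_YEARS):
            raise ValidationError(
                f"patient {self.patient_id}: age must increase by "
                f"{STEP_YEARS} years per step"
            )


@dataclass
class Cohort:
    """A set of patient timelines plus optional train/validation/test splits."""

    patients: list[PatientTimeline]
    split: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def subset(self, split_name: str) -> "Cohort":
        """Patients assigned to one split (keeps the split map)."""
        chosen = [p for p in self.patients if self.split.get(p.patient_id) == split_name]
        return Cohort(chosen, {p.patient_id: split_name for p in chosen})

    def validate(self) -> None:
        ids = self.patient_ids()
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate patient_id in cohort")
        for p in self.patients:
            p.validate()
        if self.split:
            unknown = set(self.split) - set(ids)
            if unknown:
                raise ValidationError(f"split references unknown patients: {sorted(unknown)[:5]}")


@dataclass
class ContingencyRow:
    """One Table-style comparison row: counts of a trait in two patient arms."""

    label: str
    count_hf_pos: int
    n_hf_pos: int
    count_hf_neg: int
    n_hf_neg: int

    def validate(self) -> None:
        for count, n, arm in (
            (self.count_hf_pos, self.n_hf_pos, "HF+"),
            (self.count_hf_neg, self.n_hf_neg, "HF-"),
        ):
            if n <= 0:
                raise ValueError(f"{self.label}: {arm} arm size must be positive")
            if not 0 <= count <= n:
                raise ValueError(f"{self.label}: {arm} count {count} outside [0, {n}]")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cohort(path, schema: dict[str, str] | None = None) -> Cohort:
    """Read a longitudinal cohort CSV (one row per patient per time step).

    ``schema`` optionally maps canonical column names to the names used in
    the file. Rows are grouped by patient and ordered by step index; all
    data-model invariants are checked.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df = df[CSV_COLUMNS]
    patients = []
    for pid, g in df.groupby("patient_id", sort=True):
        g = g.sort_values("step")
        steps = g["step"].to_numpy()
        if not np.array_equal(steps, np.arange(len(g))):
            raise ValidationError(
                f"patient {pid}: step indices must be consecutive from 0"
            )
        tl = PatientTimeline(
            str(pid), g.drop(columns=["patient_id", "step"]).reset_index(drop=True)
        )
        patients.append(tl)
    cohort = Cohort(patients)
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV with deterministic column and row order."""
    frames = []
    for p in sorted(cohort.patients, key=lambda t: t.patient_id):
        g = p.data.copy()
        g.insert(0, "step", np.arange(len(g)))
        g.insert(0, "patient_id", p.patient_id)
        frames.append(g)
    if frames:
        out = pd.concat(frames, ignore_index=True)[CSV_COLUMNS]
    else:
        out = pd.DataFrame(columns=CSV_COLUMNS)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filtering and encoding
# ---------------------------------------------------------------------------

def restrict_to_age_window(cohort: Cohort, min_age: float = 40.0) -> Cohort:
    """Keep only time steps at or above ``min_age`` years.

    Heart-failure hospitalizations before age 40 are excluded from modelling;
    truncated timelines are re-indexed from 0 and patients left with fewer
    than two steps are dropped.
    """
    kept = []
    for p in cohort.patients:
        mask = p.ages >= min_age - 1e-9
        if mask.sum() < 2:
            continue
        kept.append(PatientTimeline(p.patient_id, p.data.loc[mask].reset_index(drop=True)))
    split = {p.patient_id: cohort.split[p.patient_id]
             for p in kept if p.patient_id in cohort.split}
    return Cohort(kept, split)


def encode_inputs(
    timeline: PatientTimeline, with_cm_targets: bool = False
):
    """Turn a timeline into next-step (input, target) training pairs.

    Returns ``(X, y)`` — or ``(X, y, c)`` when ``with_cm_targets`` — where
    ``X[i]`` is the 20-number input at step i (19 covariates plus the step-i
    HFH indicator), ``y[i]`` is the HFH label at step i+1, and ``c[i]`` holds
    the three acute-CM indicators at step i+1 for the multi-task model.
    """
    if len(timeline) < 2:
        raise ValidationError(
            f"patient {timeline.patient_id}: need >= 2 steps to form pairs"
        )
    df = timeline.data
    X = df[INPUT_COLUMNS].to_numpy(dtype=float)[:-1]
    y = df["hf"].to_numpy(dtype=float)[1:]
    if not with_cm_targets:
        return X, y
    c = df[ACUTE_CM_COLUMNS].to_numpy(dtype=float)[1:]
    return X, y, c


# ---------------------------------------------------------------------------
# Cohort-comparison statistics
# ---------------------------------------------------------------------------

def log2_proportion_ratio(row: ContingencyRow) -> float:
    """Base-2 log of the trait-proportion ratio between the HF+ and HF- arms."""
    row.validate()
    if row.count_hf_pos == 0 or row.count_hf_neg == 0:
        raise ValueError(f"{row.label}: zero count makes the ratio undefined")
    p_pos = row.count_hf_pos / row.n_hf_pos
    p_neg = row.count_hf_neg / row.n_hf_neg
    return math.log2(p_pos / p_neg)


def binomial_enrichment_test(
    count: int, n: int, background_rate: float, two_sided: bool = False
) -> float:
    """Exact binomial test of ``count`` successes in ``n`` trials vs a
    fixed background rate.

    Defaults to one-sided in the direction of the observed deviation
    (enrichment if count/n exceeds the background, depletion otherwise);
    set ``two_sided`` for the symmetric test.
    """
    if not 0 < background_rate < 1:
        raise ValueError(f"background_rate must lie in (0,1), got {background_rate}")
    if not 0 <= count <= n:
        raise ValueError(f"count {count} outside [0, {n}]")
    if two_sided:
        alternative = "two-sided"
    else:
        alternative = "greater" if count / n >= background_rate else "less"
    return binomtest(count, n, background_rate, alternative=alternative).pvalue
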