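import numpy as np
import pandas as pd
import pytest

from hftraj.cohort import COVARIATE_COLUMNS, Cohort, PatientTimeline


def make_timeline(
    patient_id: str,
    n_steps: int,
    hf=None,
    age0: float = 40.0,
    **overrides,
) -> PatientTimeline:
    """A valid timeline with inert defaults (male, 'other' lesion, no CMs).

    ``overrides`` may set any covariate column to a scalar or a length-n
    sequence.
    """
    cols = {c: np.zeros(n_steps) for c in COVARIATE_COLUMNS}
    cols["age"] = age0 + 0.5 * np.arange(n_steps)
    cols["sex_m"] = np.ones(n_steps)
    cols["lesion_other"] = np.ones(n_steps)
    for key, value in overrides.items():
        if key not in cols:
            raise KeyError(key)
        cols[key] = np.broadcast_to(np.asarray(value, dtype=float), (n_steps,)).copy()
    cols["hf"] = (
        np.zeros(n_steps) if hf is None
        else np.broadcast_to(np.asarray(hf, dtype=float), (n_steps,)).copy()
    )
    return PatientTimeline(patient_id, pd.DataFrame(cols))


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Two patients, three steps each; one HFH in the second patient."""
    return Cohort(
        [
            make_timeline("A", 3),
            make_timeline("B", 3, hf=[0, 1, 0], cm_sepsis=[1, 0, 0]),
        ]
    )
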