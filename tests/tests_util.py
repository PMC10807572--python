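"""Shared helpers for building tiny in-memory cohorts."""

import numpy as np
import pandas as pd

import gvhdtte as g


def constant_covariate_dataset(
    csa,
    age,
    related,
    event_time,
    event,
    mrd=None,
    f2m=None,
    flu=None,
) -> g.CohortDataset:
    """Cohort whose patients hold one constant CsA level and median WBC."""
    n = len(csa)
    mrd = mrd or [False] * n
    f2m = f2m or [False] * n
    flu = flu or [False] * n
    ids = [f"T{i:03d}" for i in range(n)]
    static = pd.DataFrame(
        {
            "patient_id": ids,
            "age_years": age,
            "donor_related": related,
            "matched_related_donor": mrd,
            "female_to_male": f2m,
            "flutbi": flu,
            "event_time_days": event_time,
            "event_indicator": event,
        }
    )
    rows = []
    for pid, level in zip(ids, csa):
        rows.append({"patient_id": pid, "time_days": 0.0, "analyte": "wbc", "value": 1.0})
        rows.append({"patient_id": pid, "time_days": 0.0, "analyte": "csa", "value": level})
    reference = pd.DataFrame({"day": [0.0, 100.0], "median_wbc": [1.0, 1.0]})
    return g.CohortDataset(static, pd.DataFrame(rows), reference)
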