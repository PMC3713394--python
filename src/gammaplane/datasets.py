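"""Reference cohort: published per-person signatures from the MJFF/Kaggle
smartphone-accelerometry Parkinson's study cohort.

The raw accelerometer streams of that data challenge are not
redistributable, but the published per-participant summary values are: for
each of the 15 usable participants (6 normal controls, 9 Parkinson's
patients; one further control was excluded at the source for extreme
multimodal contamination), the Gamma (shape, scale) estimate of the
speed-peak distribution with its 95% CI, the participant's age, and the
min/max shift of their stochastic trajectory.  These transcribed values
let the cohort stage run and be validated without the original streams.

Ages for the two 55-year-old-range controls and patients are as published;
participant names are the study's flower pseudonyms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortScatter

__all__ = ["reference_cohort_table", "reference_cohort_scatter"]

# columns: participant, label, age, shape, scale,
#          ci_a_low, ci_b_low, ci_a_high, ci_b_high, shift_min, shift_max
_REFERENCE_ROWS = [
    # Parkinson's disease
    ("Daisy",  "PD", 54, 2.1892,  1.6624, 1.929, 1.442, 2.483, 1.915, 1.0147, 22.8752),
    ("Cherry", "PD", 55, 2.8527,  0.7797, 1.893, 0.498, 4.298, 1.220, 1.0252,  6.5693),
    ("Orchid", "PD", 69, 0.7476, 13.4048, 0.643, 0.886, 0.869, 14.51, 1.0079, 83.6943),
    ("Crocus", "PD", 46, 1.3966,  4.6465, 1.199, 3.870, 1.626, 5.578, 1.0012, 36.2181),
    ("Maple",  "PD", 55, 0.8482,  8.5078, 0.742, 7.114, 0.969, 9.18,  1.0032, 52.6980),
    ("Flox",   "PD", 57, 0.9854,  6.6008, 0.823, 5.231, 1.181, 7.329, 1.0207, 44.3045),
    ("Violet", "PD", 55, 0.8260,  6.0915, 0.675, 4.643, 1.011, 7.993, 1.0043, 35.8459),
    ("Peony",  "PD", 80, 1.0905,  3.9342, 0.885, 3.026, 1.343, 5.114, 1.0014, 27.7137),
    ("Iris",   "PD", 65, 1.0631,  6.8824, 0.684, 3.941, 1.651, 9.02,  1.1204, 36.5351),
    # normal controls
    ("Dafo",   "NC", 42, 1.3953,  3.1758, 1.185, 2.612, 1.642, 3.861, 1.0153, 29.0774),
    ("Rose",   "NC", 55, 2.1209,  1.9402, 1.443, 1.257, 3.117, 2.995, 1.0033, 17.0063),
    ("Orange", "NC", 57, 2.9601,  0.9281, 2.318, 0.711, 3.779, 1.211, 1.0126, 12.2356),
    ("Sunf",   "NC", 67, 3.2197,  0.6442, 2.109, 0.407, 4.914, 1.018, 1.0005,  6.5434),
    ("Apple",  "NC", 77, 3.8684,  0.5716, 2.795, 0.404, 5.354, 0.808, 1.0185,  7.4658),
    ("Sweetp", "NC", 77, 3.5192,  0.6395, 2.203, 0.386, 5.623, 1.058, 1.0014,  6.8278),
]

_COLUMNS = [
    "participant", "label", "age", "shape", "scale",
    "ci_a_low", "ci_b_low", "ci_a_high", "ci_b_high", "shift_min", "shift_max",
]


def reference_cohort_table() -> pd.DataFrame:
    """The reference cohort as a DataFrame, one row per participant."""
    df = pd.DataFrame(_REFERENCE_ROWS, columns=_COLUMNS)
    # integrity check against accidental edits: shapes/scales positive,
    # estimates inside their CIs, 6 NC + 9 PD
    if (df["label"] == "NC").sum() != 6 or (df["label"] == "PD").sum() != 9:
        raise RuntimeError("reference cohort fixture corrupted: wrong group sizes")
    ok = (
        (df["shape"] > 0).all()
        and (df["scale"] > 0).all()
        and (df["ci_a_low"] <= df["shape"]).all()
        and (df["shape"] <= df["ci_a_high"]).all()
        and (df["ci_b_low"] <= df["scale"]).all()
        and (df["scale"] <= df["ci_b_high"]).all()
    )
    if not ok:
        raise RuntimeError("reference cohort fixture corrupted: CI brackets broken")
    return df


def reference_cohort_scatter() -> CohortScatter:
    """The reference cohort packaged for :func:`gammaplane.cohort.cohort_report`."""
    df = reference_cohort_table()
    return CohortScatter(
        participant_ids=df["participant"].tolist(),
        points=df[["shape", "scale"]].to_numpy(),
        labels=df["label"].tolist(),
        ages=df["age"].to_numpy(float),
        max_shifts=df["shift_max"].to_numpy(),
    )
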