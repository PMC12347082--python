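"""Published cohort summaries used as simulation defaults and report checks.

These are the printed summary statistics of the 26-patient validation
cohort for this planning workflow: per segment and parameter, the mean
T0→T1 plan difference and its standard error (rotations in degrees,
translations in mm), the out-of-range percentages at the clinical
tolerances (4° rotations, 2 mm translations), and the cohort's covariate
composition.  The raw per-patient data were never released, so these
summaries serve two roles here:

* defaults for the synthetic-cohort generator (per-patient effects are
  drawn from Gaussians with the published mean and SD = SEM · √n), and
* inputs to internal-consistency recomputations (confidence intervals
  and significance from mean/SEM, tolerance-table row means).
"""

from __future__ import annotations

import math

N_PATIENTS = 26

#: Covariate composition of the published cohort.
N_SARME = 15
N_EXTRACTION_MAXILLA = 4
N_EXTRACTION_MANDIBLE = 13

#: Clinical tolerance levels: differences beyond these are "out of range".
ROTATION_TOLERANCE_DEG = 4.0
TRANSLATION_TOLERANCE_MM = 2.0

#: Per segment × parameter: (mean, SEM) of the published cohort.
COHORT_MEAN_SEM: dict[str, dict[str, tuple[float, float]]] = {
    "dental_maxilla": {
        "pitch": (-2.85, 0.68),
        "roll": (0.05, 0.21),
        "yaw": (-0.54, 0.33),
        "trans_lr": (0.34, 0.21),
        "trans_ap": (-0.74, 0.54),
        "trans_ud": (-0.82, 0.41),
    },
    "dental_mandible": {
        "pitch": (-1.63, 1.30),
        "roll": (0.51, 0.72),
        "yaw": (-1.52, 0.92),
        "trans_lr": (1.19, 0.51),
        "trans_ap": (0.72, 0.45),
        "trans_ud": (0.02, 0.51),
    },
    "bony_mandible": {
        "pitch": (-0.41, 0.71),
        "roll": (0.31, 0.39),
        "yaw": (-1.21, 0.49),
        "trans_lr": (0.76, 0.37),
        "trans_ap": (0.12, 0.28),
        "trans_ud": (0.08, 0.27),
    },
}

#: Published per-parameter out-of-range percentages (tolerances above).
OUT_OF_RANGE_PERCENT: dict[str, dict[str, float]] = {
    "dental_maxilla": {
        "pitch": 42.31, "roll": 0.00, "yaw": 3.85,
        "trans_lr": 11.54, "trans_ap": 23.08, "trans_ud": 30.77,
    },
    "dental_mandible": {
        "pitch": 57.69, "roll": 15.38, "yaw": 26.92,
        "trans_lr": 50.00, "trans_ap": 50.00, "trans_ud": 34.62,
    },
    "bony_mandible": {
        "pitch": 26.92, "roll": 3.85, "yaw": 15.38,
        "trans_lr": 26.92, "trans_ap": 15.38, "trans_ud": 11.54,
    },
}

#: Published mean-of-three summary rows of the out-of-range table.
OUT_OF_RANGE_MEANS: dict[str, dict[str, float]] = {
    "dental_maxilla": {"mean_rotations": 15.39, "mean_translations": 21.80},
    "dental_mandible": {"mean_rotations": 33.33, "mean_translations": 44.87},
    "bony_mandible": {"mean_rotations": 15.38, "mean_translations": 17.95},
}


def cohort_sd(segment: str, parameter: str, n: int = N_PATIENTS) -> float:
    """Per-patient SD implied by the published SEM: ``sd = sem * sqrt(n)``."""
    _, sem = COHORT_MEAN_SEM[segment][parameter]
    return sem * math.sqrt(n)
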