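"""Fixed BMI category schemes used throughout the package.

Fine categories follow the eight-band scheme used in cohort analyses of
middle-aged UK women; coarse categories are the five bands used for
population projection.  All boundaries are half-open ``[lower, upper)``;
the top band is closed below and unbounded above.
"""

from __future__ import annotations

import numpy as np

#: Lower edges of the eight fine categories (kg/m^2); the last band is open-ended.
FINE_EDGES = np.array([18.5, 20.0, 22.5, 25.0, 27.5, 30.0, 35.0, 40.0])

FINE_CATEGORIES = [
    "18.5-20",
    "20-22.5",
    "22.5-25",
    "25-27.5",
    "27.5-30",
    "30-35",
    "35-40",
    "40+",
]

#: Reference band for all relative effect measures.
REFERENCE_FINE = "20-22.5"

COARSE_CATEGORIES = ["<25", "25-29.9", "30-34.9", "35-39.9", "40+"]

#: Coarse categories counted as excess weight in attributable-cost work.
EXCESS_COARSE = ["25-29.9", "30-34.9", "35-39.9", "40+"]

FINE_TO_COARSE = {
    "18.5-20": "<25",
    "20-22.5": "<25",
    "22.5-25": "<25",
    "25-27.5": "25-29.9",
    "27.5-30": "25-29.9",
    "30-35": "30-34.9",
    "35-40": "35-39.9",
    "40+": "40+",
}

#: The two fine bands whose weighted average defines the 20-24.9 reference
#: cost in projections.
REFERENCE_BANDS = ("20-22.5", "22.5-25")

#: Knot of the piecewise-linear generative BMI-log rate relation: the
#: midpoint of the reference band.  Below it the relation is flat.
REFERENCE_KNOT = 21.25


def assign_fine_category(bmi) -> np.ndarray:
    """Map BMI values (kg/m^2) to fine category labels.

    Values below 18.5 are rejected: the analysis population excludes
    underweight below that cut.
    """
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bmi < FINE_EDGES[0]):
        raise ValueError("BMI below 18.5 kg/m^2 is outside the supported range")
    idx = np.digitize(bmi, FINE_EDGES[1:], right=False)
    return np.asarray(FINE_CATEGORIES, dtype=object)[idx]


def fine_to_coarse(fine) -> np.ndarray:
    """Map fine category labels to coarse labels, validating membership."""
    out = []
    for lab in np.asarray(fine, dtype=object):
        try:
            out.append(FINE_TO_COARSE[lab])
        except KeyError:
            raise ValueError(f"unknown fine BMI category: {lab!r}") from None
    return np.asarray(out, dtype=object)
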