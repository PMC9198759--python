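"""Bundled reference data from the published preclinical cohort.

Two small printed tables travel with the package so its desk-checkable
quantities can be recomputed without any external download:

* the demographic table of the 10 neurologically normal hemispheres
  (Braak I-II) the subfield protocol was developed on — case 6 lacks
  demographics and contributes missing values, and
* the per-subfield averages of manual cortical thickness (mm) and CP13
  semi-quantitative tau score used for the thickness-burden correlation
  (EMI excluded from thickness by protocol).
"""

from __future__ import annotations

import pandas as pd

from .gradient import CaseRecord

__all__ = ["reference_cases", "reference_thickness_sq", "REFERENCE_COHORT_ROWS"]

# case_id, hemisphere, age, sex, braak, pmi_h (None where only "< 24" is known),
# brain_weight_g
REFERENCE_COHORT_ROWS = [
    ("1", "LH", 59, "M", "I", 20.0, 1319.0),
    ("2", "LH", 59, "F", "II", None, 1402.0),
    ("3", "RH", 60, "M", "II", None, 1166.0),
    ("4", "RH", 60, "M", "I", 14.0, 1414.0),
    ("5", "LH", 70, "F", "I", 23.0, 1030.0),
    ("6", "LH", None, None, "II", None, None),
    ("7", "LH", 73, "F", "II", None, 1142.0),
    ("8", "RH", 80, "M", "II", None, 1348.0),
    ("9", "LH", 82, "M", "II", None, 1224.0),
    ("10", "LH", 84, "F", "II", None, 1221.0),
]


def reference_cases() -> list[CaseRecord]:
    """The 10-case reference cohort as :class:`~ectau.gradient.CaseRecord` objects."""
    return [
        CaseRecord(case_id=cid, hemisphere=hemi, age=age, sex=sex,
                   braak_stage=braak, pmi_h=pmi, brain_weight_g=bw)
        for cid, hemi, age, sex, braak, pmi, bw in REFERENCE_COHORT_ROWS
    ]


# (unit, mean cortical thickness mm, mean SQ score) for the 9 thickness-eligible
# entorhinal units.
_THICKNESS_SQ_ROWS = [
    ("EO", 4.08, 1.27),
    ("ER", 4.39, 1.67),
    ("ELr", 4.04, 1.45),
    ("EI_Med", 3.24, 1.73),
    ("EI_Lat", 3.31, 1.95),
    ("ELc", 3.10, 2.18),
    ("ECs_Med", 2.80, 2.70),
    ("ECs_Lat", 2.68, 2.95),
    ("ECL", 2.78, 2.87),
]


def reference_thickness_sq() -> pd.DataFrame:
    """Per-subfield average thickness (mm) and average SQ score, tidy."""
    return pd.DataFrame(_THICKNESS_SQ_ROWS,
                        columns=["unit", "thickness_mm", "sq"])
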