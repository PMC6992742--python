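"""Derivation of analysis variables from questionnaire-style fields.

Smoking amount is expressed in pack-years, alcohol intake in grams of
ethanol per day summed over beverage types, and education is collapsed
to a binary college/university-degree indicator.
"""

from __future__ import annotations

import numpy as np

#: Questionnaire education categories; the degree indicator is 1 iff the
#: first entry is present.  Grams-of-ethanol-per-drink constants for each
#: beverage type are supplied by the caller (they are survey-specific).
EDUCATION_VOCABULARY = frozenset(
    {
        "College or University degree",
        "A levels/AS levels or equivalent",
        "O levels/GCSEs or equivalent",
        "CSEs or equivalent",
        "NVQ or HND or HNC or equivalent",
        "Other professional qualifications",
        "None of the above",
        "Prefer not to answer",
    }
)
DEGREE_CATEGORY = "College or University degree"


def pack_years(cigarettes_per_day: float, years_smoked: float) -> float:
    """Pack-years: (cigarettes per day / 20) * years smoked."""
    if cigarettes_per_day < 0 or years_smoked < 0:
        raise ValueError("cigarettes_per_day and years_smoked must be >= 0")
    return (cigarettes_per_day / 20.0) * years_smoked


def alcohol_grams_per_day(drinks_per_day, grams_per_drink) -> float:
    """Total ethanol grams/day: sum over beverage types of
    (drinks per day) * (grams of alcohol per drink)."""
    d = np.asarray(drinks_per_day, dtype=float)
    g = np.asarray(grams_per_drink, dtype=float)
    if d.shape != g.shape:
        raise ValueError("drinks_per_day and grams_per_drink lengths differ")
    if d.size and ((d < 0).any() or (g < 0).any()):
        raise ValueError("drink counts and gram contents must be >= 0")
    return float(np.sum(d * g))


def collapse_education(qualifications) -> int:
    """1 iff a college or university degree appears in the list."""
    quals = list(qualifications)
    unknown = [q for q in quals if q not in EDUCATION_VOCABULARY]
    if unknown:
        raise ValueError(f"unknown education categories: {unknown}")
    return int(DEGREE_CATEGORY in quals)
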