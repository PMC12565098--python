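"""Clinical derivations: logMAR conversion, visual-field averaging, functional
impairment typing and WHO visual-impairment categorisation.

Functional types follow the study inclusion criteria on better-seeing-eye
decimal acuity (VA) and binocular visual-field radius (VF, degrees):

* central    — VA in [0.05, 0.6] and VF > 50°
* peripheral — VA >= 0.4 and VF in [5°, 50°]
* combined   — VA in [0.05, 0.4) and VF in [5°, 50°]
* control    — VA >= 0.8 and VF >= 80°

Anything else (e.g. VA 0.7 with a full field) is honestly `unclassified`:
such people were excluded from the study rather than classified.

WHO categories are derived from presenting acuity (pVA) and VF radius; when
the two criteria disagree the MORE SEVERE one wins (inferred from the study's
worked example of a patient with pVA 0.20 but VF 5° assigned category 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ClinicalLabels",
    "va_to_logmar",
    "vf_radius_noncentric",
    "classify_functional",
    "classify_who",
    "WHO_ORDER",
    "augment_cohort",
]

#: severity ordering of WHO labels (larger = more severe); the table's top
#: row ("below normal but above WHO low-vision threshold") and unimpaired
#: vision both map to ``not_categorized`` (alias cat0).
WHO_ORDER = {"not_categorized": 0, "cat1": 1, "cat2": 2, "cat3": 3, "cat4": 4}
_WHO_BY_SEVERITY = {v: k for k, v in WHO_ORDER.items()}

FUNCTIONAL_TYPES = ("control", "central", "peripheral", "combined", "unclassified")


@dataclass(frozen=True)
class ClinicalLabels:
    functional_type: str
    who_category: str
    va_logmar: float  # raw (unrounded) value


def va_to_logmar(va_decimal: float, *, rounded: bool = False) -> float:
    """logMAR = -log10(decimal acuity); e.g. 0.30 -> 0.52, 0.05 -> 1.30.

    ``rounded`` applies the 2-decimal half-up reporting convention; the raw
    value is kept for internal use.
    """
    if va_decimal <= 0:
        raise ValueError("decimal acuity must be positive")
    lm = -math.log10(va_decimal)
    if rounded:
        return math.floor(lm * 100 + 0.5) / 100
    return lm


def vf_radius_noncentric(temporal: float, nasal: float) -> float:
    """Non-concentric field constriction: mean of temporal and nasal radii."""
    if temporal < 0 or nasal < 0:
        raise ValueError("field radii must be non-negative")
    return (temporal + nasal) / 2.0


def classify_functional(va_decimal: float, vf_radius: float) -> str:
    """Assign control / central / peripheral / combined per the entry criteria."""
    if va_decimal <= 0 or vf_radius <= 0:
        raise ValueError("acuity and field radius must be positive")
    va, vf = va_decimal, vf_radius
    if 0.05 <= va <= 0.6 and vf > 50:
        return "central"
    if va >= 0.4 and 5 <= vf <= 50:
        return "peripheral"
    if 0.05 <= va < 0.4 and 5 <= vf <= 50:
        return "combined"
    if va >= 0.8 and vf >= 80:
        return "control"
    return "unclassified"


def _who_severity_va(pva: float) -> int:
    if pva < 0.02:
        return 4
    if pva < 0.05:
        return 3
    if pva < 0.1:
        return 2
    if pva < 0.3:
        return 1
    if pva <= 0.6:
        return 0  # below normal but above WHO low-vision threshold
    return -1  # outside all rows


def _who_severity_vf(vf: float) -> int:
    if vf <= 5:
        return 4
    if vf <= 10:
        return 3
    if vf <= 20:
        return 2
    if vf < 80:
        return 0
    return -1


def classify_who(pva_decimal: float, vf_radius: float) -> str:
    """WHO category from presenting acuity and field radius, severest-of-two."""
    if pva_decimal <= 0 or vf_radius <= 0:
        raise ValueError("acuity and field radius must be positive")
    sev = max(_who_severity_va(pva_decimal), _who_severity_vf(vf_radius))
    return _WHO_BY_SEVERITY[max(sev, 0)]


def derive_labels(va_decimal: float, vf_radius: float) -> ClinicalLabels:
    return ClinicalLabels(
        functional_type=classify_functional(va_decimal, vf_radius),
        who_category=classify_who(va_decimal, vf_radius),
        va_logmar=va_to_logmar(va_decimal),
    )


def augment_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add va_logmar (2-decimal reporting), functional_type and who_category
    columns derived from va_decimal and vf_radius."""
    out = cohort.copy()
    out["va_logmar"] = [va_to_logmar(v, rounded=True) for v in out["va_decimal"]]
    out["functional_type"] = [
        classify_functional(v, f) for v, f in zip(out["va_decimal"], out["vf_radius"])
    ]
    out["who_category"] = [
        classify_who(v, f) for v, f in zip(out["va_decimal"], out["vf_radius"])
    ]
    return out
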