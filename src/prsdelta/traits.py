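"""Canonical metabolic-trait panel and default simulation scales.

The panel is the 17-trait roster measured at both visits of a two-visit
prediabetes cohort: anthropometry/bioimpedance (BMI, fat-free mass, fat
mass, muscle mass, visceral and subcutaneous fat, VAT/SAT ratio), physical
activity (IPAQ total), glycemia (fasting glucose, 2 h post-OGTT glucose,
HbA1c, fasting and 2 h insulin) and lipids (Chol, Tg, Hdl, Ldl).

Change (delta) analyses model trait changes adjusted for baseline BMI, so
BMI itself is a covariate there and the delta panel has 16 traits.
"""

from __future__ import annotations

#: Trait identifiers, in reporting order.
TRAITS: tuple[str, ...] = (
    "BMI",
    "FFM",
    "FM",
    "MM",
    "VF",
    "SF",
    "VAT_SAT",
    "IPAQ",
    "fasting_glucose",
    "glucose_2h",
    "HbA1c",
    "fasting_insulin",
    "insulin_2h",
    "Chol",
    "Tg",
    "Hdl",
    "Ldl",
)

#: Traits analyzed on the change (T2 - T1) scale; BMI is the adjustment
#: covariate in those models and is therefore excluded.
DELTA_TRAITS: tuple[str, ...] = tuple(t for t in TRAITS if t != "BMI")

TRAIT_UNITS: dict[str, str] = {
    "BMI": "kg/m^2",
    "FFM": "kg",
    "FM": "kg",
    "MM": "kg",
    "VF": "cm^3",
    "SF": "cm^3",
    "VAT_SAT": "ratio",
    "IPAQ": "min/week",
    "fasting_glucose": "mg/dL",
    "glucose_2h": "mg/dL",
    "HbA1c": "%",
    "fasting_insulin": "uU/mL",
    "insulin_2h": "uU/mL",
    "Chol": "mg/dL",
    "Tg": "mg/dL",
    "Hdl": "mg/dL",
    "Ldl": "mg/dL",
}

# Baseline sampling intervals, roughly the interquartile spans reported for
# middle-aged prediabetic cohorts.  Glycemic traits are constrained to the
# prediabetic diagnostic ranges (IFG 100-125 mg/dL, HbA1c 5.7-6.4 %).
DEFAULT_BASELINE_RANGES: dict[str, tuple[float, float]] = {
    "BMI": (24.0, 31.0),
    "FFM": (48.7, 61.5),
    "FM": (20.0, 28.2),
    "MM": (21.2, 30.3),
    "VF": (65.0, 101.0),
    "SF": (117.0, 184.0),
    "VAT_SAT": (0.44, 0.64),
    "IPAQ": (240.0, 4306.0),
    "fasting_glucose": (100.0, 125.0),
    "glucose_2h": (103.0, 160.0),
    "HbA1c": (5.7, 6.4),
    "fasting_insulin": (8.5, 14.8),
    "insulin_2h": (17.2, 53.8),
    "Chol": (165.0, 221.0),
    "Tg": (67.0, 133.0),
    "Hdl": (50.4, 68.0),
    "Ldl": (83.2, 137.4),
}

# Sub-prediabetic sampling intervals for the boundary fraction of the
# cohort (individuals deliberately generated just below the diagnostic
# thresholds so eligibility classification sees both sides).
SUBTHRESHOLD_RANGES: dict[str, tuple[float, float]] = {
    "fasting_glucose": (90.0, 99.9),
    "HbA1c": (5.3, 5.69),
    "glucose_2h": (100.0, 139.0),
}

#: Default residual SD of the five-year change, per trait (trait units).
#: Chosen so that per-SD polygenic effects of the magnitude reported for
#: cohorts of a few hundred individuals (order 0.005 trait units per SD)
#: are estimable; see docs/methods.md.
DEFAULT_NOISE_SD: float = 0.05
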