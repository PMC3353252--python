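"""Unit conversions between SI (mmol/L) and conventional (mg/dl) scales.

Cohort files carry glucose and lipids in mmol/L; the published risk models
score them in mg/dl. Factors are the standard molar-mass conversions and are
overridable wherever they are consumed.
"""

from __future__ import annotations

#: mg/dl per mmol/L
GLUCOSE_MGDL_PER_MMOL = 18.0182
CHOLESTEROL_MGDL_PER_MMOL = 38.67  # HDL and other cholesterol fractions
TRIGLYCERIDE_MGDL_PER_MMOL = 88.57

DEFAULT_FACTORS = {
    "glucose": GLUCOSE_MGDL_PER_MMOL,
    "cholesterol": CHOLESTEROL_MGDL_PER_MMOL,
    "triglyceride": TRIGLYCERIDE_MGDL_PER_MMOL,
}


def mmol_to_mgdl(value, factor):
    """Convert mmol/L to mg/dl; total on all real inputs."""
    return value * factor


def mgdl_to_mmol(value, factor):
    return value / factor
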