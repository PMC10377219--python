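"""Fixed column schema for the stress-cohort table.

Every record describes one survey respondent through eleven candidate
predictors (eight continuous, three binary) and a binary stress label.
The variable order below is the canonical order used everywhere: in the
CSV layout, in screening reports and in the model's feature sequence.
"""

from __future__ import annotations

#: Continuous candidate variables, in canonical (reporting) order.
CONTINUOUS_VARS: tuple[str, ...] = (
    "age",
    "height",
    "weight",
    "sleep_duration",
    "pulse_rate",
    "sbp",
    "dbp",
    "bmi",
)

#: Binary candidate variables (two-level categorical).
BINARY_VARS: tuple[str, ...] = ("gender", "drinking", "smoking")

#: The two levels of each binary variable, (first, second).  Probabilities
#: in a cohort spec always refer to the *second* level.
BINARY_LEVELS: dict[str, tuple[str, str]] = {
    "gender": ("man", "woman"),
    "drinking": ("no", "yes"),
    "smoking": ("no", "yes"),
}

#: Label column and its levels; "high" is the positive (stressed) class.
LABEL: str = "stress"
LABEL_LEVELS: tuple[str, str] = ("low", "high")

#: All eleven candidate predictors in canonical order.
FEATURES: tuple[str, ...] = (
    "gender",
    "age",
    "height",
    "weight",
    "sleep_duration",
    "pulse_rate",
    "sbp",
    "dbp",
    "bmi",
    "drinking",
    "smoking",
)

#: Full CSV column order (predictors followed by the label).
COLUMNS: tuple[str, ...] = FEATURES + (LABEL,)

#: Physical units, for documentation and report output.
UNITS: dict[str, str] = {
    "age": "yr",
    "height": "cm",
    "weight": "kg",
    "sleep_duration": "hr",
    "pulse_rate": "bpm",
    "sbp": "mmHg",
    "dbp": "mmHg",
    "bmi": "kg/m^2",
}
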