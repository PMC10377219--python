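"""Synthetic two-group stress cohorts.

Generates case/control style health-survey cohorts: a "low stress" and a
"high stress" group, each with its own means for the continuous variables
(age, height, weight, sleep duration, pulse rate, SBP, DBP, BMI) and its
own probabilities for the binary variables (gender, drinking, smoking).
The built-in default specification reproduces the group means, category
counts and group sizes reported for the KNHANES VI stress sample, so the
downstream screening stage sees the same significance pattern as the real
survey: seven continuous variables and the three binary ones separate the
groups, while DBP and BMI are planted near-nulls.

Continuous variables are drawn from truncated normal distributions whose
location is corrected so the post-truncation mean equals the target mean.
BMI is never sampled: it is recomputed as weight/(height/100)^2 after
sampling, keeping the derived-variable identity exact.  Labels are the
group membership itself (a two-component mixture), so all class signal
lives in the between-group shifts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .schema import (
    BINARY_LEVELS,
    BINARY_VARS,
    COLUMNS,
    CONTINUOUS_VARS,
    LABEL,
    LABEL_LEVELS,
)

__all__ = [
    "CohortSpecError",
    "CohortSpec",
    "default_spec",
    "separable_spec",
    "generate_cohort",
    "generate_imbalanced_study",
]


class CohortSpecError(ValueError):
    """Raised when a cohort specification is invalid; names the field."""


# Variables sampled from truncated normals (BMI is derived, not sampled).
_SAMPLED_VARS = tuple(v for v in CONTINUOUS_VARS if v != "bmi")

# Short aliases accepted in attribute-style access (mean_sleep_low etc.).
_ALIASES = {
    "sleep": "sleep_duration",
    "pulse": "pulse_rate",
}

_DEFAULT_MEANS_LOW = {
    "age": 56.72,
    "height": 159.80,
    "weight": 63.12,
    "sleep_duration": 6.50,
    "pulse_rate": 70.10,
    "sbp": 120.92,
    "dbp": 73.52,
    "bmi": 24.08,
}
_DEFAULT_MEANS_HIGH = {
    "age": 47.54,
    "height": 161.18,
    "weight": 64.07,
    "sleep_duration": 6.15,
    "pulse_rate": 72.68,
    "sbp": 116.37,
    "dbp": 74.59,
    "bmi": 24.16,
}

# Shared standard deviations.  Not survey-published quantities: they are
# generator calibration constants, chosen so that at the default group
# sizes (640/633) two-sample tests are comfortably significant for the
# seven shifted variables and rarely significant for the DBP / BMI
# near-nulls (see docs/methods.md for the power arithmetic).
_DEFAULT_SDS = {
    "age": 15.0,
    "height": 6.0,
    "weight": 4.0,
    "sleep_duration": 1.2,
    "pulse_rate": 8.0,
    "sbp": 14.0,
    "dbp": 20.0,
    "bmi": 3.2,  # calibration reference only; BMI is derived, not sampled
}

# Probability of the second category (woman / yes / yes) per group,
# matching the reference category counts: gender 351/640 vs 405/633,
# drinking 290/628 vs 341/628, smoking 98/640 vs 162/636.
_DEFAULT_PROBS_LOW = {
    "gender": 351 / 640,
    "drinking": 290 / 628,
    "smoking": 98 / 640,
}
_DEFAULT_PROBS_HIGH = {
    "gender": 405 / 633,
    "drinking": 341 / 628,
    "smoking": 162 / 636,
}

# Physiologic truncation bounds for the sampled continuous variables.
_DEFAULT_BOUNDS = {
    "age": (18.0, 75.0),
    "height": (120.0, 210.0),
    "weight": (30.0, 180.0),
    "sleep_duration": (1.0, 14.0),
    "pulse_rate": (35.0, 180.0),
    "sbp": (70.0, 230.0),
    "dbp": (35.0, 150.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Distributional specification of a two-group stress cohort.

    Parameters
    ----------
    n_low, n_high
        Number of low-stress and high-stress subjects.
    means_low, means_high
        Per-group means of the continuous variables (keys =
        :data:`~stresslstm.schema.CONTINUOUS_VARS`).  The BMI entry is a
        calibration reference only; BMI itself is derived from height and
        weight after sampling.
    sds
        Standard deviations shared by both groups.
    probs_low, probs_high
        Per-group probability of the *second* category of each binary
        variable (woman, drinking=yes, smoking=yes).
    bounds
        (lower, upper) truncation bounds per sampled continuous variable.
    seed
        Default random seed used when :func:`generate_cohort` is called
        without an explicit one.
    """

    n_low: int = 640
    n_high: int = 633
    means_low: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MEANS_LOW)
    )
    means_high: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MEANS_HIGH)
    )
    sds: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SDS))
    probs_low: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROBS_LOW)
    )
    probs_high: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROBS_HIGH)
    )
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_low, (int, np.integer)) or self.n_low <= 0:
            raise CohortSpecError(f"n_low must be a positive integer, got {self.n_low!r}")
        if not isinstance(self.n_high, (int, np.integer)) or self.n_high <= 0:
            raise CohortSpecError(
                f"n_high must be a positive integer, got {self.n_high!r}"
            )
        for group, means in (("means_low", self.means_low), ("means_high", self.means_high)):
            for var in CONTINUOUS_VARS:
                if var not in means:
                    raise CohortSpecError(f"{group} is missing variable {var!r}")
                if not np.isfinite(means[var]):
                    raise CohortSpecError(f"{group}[{var!r}] must be finite")
        for var in CONTINUOUS_VARS:
            sd = self.sds.get(var)
            if sd is None or not np.isfinite(sd) or sd <= 0:
                raise CohortSpecError(f"sds[{var!r}] must be a positive number, got {sd!r}")
        for group, probs in (("probs_low", self.probs_low), ("probs_high", self.probs_high)):
            for var in BINARY_VARS:
                p = probs.get(var)
                if p is None or not (0.0 <= p <= 1.0):
                    raise CohortSpecError(
                        f"{group}[{var!r}] must be a probability in [0, 1], got {p!r}"
                    )
        for var in _SAMPLED_VARS:
            lo, hi = self.bounds.get(var, (None, None))
            if lo is None or hi is None or not lo < hi:
                raise CohortSpecError(f"bounds[{var!r}] must be a (low, high) pair with low < high")

    # Attribute-style shorthand: spec.mean_sleep_low, spec.mean_pulse_high,
    # spec.sd_age, spec.prob_gender_high ...
    def __getattr__(self, name: str):
        parts = name.split("_")
        kind = parts[0]
        if kind in ("mean", "prob") and len(parts) >= 3 and parts[-1] in ("low", "high"):
            var = "_".join(parts[1:-1])
            var = _ALIASES.get(var, var)
            table = {
                ("mean", "low"): self.means_low,
                ("mean", "high"): self.means_high,
                ("prob", "low"): self.probs_low,
                ("prob", "high"): self.probs_high,
            }[(kind, parts[-1])]
            if var in table:
                return table[var]
        elif kind == "sd" and len(parts) >= 2:
            var = "_".join(parts[1:])
            var = _ALIASES.get(var, var)
            if var in self.sds:
                return self.sds[var]
        raise AttributeError(f"{type(self).__name__} has no attribute {name!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        if "bounds" in d:
            d["bounds"] = {k: tuple(v) for k, v in d["bounds"].items()}
        return cls(**d)


def default_spec() -> CohortSpec:
    """Cohort specification matching the reference survey sample.

    Group means/proportions equal the published per-group summary values;
    group sizes are 640 low- and 633 high-stress subjects (the sums of the
    published gender counts).
    """
    return CohortSpec()


def separable_spec(n_low: int = 200, n_high: int = 200, shift: float = 3.0) -> CohortSpec:
    """A strongly separable variant used for learnability checks.

    Every continuous variable is shifted by ``shift`` standard deviations
    between the groups (around the default pooled centre) and the binary
    category probabilities are pushed to 0.15 vs 0.85, so the two classes
    are (nearly) linearly separable in feature space.
    """
    base = default_spec()
    means_low, means_high = {}, {}
    for var in CONTINUOUS_VARS:
        centre = 0.5 * (base.means_low[var] + base.means_high[var])
        delta = 0.5 * shift * base.sds[var]
        means_low[var] = centre - delta
        means_high[var] = centre + delta
    return replace(
        base,
        n_low=n_low,
        n_high=n_high,
        means_low=means_low,
        means_high=means_high,
        probs_low={v: 0.15 for v in BINARY_VARS},
        probs_high={v: 0.85 for v in BINARY_VARS},
    )


def _matched_loc(target: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose truncated-normal mean equals ``target``.

    Truncation pulls the mean toward the interval centre (for age the
    shift would be several years), so the underlying location is solved
    for with a root finder rather than set to the target directly.
    """

    def gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target

    span = 1.0
    while gap(target - span * sd) > 0 or gap(target + span * sd) < 0:
        span *= 2.0
        if span > 64:  # pragma: no cover - target far outside bounds
            raise CohortSpecError(
                f"cannot match mean {target} inside truncation bounds ({lo}, {hi})"
            )
    return brentq(gap, target - span * sd, target + span * sd, xtol=1e-10)


def _sample_group(
    spec: CohortSpec, group: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    means = spec.means_low if group == "low" else spec.means_high
    probs = spec.probs_low if group == "low" else spec.probs_high
    data: dict[str, np.ndarray] = {}
    for var in _SAMPLED_VARS:
        sd = spec.sds[var]
        lo, hi = spec.bounds[var]
        if not (lo <= means[var] <= hi):
            raise CohortSpecError(
                f"mean of {var!r} ({means[var]}) lies outside bounds ({lo}, {hi})"
            )
        loc = _matched_loc(means[var], sd, lo, hi)
        a, b = (lo - loc) / sd, (hi - loc) / sd
        data[var] = stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)
    data["bmi"] = data["weight"] / (data["height"] / 100.0) ** 2
    for var in BINARY_VARS:
        first, second = BINARY_LEVELS[var]
        draws = rng.random(n) < probs[var]
        data[var] = np.where(draws, second, first)
    data[LABEL] = np.repeat(group, n)
    return pd.DataFrame(data, columns=list(COLUMNS))


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table from ``spec``.

    Returns exactly ``spec.n_low + spec.n_high`` records: the low-stress
    block first, then the high-stress block.  The same ``(spec, seed)``
    pair produces a bitwise-identical table.

    Parameters
    ----------
    spec
        A validated :class:`CohortSpec`.
    seed
        Random seed; defaults to ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    low = _sample_group(spec, LABEL_LEVELS[0], spec.n_low, rng)
    high = _sample_group(spec, LABEL_LEVELS[1], spec.n_high, rng)
    return pd.concat([low, high], ignore_index=True)


def generate_imbalanced_study(seed: int = 0) -> pd.DataFrame:
    """Cohort with the survey's full-population imbalance.

    3180 records: 2529 low-stress and 651 high-stress subjects, drawn
    from the default per-group distributions.
    """
    spec = replace(default_spec(), n_low=2529, n_high=651)
    return generate_cohort(spec, seed)
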