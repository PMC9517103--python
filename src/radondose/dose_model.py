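"""Radon effective-dose model and annual-dose classification.

The effective dose from radon gas is taken proportional to the activity
concentration and the occupancy time,

    E [mSv] = C [Bq/m³] × t [h] × DCF [mSv per Bq·h·m⁻³],

with a single dose-conversion coefficient DCF that folds in the equilibrium
factor between radon and its progeny.  The default, 6.7e-6 mSv/(Bq·h·m⁻³),
is the widely used ICRP Publication 137 workplace convention (equilibrium
factor 0.4); regulators may mandate a different coefficient, so it is a
configuration field, not a constant.

Annual doses are classified against the EU Directive 2013/59/Euratom worker
categories: category B up to and including 6 mSv/year, category A above
6 mSv up to the 20 mSv/year limit for all workers, and over-limit beyond.
Pregnant or breastfeeding workers and minors carry a strict < 1 mSv limit.

Boundary conventions, applied everywhere in the package:
"6 mSv or less" → inclusive at 6; "above 6 mSv" → category A starts strictly
above; 20 mSv limit → inclusive; the special-status 1 mSv limit is strict;
all comparisons use unrounded values.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError, ValidationError

#: Recognised worker protection statuses.
WORKER_STATUSES = ("standard", "pregnant", "breastfeeding", "minor")

#: Statuses subject to the strict special dose limit.
SPECIAL_STATUSES = frozenset({"pregnant", "breastfeeding", "minor"})


@dataclass(frozen=True)
class DoseParameters:
    """All regulatory constants and the dose coefficient, user-configurable.

    Attributes
    ----------
    dose_coefficient
        mSv per (Bq·h·m⁻³) of radon-gas exposure; equilibrium factor folded in.
    reference_level
        Workplace radon reference level in Bq/m³ (exceeding it triggers
        mitigation; exactly at it does not).
    category_b_limit
        Ceiling of worker category B in mSv/year, inclusive.
    annual_dose_limit
        Effective dose limit for all workers in mSv/year, inclusive.
    special_status_limit
        Strict limit in mSv/year for pregnant/breastfeeding/minor workers.
    potential_occupancy_threshold
        Occupancy in hours/year; radon potential requires strictly more.
    min_measurement_months
        Minimum radon-measurement duration in months for a valid annual mean;
        counted as 30 days per month (a conservative floor).
    annual_window
        "calendar" (default) attributes doses to the calendar year of the job
        start date; "rolling" accumulates over the 365 days up to the job date.
    """

    dose_coefficient: float = 6.7e-6
    reference_level: float = 300.0
    category_b_limit: float = 6.0
    annual_dose_limit: float = 20.0
    special_status_limit: float = 1.0
    potential_occupancy_threshold: float = 50.0
    min_measurement_months: float = 2.0
    annual_window: str = "calendar"

    def __post_init__(self) -> None:
        for field in (
            "dose_coefficient",
            "reference_level",
            "category_b_limit",
            "annual_dose_limit",
            "special_status_limit",
            "potential_occupancy_threshold",
            "min_measurement_months",
        ):
            value = getattr(self, field)
            if not isinstance(value, (int, float)) or not value > 0:
                raise ConfigError(f"{field} must be strictly positive, got {value!r}")
        if not (self.special_status_limit < self.category_b_limit < self.annual_dose_limit):
            raise ConfigError(
                "limits must satisfy special_status_limit < category_b_limit "
                f"< annual_dose_limit, got {self.special_status_limit} / "
                f"{self.category_b_limit} / {self.annual_dose_limit}"
            )
        if self.annual_window not in ("calendar", "rolling"):
            raise ConfigError(
                f"annual_window must be 'calendar' or 'rolling', got {self.annual_window!r}"
            )

    @property
    def min_measurement_days(self) -> float:
        return 30.0 * self.min_measurement_months

    @classmethod
    def from_mapping(cls, mapping: dict) -> "DoseParameters":
        """Build parameters from a dict; unknown keys are rejected by name."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "DoseParameters":
        """Load parameters from a YAML or JSON file; every field optional."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        try:
            if path.suffix == ".json":
                data = json.loads(text)
            else:
                data = yaml.safe_load(text)
        except (json.JSONDecodeError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path} must contain a mapping, got {type(data).__name__}")
        return cls.from_mapping(data)


class WorkerCategory(enum.Enum):
    """Exposure category under Directive 2013/59/Euratom."""

    B = "B"  # ≤ 6 mSv/year: dose revision only
    A = "A"  # > 6 mSv/year: planned-exposure regime with dosimetry
    OVER_LIMIT = "OVER_LIMIT"  # > 20 mSv/year: above the limit for all workers


@dataclass(frozen=True)
class DoseAssessment:
    """Category plus status-aware compliance verdict for one annual dose."""

    category: WorkerCategory
    compliant: bool


def effective_dose(concentration: float, hours: float, params: DoseParameters) -> float:
    """Effective dose in mSv from radon concentration and occupancy time.

    Parameters
    ----------
    concentration
        Annual mean radon activity concentration in Bq/m³; must be ≥ 0.
    hours
        Occupancy time in hours; must be ≥ 0.
    params
        Regulatory parameters supplying the dose coefficient.

    Returns
    -------
    float
        ``concentration * hours * params.dose_coefficient``, full precision.
    """
    if concentration < 0:
        raise ValidationError(f"concentration must be >= 0 Bq/m³, got {concentration}")
    if hours < 0:
        raise ValidationError(f"hours must be >= 0, got {hours}")
    return concentration * hours * params.dose_coefficient


def classify_annual_dose(dose: float, status: str, params: DoseParameters) -> DoseAssessment:
    """Classify an annual dose into a worker category with a compliance flag.

    Standard workers: category B for dose ≤ ``category_b_limit``, A up to
    ``annual_dose_limit`` (inclusive), OVER_LIMIT beyond; compliant unless
    over the limit.  Special statuses (pregnant, breastfeeding, minor) are
    compliant only strictly below ``special_status_limit``; the category is
    reported alongside using the same thresholds.
    """
    if dose < 0:
        raise ValidationError(f"dose must be >= 0 mSv, got {dose}")
    if status not in WORKER_STATUSES:
        raise ValidationError(
            f"unknown worker status {status!r}; expected one of {', '.join(WORKER_STATUSES)}"
        )
    if dose <= params.category_b_limit:
        category = WorkerCategory.B
    elif dose <= params.annual_dose_limit:
        category = WorkerCategory.A
    else:
        category = WorkerCategory.OVER_LIMIT
    if status in SPECIAL_STATUSES:
        compliant = dose < params.special_status_limit
    else:
        compliant = category is not WorkerCategory.OVER_LIMIT
    return DoseAssessment(category=category, compliant=compliant)


def availability_limit(status: str, params: DoseParameters) -> tuple[float, bool]:
    """Planning ceiling for a worker status: ``(limit_mSv, inclusive)``.

    Standard workers may be planned up to the category-B ceiling inclusive;
    special statuses must stay strictly below their limit.
    """
    if status not in WORKER_STATUSES:
        raise ValidationError(f"unknown worker status {status!r}")
    if status in SPECIAL_STATUSES:
        return params.special_status_limit, False
    return params.category_b_limit, True


def within_limit(total_dose: float, status: str, params: DoseParameters) -> bool:
    """True iff ``total_dose`` is plannable for a worker of ``status``."""
    limit, inclusive = availability_limit(status, params)
    return total_dose <= limit if inclusive else total_dose < limit
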