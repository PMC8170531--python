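"""Age-specific rate inputs for the illness-death model.

The model needs three age-specific inputs: the incidence rate ``i(a)`` of the
chronic condition, the general mortality ``m(a)`` of the whole population and
the mortality rate ratio ``R(a) = m1(a)/m0(a)`` between diseased and healthy
individuals.  All three are represented as :class:`RateTable` objects --
piecewise-linear functions of age defined by knots -- and bundled into a
:class:`Scenario` together with an age range and an initial prevalence.

Two built-in scenarios emulate the regimes relevant for the method: a rare
condition with strong excess mortality in young adults (lupus-like, prevalence
well below 1%) and a common condition of older ages (type-2-diabetes-like,
prevalence of several percent).  Their rate functions are documented
parametric stand-ins chosen to produce those regimes; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import numpy as np

from .errors import (
    ExtrapolationError,
    ParseError,
    SingularityError,
    ValidationError,
)

__all__ = [
    "RateTable",
    "Scenario",
    "load_rate_table",
    "evaluate_rate",
    "builtin_scenario",
    "mortality_components",
    "BUILTIN_SCENARIOS",
]

_KINDS = ("incidence", "general_mortality", "rate_ratio")


@dataclass(frozen=True)
class RateTable:
    """A nonnegative age-indexed rate (or ratio) with linear interpolation.

    Parameters
    ----------
    ages
        Knot ages in years, strictly increasing, at least two.
    values
        Rate per person-year (incidence, mortality) or dimensionless ratio.
        Must be nonnegative; rate ratios must be strictly positive.
    kind
        One of ``incidence``, ``general_mortality``, ``rate_ratio``.
    """

    ages: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        if self.kind not in _KINDS:
            raise ValidationError(
                f"kind must be one of {_KINDS}, got {self.kind!r}"
            )
        if ages.ndim != 1 or values.ndim != 1 or ages.shape != values.shape:
            raise ValidationError("ages and values must be 1-d arrays of equal length")
        if ages.size < 2:
            raise ValidationError("a rate table needs at least 2 knots")
        if not np.all(np.isfinite(ages)) or not np.all(np.isfinite(values)):
            raise ValidationError("ages and values must be finite")
        if not np.all(np.diff(ages) > 0):
            raise ValidationError("ages must be strictly increasing")
        if np.any(values < 0):
            raise ValidationError("rate values must be nonnegative")
        if self.kind == "rate_ratio" and np.any(values <= 0):
            raise ValidationError("rate_ratio values must be strictly positive")

    @property
    def span(self) -> Tuple[float, float]:
        return float(self.ages[0]), float(self.ages[-1])

    def __call__(self, age):
        return evaluate_rate(self, age)

    def covers(self, lo: float, hi: float) -> bool:
        return self.ages[0] <= lo and hi <= self.ages[-1]


def evaluate_rate(table: RateTable, age):
    """Evaluate a :class:`RateTable` at ``age`` (scalar or array).

    Piecewise-linear between knots, exact at knots.  Ages outside the table's
    span raise :class:`~mrrest.errors.ExtrapolationError`; there is no silent
    extrapolation.
    """
    a = np.asarray(age, dtype=float)
    lo, hi = table.span
    if np.any(a < lo) or np.any(a > hi):
        raise ExtrapolationError(
            f"age {age!r} outside table span [{lo}, {hi}] for kind {table.kind!r}"
        )
    out = np.interp(a, table.ages, table.values)
    return float(out) if np.isscalar(age) or a.ndim == 0 else out


def load_rate_table(path, kind: str) -> RateTable:
    """Read a two-column CSV (age, value) into a validated :class:`RateTable`.

    An optional header line ``age,value`` is accepted.  Decimal separator is
    the dot; rows are comma-separated.  Malformed rows raise
    :class:`~mrrest.errors.ParseError` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"rate table file not found: {path}")
    ages, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1 and parts[:2] == ["age", "value"]:
                continue
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 comma-separated columns, got {len(parts)}"
                )
            try:
                ages.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric entry ({exc})") from None
    return RateTable(np.array(ages), np.array(values), kind)


@dataclass(frozen=True)
class Scenario:
    """A named bundle of the three rate inputs plus age range.

    ``initial_prevalence`` is the prevalence at the start of ``age_range``
    (default 0: disease-free at the entry age).
    """

    name: str
    incidence: RateTable
    general_mortality: RateTable
    rate_ratio: RateTable
    age_range: Tuple[float, float]
    initial_prevalence: float = 0.0

    def __post_init__(self):
        lo, hi = self.age_range
        if not lo < hi:
            raise ValidationError("age_range start must be < end")
        if not 0.0 <= self.initial_prevalence < 1.0:
            raise ValidationError("initial_prevalence must lie in [0, 1)")
        for tab, what in (
            (self.incidence, "incidence"),
            (self.general_mortality, "general_mortality"),
            (self.rate_ratio, "rate_ratio"),
        ):
            if tab.kind != what:
                raise ValidationError(f"{what} table has kind {tab.kind!r}")
            if not tab.covers(lo, hi):
                raise ValidationError(
                    f"{what} table span {tab.span} does not cover age_range {self.age_range}"
                )


def _tabulate(fn, lo: float, hi: float, kind: str, step: float = 0.5) -> RateTable:
    ages = np.arange(lo, hi + step / 2, step)
    return RateTable(ages, fn(ages), kind)


def _low_prevalence_scenario() -> Scenario:
    # Rare autoimmune-condition regime (lupus-like, adult women, ages 20-70):
    # flat incidence of 5 per 100,000 person-years; strong excess mortality
    # in the young (R = 12 at 20, in line with published standardized
    # mortality ratios of systemic lupus in young women) decaying to ~2.8 at
    # 70; Gompertz general mortality at German adult-female magnitudes
    # (1.8e-4/y at 20 to 1.5e-2/y at 70).  Entry prevalence 0.1% reflects
    # juvenile onset before 20; solved prevalence stays below 1% everywhere.
    lo, hi = 20.0, 70.0
    return Scenario(
        name="low_prevalence",
        incidence=_tabulate(lambda a: np.full_like(a, 5e-5), lo, hi, "incidence"),
        general_mortality=_tabulate(
            lambda a: np.exp(-10.39 + 0.0884 * a), lo, hi, "general_mortality"
        ),
        rate_ratio=_tabulate(
            lambda a: 2.0 + 10.0 * np.exp(-(a - 20.0) / 20.0), lo, hi, "rate_ratio"
        ),
        age_range=(lo, hi),
        initial_prevalence=1e-3,
    )


def _high_prevalence_scenario() -> Scenario:
    # Common metabolic-condition regime (type-2-diabetes-like, men, ages
    # 40-80): incidence rising from ~1.8 to ~25 per 1,000 person-years with a
    # logistic plateau in old age; rate ratio ~4.5 at 40 decaying to ~1.8 at
    # 80; Gompertz general mortality at German adult-male magnitudes
    # (1.4e-3/y at 40 to 5.8e-2/y at 80).  Disease-free at entry; solved
    # prevalence peaks above 30% at 80.
    lo, hi = 40.0, 80.0
    return Scenario(
        name="high_prevalence",
        incidence=_tabulate(
            lambda a: 0.03 / (1.0 + np.exp(-(a - 65.0) / 9.0)), lo, hi, "incidence"
        ),
        general_mortality=_tabulate(
            lambda a: np.exp(-10.296 + 0.0931 * a), lo, hi, "general_mortality"
        ),
        rate_ratio=_tabulate(
            lambda a: 1.4 + 3.1 * np.exp(-(a - 40.0) / 20.0), lo, hi, "rate_ratio"
        ),
        age_range=(lo, hi),
    )


BUILTIN_SCENARIOS = {
    "low_prevalence": _low_prevalence_scenario,
    "high_prevalence": _high_prevalence_scenario,
}


def builtin_scenario(name: str) -> Scenario:
    """Return one of the built-in simulation settings.

    ``low_prevalence`` covers ages 20-70 (rare condition, prevalence < 1%);
    ``high_prevalence`` covers ages 40-80 (common condition, peak prevalence
    above 5%).
    """
    try:
        return BUILTIN_SCENARIOS[name]()
    except KeyError:
        raise ValidationError(
            f"unknown scenario {name!r}; available: {sorted(BUILTIN_SCENARIOS)}"
        ) from None


def mortality_components(m: float, R: float, p: float) -> Tuple[float, float]:
    """Split general mortality into (m0, m1) given rate ratio and prevalence.

    Inverts m = p*m1 + (1-p)*m0 and R = m1/m0:
    m0 = m / (1 + p*(R-1)), m1 = R*m0.
    """
    if m < 0:
        raise ValidationError("general mortality m must be nonnegative")
    if R <= 0:
        raise ValidationError("rate ratio R must be positive")
    if not 0 <= p < 1:
        raise ValidationError("prevalence p must lie in [0, 1)")
    denom = 1.0 + p * (R - 1.0)
    if abs(denom) < 1e-14:
        raise SingularityError("1 + p*(R-1) vanished; mortality split undefined")
    m0 = m / denom
    return m0, R * m0
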