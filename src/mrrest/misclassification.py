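"""Misclassification maps between true and observed prevalence/incidence.

A diagnosis recorded in aggregated data has a sensitivity se (probability a
truly diseased person carries the diagnosis) and a specificity sp
(probability a truly healthy person carries none).  The observed proportion
then mixes true and false positives,

    x_obs = se * x + (1 - sp) * (1 - x),

and, for se + sp > 1, inverts exactly to

    x = (x_obs - 1 + sp) / (se + sp - 1).

Prevalence and incidence carry separate accuracy parameters (se_p, sp_p and
se_i, sp_i), each anchored at a younger and an older age and interpolated
affine-linearly in between (:class:`AccuracyProfile`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .errors import (
    InfeasibleCorrectionError,
    NonIdentifiableError,
    ValidationError,
)

__all__ = [
    "AccuracyProfile",
    "AccuracyAt",
    "accuracy_at",
    "corrupt",
    "correct_prevalence",
    "correct_incidence",
    "perturb_anchor",
    "base_case_accuracy",
    "ANCHOR_NAMES",
]

ANCHOR_NAMES = (
    "se_p_young", "se_p_old",
    "se_i_young", "se_i_old",
    "sp_p_young", "sp_p_old",
    "sp_i_young", "sp_i_old",
)


class AccuracyAt(NamedTuple):
    se_p: float
    se_i: float
    sp_p: float
    sp_i: float


@dataclass(frozen=True)
class AccuracyProfile:
    """Sensitivity/specificity anchors at a younger and an older age.

    Each of the four accuracy parameters (se_p, se_i, sp_p, sp_i) is given at
    both anchor ages and interpolated affine-linearly between them.  All anchor
    values must lie in (0, 1] and each (se, sp) pair must satisfy se + sp > 1
    (identifiability of the correction).
    """

    young_age: float
    old_age: float
    se_p_young: float
    se_p_old: float
    se_i_young: float
    se_i_old: float
    sp_p_young: float
    sp_p_old: float
    sp_i_young: float
    sp_i_old: float

    def __post_init__(self):
        if not self.young_age < self.old_age:
            raise ValidationError("young_age must be < old_age")
        for name in ANCHOR_NAMES:
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} = {v!r} must lie in (0, 1]")
        for se_name, sp_name in (
            ("se_p_young", "sp_p_young"),
            ("se_p_old", "sp_p_old"),
            ("se_i_young", "sp_i_young"),
            ("se_i_old", "sp_i_old"),
        ):
            if getattr(self, se_name) + getattr(self, sp_name) <= 1.0:
                raise ValidationError(
                    f"{se_name} + {sp_name} must exceed 1 (identifiability)"
                )

    @classmethod
    def constant(
        cls,
        young_age: float,
        old_age: float,
        se_p: float,
        se_i: float,
        sp_p: float,
        sp_i: float,
    ) -> "AccuracyProfile":
        """Profile with equal values at both anchors."""
        return cls(
            young_age=young_age, old_age=old_age,
            se_p_young=se_p, se_p_old=se_p,
            se_i_young=se_i, se_i_old=se_i,
            sp_p_young=sp_p, sp_p_old=sp_p,
            sp_i_young=sp_i, sp_i_old=sp_i,
        )

    @classmethod
    def perfect(cls, young_age: float, old_age: float) -> "AccuracyProfile":
        return cls.constant(young_age, old_age, 1.0, 1.0, 1.0, 1.0)


def accuracy_at(profile: AccuracyProfile, age: float) -> AccuracyAt:
    """Interpolate the four accuracy values affine-linearly at ``age``."""
    if not profile.young_age <= age <= profile.old_age:
        raise ValidationError(
            f"age {age} outside anchor range [{profile.young_age}, {profile.old_age}]"
        )
    w = (age - profile.young_age) / (profile.old_age - profile.young_age)

    def lerp(young, old):
        return (1.0 - w) * young + w * old

    return AccuracyAt(
        se_p=lerp(profile.se_p_young, profile.se_p_old),
        se_i=lerp(profile.se_i_young, profile.se_i_old),
        sp_p=lerp(profile.sp_p_young, profile.sp_p_old),
        sp_i=lerp(profile.sp_i_young, profile.sp_i_old),
    )


def perturb_anchor(profile: AccuracyProfile, anchor: str, value: float) -> AccuracyProfile:
    """Return a copy of ``profile`` with one anchor set to ``value``."""
    if anchor not in ANCHOR_NAMES:
        raise ValidationError(f"unknown anchor {anchor!r}; one of {ANCHOR_NAMES}")
    return replace(profile, **{anchor: value})


def base_case_accuracy(scenario_name: str) -> AccuracyProfile:
    """Base-case accuracy of the two built-in simulation settings.

    Low prevalence: se 99.5%, sp 99.999% at both 20 and 70 years.
    High prevalence: se 95%, sp 99.95% at both 40 and 80 years.
    """
    if scenario_name == "low_prevalence":
        return AccuracyProfile.constant(20.0, 70.0, 0.995, 0.995, 0.99999, 0.99999)
    if scenario_name == "high_prevalence":
        return AccuracyProfile.constant(40.0, 80.0, 0.95, 0.95, 0.9995, 0.9995)
    raise ValidationError(
        f"unknown scenario {scenario_name!r}; available: "
        "['high_prevalence', 'low_prevalence']"
    )


def _check_se_sp(se: float, sp: float) -> None:
    if not (0.0 < se <= 1.0 and 0.0 < sp <= 1.0):
        raise ValidationError("se and sp must lie in (0, 1]")


def corrupt(value, se: float, sp: float):
    """Forward misclassification map: true -> observed.

    observed = se * value + (1 - sp) * (1 - value).  ``value`` must lie in
    [0, 1]; the result does too.  Accepts scalars or arrays.
    """
    _check_se_sp(se, sp)
    v = np.asarray(value, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValidationError("value must lie in [0, 1]")
    out = se * v + (1.0 - sp) * (1.0 - v)
    return float(out) if np.isscalar(value) or v.ndim == 0 else out


def _correct(obs: float, se: float, sp: float, what: str, check: bool) -> float:
    _check_se_sp(se, sp)
    denom = se + sp - 1.0
    if denom <= 0.0:
        raise NonIdentifiableError(
            f"se + sp = {se + sp!r} <= 1: correction not identifiable"
        )
    raw = (obs - 1.0 + sp) / denom
    if check and not 0.0 <= raw <= 1.0:
        raise InfeasibleCorrectionError(raw, what)
    return raw


def correct_prevalence(p_obs: float, se_p: float, sp_p: float, check: bool = True) -> float:
    """Invert the misclassification map for an observed prevalence.

    Returns (p_obs - 1 + sp_p) / (se_p + sp_p - 1).  A result outside [0, 1]
    raises :class:`~mrrest.errors.InfeasibleCorrectionError` carrying the raw
    value (set ``check=False`` to obtain the raw value without the range
    check, e.g. when scanning for feasibility).
    """
    return _correct(p_obs, se_p, sp_p, "corrected prevalence", check)


def correct_incidence(i_obs: float, se_i: float, sp_i: float, check: bool = False) -> float:
    """Invert the misclassification map for an observed incidence rate.

    Same algebra as :func:`correct_prevalence` applied to the incidence, which
    must be supplied on a per-person-year scale.  Range checking is off by
    default because a rate is not confined to [0, 1]; pass ``check=True`` to
    enforce nonnegativity-style feasibility as for proportions.
    """
    return _correct(i_obs, se_i, sp_i, "corrected incidence", check)
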