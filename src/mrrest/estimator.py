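"""Mortality-rate-ratio estimator from prevalence, incidence and mortality.

Rearranging the prevalence ODE yields a closed-form estimator for the
mortality rate ratio R = m1/m0 at each age:

    R = 1 + (1/p) * (i - D) / (m - i + D),    D = (dp/da) / (1 - p),

given the prevalence p, its derivative dp/da, the incidence i and the general
mortality m.  When the observed prevalence/incidence suffer from imperfect
diagnostic accuracy they may be corrected first (see
:mod:`mrrest.misclassification`); applying the estimator to uncorrected
observations quantifies the resulting bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibleCorrectionError, ValidationError
from .forward import numerical_dp
from .misclassification import AccuracyProfile, accuracy_at, correct_incidence, correct_prevalence

__all__ = ["RREstimate", "estimate_R", "estimate_R_profile", "estimates_to_frame"]

#: statuses carried by :class:`RREstimate`
STATUS_OK = "ok"
STATUS_SINGULAR = "singular"
STATUS_INFEASIBLE = "infeasible_input"


@dataclass(frozen=True)
class RREstimate:
    """One age-specific mortality-rate-ratio estimate."""

    age: float
    R_hat: float
    status: str = STATUS_OK

    def __post_init__(self):
        if self.status == STATUS_OK and not np.isfinite(self.R_hat):
            raise ValidationError("status 'ok' requires a finite R_hat")


def estimate_R(
    p: float,
    dp: float,
    i: float,
    m: float,
    age: float = np.nan,
    singular_rtol: float = 1e-12,
) -> RREstimate:
    """Estimate the mortality rate ratio at one age.

    Parameters are the (true or corrected) prevalence ``p`` in (0, 1), its
    age derivative ``dp``, incidence ``i`` and general mortality ``m``.

    A denominator m - i + D with magnitude below ``singular_rtol`` times the
    scale of its terms yields status ``singular`` (R_hat = nan) rather than an
    exception: near-singular ages are a finding, not a failure.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError("prevalence p must lie strictly in (0, 1)")
    if i < 0 or m < 0:
        raise ValidationError("rates i and m must be nonnegative")
    D = dp / (1.0 - p)
    denom = m - i + D
    tol = singular_rtol * max(m, i, abs(D), 1.0)
    if abs(denom) < tol:
        return RREstimate(age=age, R_hat=np.nan, status=STATUS_SINGULAR)
    return RREstimate(age=age, R_hat=1.0 + (i - D) / denom / p, status=STATUS_OK)


def estimate_R_profile(
    ages: Sequence[float],
    p_obs: Sequence[float],
    i_obs: Sequence[float],
    m: Sequence[float],
    profile: Optional[AccuracyProfile] = None,
    dp_obs: Optional[Sequence[float]] = None,
) -> list[RREstimate]:
    """Estimate R(a) along an age grid of observed prevalence and incidence.

    When ``profile`` is given, prevalence and incidence are corrected for
    misclassification age by age before the estimator is applied.  The
    derivative dp/da of the (corrected) prevalence is by default taken from
    the series with central finite differences; a caller holding a better
    derivative of the *observed* prevalence (e.g. the analytic one in a
    simulation study) may pass it as ``dp_obs`` — it is corrected by the same
    affine rescaling as the prevalence itself.  Ages whose corrected inputs
    are infeasible (corrected proportion outside [0, 1] or nonpositive
    prevalence) carry status ``infeasible_input``.
    """
    ages = np.asarray(ages, dtype=float)
    p_obs = np.asarray(p_obs, dtype=float)
    i_obs = np.asarray(i_obs, dtype=float)
    m = np.asarray(m, dtype=float)
    if not (ages.shape == p_obs.shape == i_obs.shape == m.shape):
        raise ValidationError("ages, p_obs, i_obs, m must share one grid")

    feasible = np.ones(ages.size, dtype=bool)
    if profile is None:
        p_corr, i_corr = p_obs.copy(), i_obs.copy()
    else:
        p_corr = np.empty_like(p_obs)
        i_corr = np.empty_like(i_obs)
        for k, a in enumerate(ages):
            acc = accuracy_at(profile, a)
            try:
                p_corr[k] = correct_prevalence(p_obs[k], acc.se_p, acc.sp_p)
            except InfeasibleCorrectionError as exc:
                p_corr[k] = exc.raw_value
                feasible[k] = False
            i_corr[k] = correct_incidence(i_obs[k], acc.se_i, acc.sp_i)
            if i_corr[k] < 0:
                feasible[k] = False

    if dp_obs is None:
        # dp of the (corrected) prevalence series; infeasible p values still
        # enter the stencil, but their own ages are flagged below.
        dp = numerical_dp(ages, p_corr)
    else:
        dp_obs = np.asarray(dp_obs, dtype=float)
        if dp_obs.shape != ages.shape:
            raise ValidationError("dp_obs must align with ages")
        if profile is None:
            dp = dp_obs
        else:
            # chain rule for p = (p_obs - 1 + sp(a)) / c(a), c = se + sp - 1,
            # with affine-linear se(a), sp(a) (constant slopes)
            span = profile.old_age - profile.young_age
            sp_slope = (profile.sp_p_old - profile.sp_p_young) / span
            c_slope = sp_slope + (profile.se_p_old - profile.se_p_young) / span
            c = np.array(
                [accuracy_at(profile, a).se_p + accuracy_at(profile, a).sp_p - 1.0 for a in ages]
            )
            dp = (dp_obs + sp_slope) / c - p_corr * c_slope / c

    out: list[RREstimate] = []
    for k, a in enumerate(ages):
        if not feasible[k] or not 0.0 < p_corr[k] < 1.0:
            out.append(RREstimate(age=a, R_hat=np.nan, status=STATUS_INFEASIBLE))
            continue
        out.append(estimate_R(p_corr[k], dp[k], max(i_corr[k], 0.0), m[k], age=a))
    return out


def estimates_to_frame(estimates: Sequence[RREstimate]) -> pd.DataFrame:
    """Tabulate a sequence of estimates as a DataFrame (age, R_hat, status)."""
    return pd.DataFrame(
        {
            "age": [e.age for e in estimates],
            "R_hat": [e.R_hat for e in estimates],
            "status": [e.status for e in estimates],
        }
    )
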