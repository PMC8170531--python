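"""Specificity inversion: recover sp (and the false-positive ratio) from data.

Under the equal-accuracy assumption (the same se and sp apply to prevalence
and incidence within an age group), the prevalence ODE, combined with the
misclassification corrections, determines the specificity as a function

    sp = Φ(se, p_obs, i_obs, m, R).

Rather than transcribing the lengthy closed form, Φ is realised numerically:
:func:`inversion_residual` evaluates how far the corrected data are from
satisfying the ODE for a candidate sp, and :func:`solve_specificity` finds
the sp in (1 - se, 1] that zeroes the residual by bracketed root search.
The false-positive ratio is FPR = 1 - sp.

:func:`fpr_envelope` propagates an unknown sensitivity through the inversion:
se is drawn uniformly per age group and per Monte-Carlo sample, and the
envelope (min/max plus all samples) of the resulting FPR is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .claims import ClaimsDataset, cohort_diagonal_dp
from .errors import ValidationError
from .forward import prevalence_rhs

__all__ = [
    "InversionResult",
    "inversion_residual",
    "solve_specificity",
    "fpr_envelope",
    "EnvelopeResult",
]

STATUS_OK = "ok"
STATUS_BOUNDARY = "boundary"
STATUS_NO_ROOT = "no_root"

#: margin above the identifiability boundary sp = 1 - se for the search
_EDGE = 1e-9


@dataclass(frozen=True)
class InversionResult:
    """Outcome of one specificity inversion.

    ``status`` is ``ok`` when a root was bracketed, ``boundary`` when the
    residual has no zero but is closest to zero at sp = 1 (FPR pinned at 0),
    and ``no_root`` when no feasible specificity exists.
    """

    age: float
    se_used: float
    sp: float
    fpr: float
    status: str

    def __post_init__(self):
        if self.status == STATUS_OK:
            if not np.isfinite(self.sp):
                raise ValidationError("status 'ok' requires finite sp")
            if abs(self.fpr - (1.0 - self.sp)) > 1e-15:
                raise ValidationError("fpr must equal 1 - sp")
        if self.status == STATUS_BOUNDARY and self.sp != 1.0:
            raise ValidationError("boundary status pins sp at 1")


def inversion_residual(
    sp: float,
    se: float,
    p_obs: float,
    dp_obs: float,
    i_obs: float,
    m: float,
    R: float,
) -> float:
    """Defect of the prevalence ODE for a candidate specificity.

    The shared (se, sp) corrects p_obs and i_obs; because the correction is
    affine in the observed value with per-age constant coefficients, the
    derivative rescales as dp = dp_obs / (se + sp - 1).  The residual is
    dp minus the ODE right-hand side at the corrected values; it vanishes iff
    (se, sp) is consistent with the data and R.

    Returns nan when the corrected prevalence leaves (0, 1) (infeasible
    region, excluded from the root search).
    """
    c = se + sp - 1.0
    if c <= 0.0:
        raise ValidationError("se + sp must exceed 1")
    p = (p_obs - 1.0 + sp) / c
    if not 0.0 < p < 1.0:
        return np.nan
    i = (i_obs - 1.0 + sp) / c
    dp = dp_obs / c
    return dp - prevalence_rhs(p, i, m, R)


def solve_specificity(
    se: float,
    p_obs: float,
    dp_obs: float,
    i_obs: float,
    m: float,
    R: float,
    age: float = np.nan,
    n_scan: int = 512,
    xtol: float = 1e-12,
) -> InversionResult:
    """Solve Φ: find the specificity consistent with the observed data.

    Scans sp over (1 - se, 1] (restricted to the region where the corrected
    prevalence is feasible), brackets a sign change of the residual and
    refines it with Brent's method to ``xtol``.  If the residual never
    changes sign and its magnitude is smallest at sp = 1, the FPR is pinned
    at 0 (``boundary``); otherwise ``no_root``.  When several sign changes
    exist the root closest to sp = 1 (smallest FPR) is returned.
    """
    if not 0.0 < se <= 1.0:
        raise ValidationError("se must lie in (0, 1]")
    if R <= 0:
        raise ValidationError("R must be positive")
    for name, v in (("p_obs", p_obs), ("dp_obs", dp_obs), ("i_obs", i_obs), ("m", m)):
        if not np.isfinite(v):
            raise ValidationError(f"{name} must be finite")

    sp_lo = 1.0 - se + _EDGE
    if sp_lo >= 1.0:
        sp_lo = 1.0 - _EDGE
    grid = np.linspace(sp_lo, 1.0, n_scan)
    res = np.array(
        [inversion_residual(sp, se, p_obs, dp_obs, i_obs, m, R) for sp in grid]
    )
    finite = np.isfinite(res)
    if not finite.any():
        return InversionResult(age=age, se_used=se, sp=np.nan, fpr=np.nan, status=STATUS_NO_ROOT)

    # bracket sign changes between consecutive feasible points, nearest to sp=1 first
    idx = np.flatnonzero(finite)
    for j in range(len(idx) - 1, 0, -1):
        k0, k1 = idx[j - 1], idx[j]
        if k1 != k0 + 1:
            continue  # feasibility gap; no valid bracket
        r0, r1 = res[k0], res[k1]
        if r0 == 0.0 and r1 == 0.0:
            continue
        if r1 == 0.0 or r0 * r1 < 0.0:
            if r1 == 0.0:
                root = grid[k1]
            elif r0 == 0.0:
                root = grid[k0]
            else:
                root = brentq(
                    inversion_residual,
                    grid[k0],
                    grid[k1],
                    args=(se, p_obs, dp_obs, i_obs, m, R),
                    xtol=xtol,
                )
            root = min(root, 1.0)
            return InversionResult(
                age=age, se_used=se, sp=root, fpr=1.0 - root, status=STATUS_OK
            )

    # no sign change: boundary if |residual| is minimised at sp = 1
    finite_res = np.abs(res[finite])
    if finite[-1] and np.abs(res[-1]) <= finite_res.min() * (1 + 1e-12):
        return InversionResult(age=age, se_used=se, sp=1.0, fpr=0.0, status=STATUS_BOUNDARY)
    return InversionResult(age=age, se_used=se, sp=np.nan, fpr=np.nan, status=STATUS_NO_ROOT)


@dataclass(frozen=True)
class EnvelopeResult:
    """Monte-Carlo FPR envelope over sampled sensitivities.

    ``samples`` is a long-format table (sample, age_mid, se, sp, fpr, status);
    ``summary`` one row per age group (age_mid, fpr_min, fpr_max, n_ok,
    n_boundary, n_no_root).
    """

    samples: pd.DataFrame
    summary: pd.DataFrame
    seed: int


def fpr_envelope(
    claims: ClaimsDataset,
    se_low: float = 0.7,
    se_high: float = 0.99,
    n_samples: int = 10000,
    seed: int = 0,
) -> EnvelopeResult:
    """Envelope of the false-positive ratio under unknown sensitivity.

    For each Monte-Carlo sample and each age group, a sensitivity is drawn
    independently from Uniform(se_low, se_high) and the specificity inversion
    is solved with the group's observed prevalence change (cohort-diagonal
    derivative), observed incidence, general mortality and rate ratio.
    Samples without a feasible root are recorded with status ``no_root`` and
    excluded from the min/max envelope.

    Reproducible under a fixed ``seed``: each age group draws from its own
    deterministic substream, so the envelope of group k does not depend on the
    number of other groups' draws consumed.
    """
    if not 0.0 < se_low < se_high <= 1.0:
        raise ValidationError("require 0 < se_low < se_high <= 1")
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")

    dp_obs = cohort_diagonal_dp(claims)
    # observed prevalence at the mid-period: the two calendar years averaged
    # at the same age (exact under age-only rates, centred in time otherwise)
    p_mid = (claims.p_obs_year1 + claims.p_obs_year2) / 2.0
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(claims.n_groups)]

    rows = []
    for k in range(claims.n_groups):
        a = claims.midpoints[k]
        ses = streams[k].uniform(se_low, se_high, size=n_samples)
        for n, se in enumerate(ses):
            r = solve_specificity(
                se,
                p_mid[k],
                dp_obs[k],
                claims.i_obs[k],
                claims.m[k],
                claims.R[k],
                age=a,
            )
            rows.append((n, a, se, r.sp, r.fpr, r.status))
    samples = pd.DataFrame(
        rows, columns=["sample", "age_mid", "se", "sp", "fpr", "status"]
    )

    def summarise(g: pd.DataFrame) -> pd.Series:
        ok = g[g["status"] != STATUS_NO_ROOT]
        return pd.Series(
            {
                "fpr_min": ok["fpr"].min() if len(ok) else np.nan,
                "fpr_max": ok["fpr"].max() if len(ok) else np.nan,
                "n_ok": int((g["status"] == STATUS_OK).sum()),
                "n_boundary": int((g["status"] == STATUS_BOUNDARY).sum()),
                "n_no_root": int((g["status"] == STATUS_NO_ROOT).sum()),
            }
        )

    summary = (
        samples.groupby("age_mid", sort=True).apply(summarise, include_groups=False).reset_index()
    )
    for col in ("n_ok", "n_boundary", "n_no_root"):
        summary[col] = summary[col].astype(int)
    return EnvelopeResult(samples=samples, summary=summary, seed=seed)
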