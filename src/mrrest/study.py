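"""Simulation-study workflow: bias curves and tornado importance ranking.

The study protocol has four steps: solve the prevalence ODE for a scenario
with known rates; corrupt the resulting prevalence and incidence through the
forward misclassification map with a given accuracy profile; apply the
rate-ratio estimator to the observed (uncorrected) quantities; and compare
the estimate with the true R underlying the simulation.

Two summaries are produced: the age-specific difference between estimated and
true R (:func:`run_simulation_study`) and the summed absolute relative error
over the whole age range, which feeds a one-at-a-time tornado analysis of the
eight accuracy anchors (:func:`tornado_analysis`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .errors import ValidationError
from .estimator import STATUS_OK, estimate_R_profile
from .forward import solve_prevalence
from .misclassification import (
    ANCHOR_NAMES,
    AccuracyProfile,
    accuracy_at,
    corrupt,
    perturb_anchor,
)
from .rates import Scenario

__all__ = [
    "run_simulation_study",
    "summed_abs_relative_error",
    "tornado_analysis",
    "TornadoEntry",
]


@dataclass(frozen=True)
class TornadoEntry:
    """Outcome change attributed to one accuracy anchor (>= 0)."""

    input_name: str
    outcome_change: float


def _observed_series(scenario: Scenario, profile: AccuracyProfile, step: float):
    """Solve the scenario and corrupt p and i with the profile.

    Returns interior grid ages with true rates, the observed series and the
    true prevalence.  Endpoints are dropped: the entry age is disease-free
    (p = 0, estimator undefined) and one-sided derivative stencils at the two
    boundary ages would mix discretisation regimes into the comparison.
    """
    traj = solve_prevalence(scenario, step=step)
    ages = traj.ages
    i_true = np.asarray(scenario.incidence(ages))
    m = np.asarray(scenario.general_mortality(ages))
    R_true = np.asarray(scenario.rate_ratio(ages))

    acc = [accuracy_at(profile, a) for a in ages]
    p_obs = np.array([corrupt(p, a.se_p, a.sp_p) for p, a in zip(traj.p, acc)])
    i_obs = np.array([corrupt(i, a.se_i, a.sp_i) for i, a in zip(i_true, acc)])

    # Analytic derivative of the observed prevalence: the corruption is
    # affine in p with affine-linear age coefficients, so
    # dp_obs = se' p - sp' (1-p) + (se + sp - 1) dp with constant slopes.
    span = profile.old_age - profile.young_age
    se_slope = (profile.se_p_old - profile.se_p_young) / span
    sp_slope = (profile.sp_p_old - profile.sp_p_young) / span
    se_p = np.array([a.se_p for a in acc])
    sp_p = np.array([a.sp_p for a in acc])
    dp_obs = se_slope * traj.p - sp_slope * (1.0 - traj.p) + (se_p + sp_p - 1.0) * traj.dp
    return traj, ages, i_true, m, R_true, p_obs, i_obs, dp_obs


def run_simulation_study(
    scenario: Scenario, profile: AccuracyProfile, step: float = 0.1
) -> pd.DataFrame:
    """Run the four-step protocol for one scenario and accuracy profile.

    Returns a table over the interior age grid with columns ``age``,
    ``R_true``, ``R_obs_perfect`` (estimator applied to the uncorrupted
    series) and ``R_obs_imperfect`` (estimator applied to the corrupted
    series, no correction), plus the two status columns.
    """
    traj, ages, i_true, m, R_true, p_obs, i_obs, dp_obs = _observed_series(
        scenario, profile, step
    )
    perfect = estimate_R_profile(ages, traj.p, i_true, m, dp_obs=traj.dp)
    imperfect = estimate_R_profile(ages, p_obs, i_obs, m, dp_obs=dp_obs)
    df = pd.DataFrame(
        {
            "age": ages,
            "R_true": R_true,
            "R_obs_perfect": [e.R_hat for e in perfect],
            "status_perfect": [e.status for e in perfect],
            "R_obs_imperfect": [e.R_hat for e in imperfect],
            "status_imperfect": [e.status for e in imperfect],
        }
    )
    return df.iloc[1:-1].reset_index(drop=True)


def summed_abs_relative_error(R_true, R_est) -> float:
    """Sum of |R_est - R_true| / R_true over the age range."""
    R_true = np.asarray(R_true, dtype=float)
    R_est = np.asarray(R_est, dtype=float)
    if R_true.shape != R_est.shape:
        raise ValidationError("series must have equal length")
    if np.any(R_true <= 0):
        raise ValidationError("R_true must be positive")
    return float(np.sum(np.abs(R_est - R_true) / R_true))


def _study_outcome(
    scenario: Scenario,
    profile: AccuracyProfile,
    step: float,
    group_width: float,
) -> float:
    """Summed absolute relative error of the uncorrected estimate.

    The sum runs over an age-group grid of spacing ``group_width`` starting
    one group above the entry age (estimates over "a wide range of age
    groups"); the entry age itself is excluded because prevalence there is
    fixed by the initial condition and the estimator degenerates as p -> 0.
    """
    _, ages, i_true, m, R_true, p_obs, i_obs, dp_obs = _observed_series(
        scenario, profile, step
    )
    est = estimate_R_profile(ages, p_obs, i_obs, m, dp_obs=dp_obs)
    a0, a1 = scenario.age_range
    eval_ages = np.arange(a0 + group_width, a1 + step / 2, group_width)
    idx = [int(np.argmin(np.abs(ages - a))) for a in eval_ages]
    sel = [k for k in idx if est[k].status == STATUS_OK]
    if not sel:
        raise ValidationError("no valid estimates on the age-group grid")
    return summed_abs_relative_error(
        R_true[sel], np.array([est[k].R_hat for k in sel])
    )


def tornado_analysis(
    scenario: Scenario,
    base_profile: AccuracyProfile,
    step: float = 0.1,
    delta: float = 2e-4,
    group_width: float = 2.5,
) -> List[TornadoEntry]:
    """One-at-a-time importance of the eight accuracy anchors.

    Each anchor (se_p, se_i, sp_p, sp_i at the younger and older age) is
    lowered by the common decrement ``delta`` in turn while the other seven
    keep their base-case values; the entry records the absolute change of the
    summed absolute relative error relative to the base case.  Entries are
    sorted descending, largest (most influential input) first.

    A common perturbation size is what makes the bars comparable as input
    importances: a false-positive fraction (1 - sp) enters the observed
    prevalence and incidence additively, while (1 - se) only scales them, so
    equal decrements expose that structural asymmetry instead of weighting
    each input by its own baseline imperfection.
    """
    if delta <= 0:
        raise ValidationError("delta must be positive")
    base = _study_outcome(scenario, base_profile, step, group_width)
    entries = []
    for name in ANCHOR_NAMES:
        perturbed = perturb_anchor(base_profile, name, getattr(base_profile, name) - delta)
        outcome = _study_outcome(scenario, perturbed, step, group_width)
        entries.append(TornadoEntry(input_name=name, outcome_change=abs(outcome - base)))
    return sorted(entries, key=lambda e: e.outcome_change, reverse=True)
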