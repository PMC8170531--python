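"""Claims-style grouped datasets and their synthetic generator.

Administrative (claims) data report prevalence and incidence aggregated into
age groups rather than on a fine age grid: prevalence per group at two
calendar years several years apart, incidence at the mid-period, plus a
mortality rate ratio and general mortality per group.  The default geometry
mirrors large statutory-health-insurance reports: K = 9 groups of width 7.5
years centred at 25, 32.5, ..., 85, prevalence years six years apart.

:func:`synthesize_claims` builds such a dataset from a :class:`Scenario` with
known ground truth, so that the specificity inversion and the false-positive
envelope can be validated end to end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .forward import solve_prevalence
from .misclassification import AccuracyProfile, accuracy_at, corrupt
from .rates import Scenario

__all__ = [
    "ClaimsDataset",
    "synthesize_claims",
    "cohort_diagonal_dp",
    "load_claims",
    "save_claims",
    "DEFAULT_MIDPOINTS",
    "DEFAULT_GROUP_WIDTH",
    "DEFAULT_YEAR_GAP",
]

#: default grouped-data geometry (9 groups, width 7.5 y, centres 25..85)
DEFAULT_MIDPOINTS = tuple(25.0 + 7.5 * k for k in range(9))
DEFAULT_GROUP_WIDTH = 7.5
DEFAULT_YEAR_GAP = 6.0


@dataclass(frozen=True)
class ClaimsDataset:
    """Aggregated observed inputs per age group.

    ``p_obs_year1``/``p_obs_year2`` are observed prevalences per group at the
    two calendar years; ``i_obs`` the observed incidence rate at mid-period;
    ``R`` the mortality rate ratio (assumed free of misclassification) and
    ``m`` the general mortality, both per group.
    """

    midpoints: np.ndarray
    group_width: float
    p_obs_year1: np.ndarray
    p_obs_year2: np.ndarray
    year1: float
    year2: float
    i_obs: np.ndarray
    R: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        mids = np.asarray(self.midpoints, dtype=float)
        object.__setattr__(self, "midpoints", mids)
        for name in ("p_obs_year1", "p_obs_year2", "i_obs", "R", "m"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != mids.shape:
                raise ValidationError(f"{name} must align with midpoints")
        if mids.ndim != 1 or mids.size < 2 or not np.all(np.diff(mids) > 0):
            raise ValidationError("midpoints must be strictly increasing, >= 2 groups")
        if self.group_width <= 0:
            raise ValidationError("group_width must be positive")
        if not self.year1 < self.year2:
            raise ValidationError("year1 must be < year2")
        for name in ("p_obs_year1", "p_obs_year2"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if np.any(self.i_obs < 0) or np.any(self.m < 0):
            raise ValidationError("rates must be nonnegative")
        if np.any(self.R <= 0):
            raise ValidationError("R must be positive")

    @property
    def n_groups(self) -> int:
        return int(self.midpoints.size)

    @property
    def year_gap(self) -> float:
        return float(self.year2 - self.year1)


def cohort_diagonal_dp(claims: ClaimsDataset) -> np.ndarray:
    """Directional derivative (∂t+∂a)p per group from the two prevalence years.

    The derivative along aging cohorts splits into its two components, each
    estimated from the grouped data at the mid-period:

    * the age component ∂a p from the derivative of a cubic spline through
      the year-averaged grouped prevalence (finite differences when fewer
      than 4 groups are available), and
    * the calendar-time component ∂t p from the same-age difference of the
      two years divided by the year gap.

    This is equivalent to the cohort-diagonal difference
    [p_y2(a + g/2) - p_y1(a - g/2)] / g up to its O(g^2) truncation error,
    which the spline-derivative form removes.  The result may be negative for
    noisy data; no clipping is applied.
    """
    from scipy.interpolate import CubicSpline

    g = claims.year_gap
    mids = claims.midpoints
    p_mid = (claims.p_obs_year1 + claims.p_obs_year2) / 2.0
    if claims.n_groups >= 4:
        da = CubicSpline(mids, p_mid)(mids, 1)
    else:
        da = np.gradient(p_mid, mids)
    dt = (claims.p_obs_year2 - claims.p_obs_year1) / g
    return np.asarray(da + dt)


def _group_means(ages: np.ndarray, values: np.ndarray, mids: np.ndarray, width: float) -> np.ndarray:
    out = np.empty(mids.size)
    for k, a in enumerate(mids):
        mask = (ages >= a - width / 2) & (ages <= a + width / 2)
        if not np.any(mask):
            raise ValidationError(f"no grid points in group centred at {a}")
        out[k] = values[mask].mean()
    return out


def synthesize_claims(
    scenario: Scenario,
    profile: AccuracyProfile,
    group_midpoints: Sequence[float] = None,
    group_width: float = DEFAULT_GROUP_WIDTH,
    year_gap: float = DEFAULT_YEAR_GAP,
    seed: int = 0,
    noise_sd: float = 0.0,
    year1: float = 2009.0,
    step: float = 0.05,
) -> Tuple[ClaimsDataset, pd.DataFrame]:
    """Generate a grouped claims-like dataset with known ground truth.

    The scenario's prevalence ODE is solved on a fine grid; true prevalence,
    incidence, rate ratio and general mortality are aggregated to group means
    over each group's age span.  Observed prevalence and incidence are then
    corrupted with the accuracy profile (evaluated at each group midpoint) and
    optionally perturbed by multiplicative lognormal noise with relative
    standard deviation ``noise_sd``.  Rates are age-only, so the prevalence
    profile is identical at both calendar years before corruption/noise.

    Returns the dataset and a ground-truth table with the true ``p``, ``i``,
    ``R``, ``m`` and the accuracy values used per group.
    """
    mids = np.asarray(
        DEFAULT_MIDPOINTS if group_midpoints is None else group_midpoints, dtype=float
    )
    if year_gap <= 0:
        raise ValidationError("year_gap must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    lo, hi = scenario.age_range
    # group means need the full span; the cohort diagonal additionally reads
    # the interpolant at mids[0] - year_gap/2 and mids[-1] + year_gap/2, which
    # the linear end-segment extension covers.
    if mids[0] - group_width / 2 < lo or mids[-1] + group_width / 2 > hi:
        raise ValidationError(
            f"groups [{mids[0] - group_width / 2}, {mids[-1] + group_width / 2}] "
            f"exceed scenario age range {scenario.age_range}"
        )

    traj = solve_prevalence(scenario, step=step)
    i_grid = scenario.incidence(traj.ages)
    m_grid = scenario.general_mortality(traj.ages)
    R_grid = scenario.rate_ratio(traj.ages)

    p_true = _group_means(traj.ages, traj.p, mids, group_width)
    i_true = _group_means(traj.ages, i_grid, mids, group_width)
    m_grp = _group_means(traj.ages, m_grid, mids, group_width)
    R_grp = _group_means(traj.ages, R_grid, mids, group_width)

    acc = [accuracy_at(profile, a) for a in mids]
    p_obs = np.array([corrupt(p, ac.se_p, ac.sp_p) for p, ac in zip(p_true, acc)])
    i_obs = np.array([corrupt(i, ac.se_i, ac.sp_i) for i, ac in zip(i_true, acc)])

    rng = np.random.default_rng(seed)
    p_obs_y1, p_obs_y2 = p_obs.copy(), p_obs.copy()
    if noise_sd > 0:
        sigma = np.sqrt(np.log1p(noise_sd**2))
        mu = -sigma**2 / 2  # unit-mean lognormal
        def jitter(x):
            return np.clip(x * rng.lognormal(mu, sigma, size=x.shape), 0.0, 1.0)
        p_obs_y1 = jitter(p_obs_y1)
        p_obs_y2 = jitter(p_obs_y2)
        i_obs = i_obs * rng.lognormal(mu, sigma, size=i_obs.shape)

    dataset = ClaimsDataset(
        midpoints=mids,
        group_width=group_width,
        p_obs_year1=p_obs_y1,
        p_obs_year2=p_obs_y2,
        year1=year1,
        year2=year1 + year_gap,
        i_obs=i_obs,
        R=R_grp,
        m=m_grp,
    )
    truth = pd.DataFrame(
        {
            "age_mid": mids,
            "p": p_true,
            "i": i_true,
            "R": R_grp,
            "m": m_grp,
            "se_p": [a.se_p for a in acc],
            "se_i": [a.se_i for a in acc],
            "sp_p": [a.sp_p for a in acc],
            "sp_i": [a.sp_i for a in acc],
        }
    )
    return dataset, truth


_META_KEYS = ("year1", "year2", "group_width")


def save_claims(claims: ClaimsDataset, path) -> None:
    """Write a claims dataset as CSV with ``# key=value`` metadata comments."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "age_mid": claims.midpoints,
            "p_obs_y1": claims.p_obs_year1,
            "p_obs_y2": claims.p_obs_year2,
            "i_obs": claims.i_obs,
            "R": claims.R,
            "m": claims.m,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# year1={claims.year1}\n")
        fh.write(f"# year2={claims.year2}\n")
        fh.write(f"# group_width={claims.group_width}\n")
        df.to_csv(fh, index=False)


def load_claims(path) -> ClaimsDataset:
    """Read a claims dataset written by :func:`save_claims`."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"claims file not found: {path}")
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            try:
                key, value = line[1:].strip().split("=", 1)
                meta[key.strip()] = float(value)
            except ValueError:
                raise ParseError(f"{path}: malformed metadata line {line!r}") from None
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise ParseError(f"{path}: missing metadata keys {missing}")
    df = pd.read_csv(path, comment="#")
    required = {"age_mid", "p_obs_y1", "p_obs_y2", "i_obs", "R", "m"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return ClaimsDataset(
        midpoints=df["age_mid"].to_numpy(),
        group_width=meta["group_width"],
        p_obs_year1=df["p_obs_y1"].to_numpy(),
        p_obs_year2=df["p_obs_y2"].to_numpy(),
        year1=meta["year1"],
        year2=meta["year2"],
        i_obs=df["i_obs"].to_numpy(),
        R=df["R"].to_numpy(),
        m=df["m"].to_numpy(),
    )
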