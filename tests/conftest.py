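import numpy as np
import pytest

from mrrest import (
    AccuracyProfile,
    base_case_accuracy,
    builtin_scenario,
    solve_prevalence,
    synthesize_claims,
)

SCENARIO_NAMES = ("low_prevalence", "high_prevalence")

#: group geometry used for synthetic claims inside the high-prevalence range
CLAIMS_MIDPOINTS = np.arange(45.0, 76.0, 5.0)
CLAIMS_WIDTH = 5.0
CLAIMS_YEAR_GAP = 6.0


@pytest.fixture(scope="session", params=SCENARIO_NAMES)
def scenario(request):
    return builtin_scenario(request.param)


@pytest.fixture(scope="session")
def low_scenario():
    return builtin_scenario("low_prevalence")


@pytest.fixture(scope="session")
def high_scenario():
    return builtin_scenario("high_prevalence")


@pytest.fixture(scope="session")
def trajectory(scenario):
    return solve_prevalence(scenario, step=0.1)


@pytest.fixture(scope="session")
def base_profile(scenario):
    return base_case_accuracy(scenario.name)


@pytest.fixture(scope="session")
def claims_with_truth(high_scenario):
    """Noise-free grouped dataset with constant (se, sp) = (0.9, 0.999)."""
    profile = AccuracyProfile.constant(40.0, 80.0, 0.9, 0.9, 0.999, 0.999)
    claims, truth = synthesize_claims(
        high_scenario,
        profile,
        group_midpoints=CLAIMS_MIDPOINTS,
        group_width=CLAIMS_WIDTH,
        year_gap=CLAIMS_YEAR_GAP,
        seed=7,
    )
    return claims, truth


def grid_search_specificity(se, p_obs, dp_obs, i_obs, m, R, resolution=1e-6):
    """Independent exhaustive-search oracle for the specificity inversion.

    Evaluates the prevalence-equation defect on a uniform sp lattice over
    (1 - se, 1] and returns the lattice point with the smallest |defect|
    among feasible candidates (corrected prevalence inside (0, 1)).
    """
    lo = 1.0 - se + resolution
    sp = np.arange(lo, 1.0 + resolution / 2, resolution)
    c = se + sp - 1.0
    p = (p_obs - 1.0 + sp) / c
    i = (i_obs - 1.0 + sp) / c
    dp = dp_obs / c
    q = p * (R - 1.0)
    res = dp - (1.0 - p) * (i - m * q / (1.0 + q))
    res[(p <= 0.0) | (p >= 1.0)] = np.nan
    if np.all(np.isnan(res)):
        return np.nan
    return float(sp[np.nanargmin(np.abs(res))])
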