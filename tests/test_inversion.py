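import numpy as np
import pytest

from mrrest import (
    ValidationError,
    corrupt,
    fpr_envelope,
    inversion_residual,
    solve_specificity,
)
from mrrest.forward import prevalence_rhs
from tests.conftest import grid_search_specificity


def _synthetic_instance(rng):
    """A self-consistent (p, dp, i, m, R) point corrupted with known (se, sp)."""
    p = rng.uniform(0.005, 0.3)
    i = rng.uniform(1e-4, 0.02)
    m = rng.uniform(5e-4, 0.05)
    R = rng.uniform(1.2, 8.0)
    dp = prevalence_rhs(p, i, m, R)
    se = rng.uniform(0.7, 0.99)
    sp = rng.uniform(0.995, 1.0)
    c = se + sp - 1.0
    return dict(
        se=se, sp=sp, p_obs=corrupt(p, se, sp), dp_obs=c * dp,
        i_obs=corrupt(i, se, sp), m=m, R=R,
    )


class TestInversionResidual:
    def test_zero_at_true_specificity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            inst = _synthetic_instance(rng)
            res = inversion_residual(
                inst["sp"], inst["se"], inst["p_obs"], inst["dp_obs"],
                inst["i_obs"], inst["m"], inst["R"],
            )
            assert abs(res) < 1e-10

    def test_nonzero_away_from_true_specificity(self):
        rng = np.random.default_rng(1)
        inst = _synthetic_instance(rng)
        if inst["sp"] < 0.9999:
            res = inversion_residual(
                1.0, inst["se"], inst["p_obs"], inst["dp_obs"],
                inst["i_obs"], inst["m"], inst["R"],
            )
            assert abs(res) > 1e-8

    def test_zero_for_perfect_accuracy_on_consistent_data(self):
        p, i, m, R = 0.05, 0.003, 0.01, 3.0
        dp = prevalence_rhs(p, i, m, R)
        assert inversion_residual(1.0, 1.0, p, dp, i, m, R) == pytest.approx(0.0, abs=1e-15)

    def test_requires_identifiability(self):
        with pytest.raises(ValidationError):
            inversion_residual(0.4, 0.5, 0.1, 0.0, 0.01, 0.01, 2.0)

    def test_infeasible_region_is_nan(self):
        # sp below 1 - p_obs makes the corrected prevalence negative
        res = inversion_residual(0.9899, 0.99, 0.01, 0.0, 0.001, 0.01, 2.0)
        assert np.isnan(res)


class TestSolveSpecificity:
    def test_recovers_known_specificity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            inst = _synthetic_instance(rng)
            r = solve_specificity(
                inst["se"], inst["p_obs"], inst["dp_obs"],
                inst["i_obs"], inst["m"], inst["R"],
            )
            assert r.status in ("ok", "boundary")
            assert r.sp == pytest.approx(inst["sp"], abs=1e-6)
            assert r.fpr == pytest.approx(1.0 - inst["sp"], abs=1e-6)

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            inst = _synthetic_instance(rng)
            r = solve_specificity(
                inst["se"], inst["p_obs"], inst["dp_obs"],
                inst["i_obs"], inst["m"], inst["R"],
            )
            oracle = grid_search_specificity(
                inst["se"], inst["p_obs"], inst["dp_obs"],
                inst["i_obs"], inst["m"], inst["R"],
            )
            assert r.sp == pytest.approx(oracle, abs=2e-6)

    def test_perfect_data_fixed_point(self):
        p, i, m, R = 0.05, 0.003, 0.01, 3.0
        dp = prevalence_rhs(p, i, m, R)
        r = solve_specificity(1.0, p, dp, i, m, R)
        assert r.sp == pytest.approx(1.0, abs=1e-9)
        assert r.fpr == pytest.approx(0.0, abs=1e-9)

    def test_boundary_when_only_perfect_specificity_feasible(self):
        # data corrupted with sp = 1 then pushed so the root exceeds 1:
        # the residual keeps one sign on (1-se, 1] and is smallest at sp = 1
        p, i, m, R, se = 0.08, 0.004, 0.015, 2.5, 0.9
        dp = prevalence_rhs(p, i, m, R)
        r = solve_specificity(se, se * p, se * dp + 1e-5, se * i, m, R)
        assert r.status == "boundary"
        assert r.sp == 1.0
        assert r.fpr == 0.0

    def test_invalid_sensitivity(self):
        with pytest.raises(ValidationError):
            solve_specificity(0.0, 0.1, 0.0, 0.001, 0.01, 2.0)


class TestFprEnvelope:
    def test_deterministic_under_seed(self, claims_with_truth):
        claims, _ = claims_with_truth
        a = fpr_envelope(claims, 0.7, 0.99, n_samples=50, seed=4)
        b = fpr_envelope(claims, 0.7, 0.99, n_samples=50, seed=4)
        assert a.samples.equals(b.samples)
        assert a.summary.equals(b.summary)

    def test_envelope_structure(self, claims_with_truth):
        claims, _ = claims_with_truth
        env = fpr_envelope(claims, 0.7, 0.99, n_samples=100, seed=5)
        s = env.summary
        assert len(s) == claims.n_groups
        assert np.all(s.fpr_min <= s.fpr_max)
        assert np.all(s.fpr_min >= 0.0)
        assert np.all(s.fpr_max <= 0.3)
        assert np.all(s[["n_ok", "n_boundary", "n_no_root"]].sum(axis=1) == 100)

    def test_single_sample_at_true_sensitivity_recovers_fpr(self, claims_with_truth):
        claims, _ = claims_with_truth
        eps = 1e-9
        env = fpr_envelope(claims, 0.9 - eps, 0.9 + eps, n_samples=1, seed=6)
        assert np.allclose(env.summary.fpr_max, 1e-3, atol=1e-4)

    def test_invalid_range_rejected(self, claims_with_truth):
        claims, _ = claims_with_truth
        with pytest.raises(ValidationError):
            fpr_envelope(claims, 0.99, 0.7, n_samples=10, seed=0)
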