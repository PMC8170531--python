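import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrrest import (
    AccuracyProfile,
    InfeasibleCorrectionError,
    NonIdentifiableError,
    ValidationError,
    accuracy_at,
    base_case_accuracy,
    correct_incidence,
    correct_prevalence,
    corrupt,
    perturb_anchor,
)

se_sp_pairs = st.tuples(st.floats(0.55, 1.0), st.floats(0.55, 1.0)).filter(
    lambda t: t[0] + t[1] > 1.0 + 1e-6
)


class TestAccuracyProfile:
    def test_identifiability_enforced(self):
        with pytest.raises(ValidationError, match="exceed 1"):
            AccuracyProfile.constant(20.0, 70.0, 0.4, 0.9, 0.5, 0.99)

    def test_anchor_range_enforced(self):
        with pytest.raises(ValidationError):
            AccuracyProfile.constant(70.0, 20.0, 0.9, 0.9, 0.99, 0.99)

    def test_base_case_values(self):
        low = base_case_accuracy("low_prevalence")
        acc = accuracy_at(low, 45.0)  # equal anchors: constant in age
        assert acc.se_p == acc.se_i == pytest.approx(0.995)
        assert acc.sp_p == acc.sp_i == pytest.approx(0.99999)
        high = base_case_accuracy("high_prevalence")
        acc = accuracy_at(high, 60.0)
        assert acc.se_p == pytest.approx(0.95)
        assert acc.sp_p == pytest.approx(0.9995)

    def test_affine_interpolation_midpoint(self):
        prof = AccuracyProfile(
            young_age=40.0, old_age=80.0,
            se_p_young=0.9, se_p_old=1.0,
            se_i_young=0.9, se_i_old=1.0,
            sp_p_young=0.99, sp_p_old=0.999,
            sp_i_young=0.99, sp_i_old=0.999,
        )
        acc = accuracy_at(prof, 60.0)
        assert acc.se_p == pytest.approx(0.95)
        assert acc.sp_p == pytest.approx(0.9945)

    def test_endpoint_exactness(self):
        prof = base_case_accuracy("high_prevalence")
        assert accuracy_at(prof, prof.young_age).se_p == prof.se_p_young

    def test_age_outside_anchor_range(self):
        with pytest.raises(ValidationError, match="outside"):
            accuracy_at(base_case_accuracy("low_prevalence"), 80.0)

    def test_perturb_anchor_replaces_one_value(self):
        prof = base_case_accuracy("low_prevalence")
        pert = perturb_anchor(prof, "sp_i_young", 1.0)
        assert pert.sp_i_young == 1.0
        assert pert.sp_i_old == prof.sp_i_old


class TestCorruptAndCorrect:
    def test_corrupt_hand_value(self):
        assert corrupt(0.1, 0.95, 0.999) == pytest.approx(0.0959, rel=1e-12)

    def test_perfect_accuracy_is_identity(self):
        assert corrupt(0.37, 1.0, 1.0) == 0.37
        assert correct_prevalence(0.37, 1.0, 1.0) == pytest.approx(0.37, rel=1e-15)
        assert correct_incidence(0.002, 1.0, 1.0) == pytest.approx(0.002, rel=1e-15)

    def test_false_positive_floor(self):
        assert corrupt(0.0, 0.9, 0.998) == pytest.approx(0.002, rel=1e-12)

    @pytest.mark.parametrize(
        "obs, se, sp, expected",
        [
            (0.0959, 0.95, 0.999, 0.1),
            (0.05, 0.95, 0.9995, 0.0495 / 0.9495),  # hand evaluation
        ],
    )
    def test_correct_prevalence_hand_values(self, obs, se, sp, expected):
        assert correct_prevalence(obs, se, sp) == pytest.approx(expected, rel=1e-10)

    def test_correct_incidence_hand_value(self):
        assert correct_incidence(0.0015, 0.95, 0.9995) == pytest.approx(
            0.001 / 0.9495, rel=1e-10
        )

    def test_non_identifiable_raises(self):
        with pytest.raises(NonIdentifiableError):
            correct_prevalence(0.1, 0.5, 0.5)

    def test_infeasible_result_flagged_not_clipped(self):
        # observed below the false-positive floor implies negative prevalence
        with pytest.raises(InfeasibleCorrectionError) as exc:
            correct_prevalence(0.001, 0.95, 0.99)
        assert exc.value.raw_value < 0.0
        raw = correct_prevalence(0.001, 0.95, 0.99, check=False)
        assert raw == pytest.approx(exc.value.raw_value)

    def test_value_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            corrupt(1.5, 0.9, 0.99)

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(x=st.floats(0.0, 1.0), pair=se_sp_pairs)
    def test_corrupt_correct_exact_inverse(self, x, pair):
        se, sp = pair
        assert correct_prevalence(corrupt(x, se, sp), se, sp) == pytest.approx(
            x, rel=1e-12, abs=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(pair=se_sp_pairs, a=st.floats(0.0, 1.0), b=st.floats(0.0, 1.0))
    def test_corrupt_strictly_increasing(self, pair, a, b):
        se, sp = pair
        lo, hi = sorted((a, b))
        if hi - lo > 1e-12:
            assert corrupt(hi, se, sp) > corrupt(lo, se, sp)
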