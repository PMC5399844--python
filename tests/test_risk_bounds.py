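"""Risk-scale bounds: published values, hand-worked cases, boundary
conventions, and equivalence with independent oracles."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import sccbounds as sb
from sccbounds.risk_bounds import (
    global_risk_lb_arr,
    sjolander_specific_lb_arr,
    specific_risk_lb_arr,
)

from conftest import random_risk_matrix
from test_contrasts import brute_force_contrasts


def brute_force_global_lb(R):
    """Direct scalar evaluation of the contrast minimisation (no log space)."""
    L1, L2 = R.shape
    best = 1.0
    for u in brute_force_contrasts(L1):
        for v in brute_force_contrasts(L2):
            prod = 1.0
            for i in range(L1):
                for j in range(L2):
                    prod *= (1.0 - R[i, j]) ** (u[i] * v[j])
            best = min(best, prod, 1.0)
    return 1.0 - best


class TestSpecificBounds:
    def test_hypertension_cohort_values(self, hypertension_risks):
        R = hypertension_risks
        assert round(sb.specific_risk_lb(R, "high", "old"), 4) == 0.0411
        assert round(sb.specific_rp_lb(R, "high", "old"), 4) == 0.1509
        assert sb.specific_risk_ub(R, "high", "old") == pytest.approx(278 / 1021)
        for i, j in [("low", "young"), ("low", "old"), ("high", "young")]:
            assert round(sb.specific_risk_lb(R, i, j), 4) == 0.0
        # 1-based integer indexing is equivalent to labels
        assert sb.specific_risk_lb(R, 2, 2) == sb.specific_risk_lb(R, "high", "old")

    def test_hand_worked_2x2(self):
        R = sb.RiskMatrix([[0.5, 0.5], [0.5, 0.875]])
        # ratio = (1-0.875) / (0.5 * 0.5) = 0.5
        assert sb.specific_risk_lb(R, 2, 2) == pytest.approx(0.5, abs=1e-12)
        assert sb.specific_rp_lb(R, 2, 2) == pytest.approx(0.5 / 0.875, abs=1e-12)

    def test_zero_matrix_gives_zero(self):
        R = sb.RiskMatrix(np.zeros((3, 3)))
        assert sb.specific_risk_lb(R, 1, 1) == 0.0
        assert sb.specific_rp_lb(R, 1, 1) == 0.0  # 0/0 convention
        assert sb.specific_risk_ub(R, 2, 3) == 0.0

    def test_sure_risk_conventions(self):
        # numerator zero, denominators positive -> bound 1 (and a warning)
        with pytest.warns(RuntimeWarning):
            R = sb.RiskMatrix([[0.2, 0.3], [0.4, 1.0]])
            assert sb.specific_risk_lb(R, 2, 2) == 1.0
            assert sb.specific_rp_lb(R, 2, 2) == 1.0
        # a zero denominator factor makes every comparison uninformative
        with pytest.warns(RuntimeWarning):
            R = sb.RiskMatrix([[0.5, 1.0], [0.3, 0.2]])
            assert sb.specific_risk_lb(R, 1, 1) == 0.0

    def test_index_errors_name_the_axis(self, hypertension_risks):
        with pytest.raises(ValueError, match="axis 1"):
            sb.specific_risk_lb(hypertension_risks, 3, 1)
        with pytest.raises(ValueError, match="axis 2"):
            sb.specific_risk_ub(hypertension_risks, 1, "elderly")


class TestEq9BinaryClosedForm:
    """On 2x2 grids the general minimum has a single term; the shared code
    path must equal the direct binary formula."""

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            R = random_risk_matrix(rng, 2, 2)
            m = sb.RiskMatrix(R)
            for i, j in [(1, 1), (1, 2), (2, 1), (2, 2)]:
                a, b = i - 1, j - 1
                direct = 1.0 - min(
                    (1 - R[a, b]) / ((1 - R[1 - a, b]) * (1 - R[a, 1 - b])), 1.0
                )
                assert sb.specific_risk_lb(m, i, j) == pytest.approx(direct, abs=1e-12)


class TestGlobalBounds:
    def test_hypertension_cohort_values(self, hypertension_risks):
        assert round(sb.global_risk_lb(hypertension_risks), 4) == 0.0830
        assert round(sb.global_risk_ub(hypertension_risks), 4) == 0.4718
        assert round(sb.global_rp_lb(hypertension_risks), 4) == 0.1758

    def test_hand_worked_2x2(self):
        R = sb.RiskMatrix([[0.5, 0.5], [0.5, 0.875]])
        # signed product (0.5 * 0.125) / (0.5 * 0.5) = 0.25 -> LB 0.75
        assert sb.global_risk_lb(R) == pytest.approx(0.75, abs=1e-12)
        assert sb.global_risk_ub(R) == pytest.approx(1 - 0.5**3 * 0.125, abs=1e-12)
        assert sb.global_rp_lb(R) == pytest.approx(0.75 / 0.984375, abs=1e-12)

    def test_multiplicative_structure_is_null(self):
        # survival 1-R_ij = a_i * b_j -> every signed product is exactly 1
        a = np.array([0.9, 0.7, 0.6])
        b = np.array([0.95, 0.8])
        R = sb.RiskMatrix(1.0 - np.outer(a, b))
        assert sb.global_risk_lb(R) == pytest.approx(0.0, abs=1e-12)
        assert sb.global_rp_lb(R) == pytest.approx(0.0, abs=1e-12)

    def test_sure_risk_conventions(self):
        with pytest.warns(RuntimeWarning):
            # a single sure-risk cell: some contrast gives it exponent +1,
            # the product collapses to 0 and the bound to 1
            R = sb.RiskMatrix([[0.2, 0.3], [0.4, 1.0]])
            assert sb.global_risk_lb(R) == 1.0
            assert sb.global_risk_ub(R) == 1.0
        with pytest.warns(RuntimeWarning):
            # two sure-risk cells sharing a row get opposite exponents in
            # every contrast pair, so each pair has a diverging factor and
            # is capped as uninformative
            R = sb.RiskMatrix([[1.0, 1.0], [0.3, 0.4]])
            assert sb.global_risk_lb(R) == 0.0

    def test_zero_matrix(self):
        R = sb.RiskMatrix(np.zeros((2, 3)))
        assert sb.global_risk_ub(R) == 0.0
        assert sb.global_rp_lb(R) == 0.0  # 0/0 convention

    @pytest.mark.parametrize("shape", [(2, 2), (2, 3), (3, 3), (4, 3), (4, 4)])
    def test_brute_force_oracle(self, shape):
        rng = np.random.default_rng(sum(shape))
        for _ in range(8):
            R = random_risk_matrix(rng, *shape)
            assert sb.global_risk_lb(sb.RiskMatrix(R)) == pytest.approx(
                brute_force_global_lb(R), abs=1e-12
            )

    def test_argmin_pair_is_reported_and_attains_minimum(self, hypertension_risks):
        lb, (u, v) = sb.global_risk_lb_detail(hypertension_risks)
        S = 1.0 - hypertension_risks.values
        prod = float(np.prod(S ** np.outer(u, v)))
        assert 1.0 - min(prod, 1.0) == pytest.approx(lb, abs=1e-12)


class TestPrism:
    def test_hypertension_value_and_equivalence(self, hypertension_risks):
        S = 1.0 - hypertension_risks.values
        expected = (S[1, 0] * S[0, 1]) / (S[1, 1] * S[0, 0])
        p = sb.prism(hypertension_risks)
        assert p == pytest.approx(expected, abs=1e-12)
        assert 1 - min(p, 1 / p) == pytest.approx(
            sb.global_risk_lb(hypertension_risks), abs=1e-12
        )
        assert round(1 - min(p, 1 / p), 4) == 0.0830

    def test_binary_equivalence_random(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            m = sb.RiskMatrix(random_risk_matrix(rng, 2, 2))
            p = sb.prism(m)
            assert sb.global_risk_lb(m) == pytest.approx(
                1 - min(p, 1 / p), abs=1e-12
            )

    def test_row_swap_inverts(self):
        rng = np.random.default_rng(3)
        m = sb.RiskMatrix(random_risk_matrix(rng, 2, 2))
        swapped = m.permute([1, 0], [0, 1])
        assert sb.prism(swapped) == pytest.approx(1 / sb.prism(m), abs=1e-12)

    def test_requires_2x2(self):
        with pytest.raises(ValueError, match="2x2"):
            sb.prism(sb.RiskMatrix(np.full((3, 2), 0.1)))


class TestSjolanderAndDominance:
    def test_hypertension_value(self, hypertension_risks):
        R = hypertension_risks.values
        expected = max(R[1, 1] - R[0, 1] - R[1, 0], 0.0)
        got = sb.sjolander_specific_lb(hypertension_risks, "high", "old")
        assert got == pytest.approx(expected, abs=1e-12)
        assert round(got, 4) == 0.0150

    def test_clamps_at_zero(self):
        m = sb.RiskMatrix([[0.3, 0.3], [0.3, 0.3]])
        assert sb.sjolander_specific_lb(m, 2, 2) == 0.0
        assert sb.sjolander_specific_lb(sb.RiskMatrix(np.zeros((2, 2))), 1, 1) == 0.0

    @pytest.mark.parametrize("shape", [(2, 2), (3, 3), (4, 2)])
    def test_dominance_over_sjolander(self, shape):
        """The no-redundancy lower bound is never below the assumption-free
        one (10^4 random matrices per shape)."""
        rng = np.random.default_rng(11)
        R = rng.uniform(0, 1, size=(10_000, *shape))
        ours = specific_risk_lb_arr(R)
        theirs = sjolander_specific_lb_arr(R)
        assert np.all(ours >= theirs - 1e-12)


class TestStructuralProperties:
    def test_ordering_invariants(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            L1, L2 = rng.integers(2, 5, size=2)
            m = sb.RiskMatrix(rng.uniform(0, 1, size=(L1, L2)))
            res = sb.all_bounds(m)
            assert np.all(res.specific_risk_lb >= -1e-15)
            assert np.all(res.specific_risk_lb <= res.specific_risk_ub + 1e-12)
            assert np.all(res.specific_risk_ub <= 1.0)
            assert np.all(res.specific_rp_lb <= 1.0 + 1e-12)
            assert res.global_risk_lb <= res.global_risk_ub + 1e-12
            assert res.global_rp_lb <= res.global_rp_ub == 1.0

    def test_exchangeability_under_level_permutation(self):
        rng = np.random.default_rng(23)
        m = sb.RiskMatrix(random_risk_matrix(rng, 3, 4))
        res = sb.all_bounds(m)
        for o1 in permutations(range(3)):
            o2 = tuple(rng.permutation(4))
            pm = m.permute(o1, o2)
            pres = sb.all_bounds(pm)
            assert pres.global_risk_lb == pytest.approx(res.global_risk_lb, abs=1e-12)
            assert pres.global_risk_ub == pytest.approx(res.global_risk_ub, abs=1e-12)
            np.testing.assert_allclose(
                pres.specific_risk_lb,
                res.specific_risk_lb[np.ix_(o1, o2)],
                atol=1e-12,
            )

    def test_all_bounds_composes_per_operation_calls(self):
        rng = np.random.default_rng(29)
        m = sb.RiskMatrix(random_risk_matrix(rng, 4, 3))
        res = sb.all_bounds(m)
        for i in range(1, 5):
            for j in range(1, 4):
                assert res.specific_risk_lb[i - 1, j - 1] == sb.specific_risk_lb(m, i, j)
                assert res.specific_risk_ub[i - 1, j - 1] == sb.specific_risk_ub(m, i, j)
                assert res.specific_rp_lb[i - 1, j - 1] == sb.specific_rp_lb(m, i, j)
        assert res.global_risk_lb == sb.global_risk_lb(m)
        assert res.global_risk_ub == sb.global_risk_ub(m)
        assert res.global_rp_lb == sb.global_rp_lb(m)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    hnp.arrays(
        float,
        (3, 3),
        elements=st.floats(0.0, 1.0, allow_nan=False, allow_infinity=False),
    )
)
def test_bound_ordering_holds_for_arbitrary_risks(R):
    """0 <= specific LB <= UB <= 1 and global LB <= UB for any risk grid,
    including boundary risks of exactly 0 or 1."""
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        res = sb.all_bounds(sb.RiskMatrix(R))
    assert np.all(res.specific_risk_lb >= 0.0)
    assert np.all(res.specific_risk_lb <= res.specific_risk_ub + 1e-12)
    assert 0.0 <= res.global_risk_lb <= 1.0
    assert res.global_risk_lb <= res.global_risk_ub + 1e-12
    assert 0.0 <= res.global_rp_lb <= 1.0 + 1e-12


def test_risk_matrix_validation():
    with pytest.raises(ValueError):
        sb.RiskMatrix([[0.5]])
    with pytest.raises(ValueError):
        sb.RiskMatrix([[0.5, 1.2], [0.1, 0.2]])
    with pytest.raises(ValueError, match="duplicate"):
        sb.RiskMatrix(np.zeros((2, 2)), ("a", "a"), ("x", "y"))
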