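"""Unit and property tests for the power-law model and its estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

import fractalsad as fs
from fractalsad.errors import (
    DivergentSeriesError,
    InsufficientRanksError,
    InvalidArgumentError,
    InvalidSampleError,
)

from conftest import make_random_sad

GAMMA = 0.5772156649015329


def sse_minimizer_oracle(sample: fs.RankAbundance) -> float:
    """Independent estimate: dense grid + bounded scalar minimization of the SSE."""
    F = np.log(sample.abundances / sample.abundances[0])
    D = np.log(np.arange(1, sample.S + 1))

    def sse(p):
        resid = -p * D - F
        return float(resid @ resid)

    grid = np.linspace(-10, 10, 2001)
    best = grid[int(np.argmin([sse(p) for p in grid]))]
    res = minimize_scalar(sse, bounds=(best - 0.02, best + 0.02), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


class TestPredictSad:
    @pytest.mark.parametrize(
        "p, S, A1, expected",
        [
            (1, 6, 1, [1, 1 / 2, 1 / 3, 1 / 4, 1 / 5, 1 / 6]),
            (0, 4, 5, [5, 5, 5, 5]),
            (2, 3, 1, [1, 0.25, 1 / 9]),
        ],
    )
    def test_examples(self, p, S, A1, expected):
        sad = fs.predict_sad(p, S, A1)
        np.testing.assert_allclose(sad.abundances, expected, rtol=0, atol=0)
        assert sad.abundances[0] == A1
        assert sad.S == S

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            fs.predict_sad(1, 0)
        with pytest.raises(InvalidArgumentError):
            fs.predict_sad(1, 5, A1=0)
        with pytest.raises(InvalidArgumentError):
            fs.predict_sad(1, 5, A1=-2)


class TestRankAbundance:
    def test_rejects_unsorted_and_nonpositive(self):
        with pytest.raises(InvalidSampleError):
            fs.RankAbundance("bad", [1, 2, 3])
        with pytest.raises(InvalidSampleError):
            fs.RankAbundance("bad", [3, 0, 1])
        with pytest.raises(InvalidSampleError):
            fs.RankAbundance("bad", [])

    def test_from_counts_drops_zeros_and_ranks(self):
        s = fs.RankAbundance.from_counts("x", [0, 5, 0, 2, 9])
        assert s.abundances.tolist() == [9, 5, 2]
        assert s.S == 3 and s.A_T == 16

    def test_from_counts_stable_ties_by_species_label(self):
        s = fs.RankAbundance.from_counts(
            "x", [4, 7, 4], species=["b", "c", "a"]
        )
        # both rank-2 candidates have abundance 4; label "a" sorts first
        assert s.abundances.tolist() == [7, 4, 4]

    def test_from_counts_rejects_negative(self):
        with pytest.raises(InvalidSampleError):
            fs.RankAbundance.from_counts("x", [3, -1, 2])


class TestEstimateP:
    def test_zipf_worked_example_is_exact(self):
        """Counts proportional to 1, 1/2, ..., 1/6 give exponent exactly 1."""
        s = fs.RankAbundance("zipf6", np.array([60, 30, 20, 15, 12, 10.0]))
        fit = fs.estimate_p(s)
        assert fit.p == 1.0
        assert fit.S == fit.n_used == 6

    def test_flat_sad_gives_zero(self):
        for S in (2, 5, 40):
            s = fs.RankAbundance("flat", np.full(S, 3.0))
            fit = fs.estimate_p(s)
            assert fit.p == 0.0
            assert fit.r_squared == 1.0

    def test_exact_power_law_machine_precision(self):
        r = np.arange(1, 5, dtype=float)
        s = fs.RankAbundance("pl", r ** -2.5)
        fit = fs.estimate_p(s)
        assert fit.p == pytest.approx(2.5, abs=1e-14)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-14)

    def test_matches_numerical_minimizer_on_small_sample(self):
        s = fs.RankAbundance("tri", np.array([100.0, 40.0, 5.0]))
        fit = fs.estimate_p(s)
        assert fit.p == pytest.approx(sse_minimizer_oracle(s), abs=1e-10)

    def test_insufficient_ranks(self):
        with pytest.raises(InsufficientRanksError):
            fs.estimate_p(fs.RankAbundance("one", [5.0]))

    @pytest.mark.parametrize("q", [-1, 0, 0.235, 1, 1.034, 2, 5.825])
    @pytest.mark.parametrize("S", [2, 6, 50, 1000])
    def test_exact_recovery_round_trip(self, q, S):
        fit = fs.estimate_p(fs.predict_sad(q, S))
        assert fit.p == pytest.approx(q, abs=1e-12)

    @given(scale=st.floats(min_value=1e-6, max_value=1e6), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale, seed):
        """Multiplying all abundances by a constant changes neither p nor R^2."""
        s = make_random_sad(np.random.default_rng(seed), max_S=50)
        scaled = fs.RankAbundance(s.sample_id, s.abundances * scale)
        f1, f2 = fs.estimate_p(s), fs.estimate_p(scaled)
        assert f1.p == pytest.approx(f2.p, rel=1e-9, abs=1e-12)
        assert f1.r_squared == pytest.approx(f2.r_squared, rel=1e-9, abs=1e-12)


class TestRSquared:
    def test_exact_power_law_is_one(self):
        s = fs.predict_sad(1.7, 20)
        assert fs.r_squared_log(s, 1.7) == pytest.approx(1.0, abs=1e-14)

    def test_flat_sad_at_zero_exponent_is_one(self):
        s = fs.RankAbundance("flat", np.full(8, 2.0))
        assert fs.r_squared_log(s, 0.0) == 1.0

    def test_term_by_term_recomputation(self):
        s = fs.RankAbundance("tri", np.array([100.0, 40.0, 5.0]))
        p = fs.estimate_p(s).p
        F = [math.log(a / 100.0) for a in (100.0, 40.0, 5.0)]
        D = [math.log(r) for r in (1, 2, 3)]
        ss_res = sum((f + p * d) ** 2 for f, d in zip(F, D))
        fbar = sum(F) / 3
        ss_tot = sum((f - fbar) ** 2 for f in F)
        assert fs.r_squared_log(s, p) == pytest.approx(1 - ss_res / ss_tot, abs=1e-15)
        ss_tot_u = sum(f * f for f in F)
        assert fs.r_squared_log(s, p, centered=False) == pytest.approx(
            1 - ss_res / ss_tot_u, abs=1e-15
        )

    def test_can_be_negative_for_pathological_fit(self):
        s = fs.RankAbundance("tri", np.array([100.0, 40.0, 5.0]))
        assert fs.r_squared_log(s, -3.0) < 0

    def test_insufficient_ranks(self):
        with pytest.raises(InsufficientRanksError):
            fs.r_squared_log(fs.RankAbundance("one", [5.0]), 1.0)


class TestHarmonicSeries:
    def test_finite_sum_examples(self):
        assert fs.effective_species_finite(1, 6) == pytest.approx(49 / 20, abs=1e-15)
        assert fs.effective_species_finite(0, 7) == 7.0

    def test_finite_sum_matches_high_precision(self):
        import mpmath

        expected = float(mpmath.nsum(lambda r: r ** -2, [1, 1000]))
        assert fs.effective_species_finite(2, 1000) == pytest.approx(expected, abs=1e-12)

    def test_finite_sum_monotone_in_p_and_S(self):
        for S in (2, 10, 100):
            vals = [fs.effective_species_finite(p, S) for p in (0, 0.5, 1, 2, 4)]
            assert all(a > b for a, b in zip(vals, vals[1:]))
        for p in (0, 0.7, 1.5):
            vals = [fs.effective_species_finite(p, S) for S in (1, 2, 5, 50)]
            assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_infinite_sum_zeta_values(self):
        import mpmath

        assert fs.effective_species_infinite(2) == pytest.approx(math.pi ** 2 / 6, abs=1e-10)
        for p in (1.5, 3.0, 10.0):
            assert fs.effective_species_infinite(p, tol=1e-10) == pytest.approx(
                float(mpmath.zeta(p)), abs=1e-9
            )

    @pytest.mark.parametrize("p", [1.0, 0.5, 0.0, -2.0])
    def test_divergence_signal_at_and_below_one(self, p):
        with pytest.raises(DivergentSeriesError):
            fs.effective_species_infinite(p)

    def test_finite_sum_approaches_infinite_limit(self):
        z = fs.effective_species_infinite(2, tol=1e-12)
        partial = fs.effective_species_finite(2, 10_000)
        # tail of sum r^-2 beyond S is below the integral bound 1/S
        assert 0 < z - partial < 1e-4

    def test_zipf_partial_sums_grow_like_log(self):
        for S in (10, 100, 1000):
            gap = fs.effective_species_finite(1, S) - math.log(S)
            assert GAMMA < gap < 1.0

    def test_harmonic_gap_examples(self):
        assert fs.harmonic_gap(1) == 1.0
        assert fs.harmonic_gap(2) == pytest.approx(1.5 - math.log(2), abs=1e-15)

    def test_harmonic_gap_converges_to_gamma(self):
        S = 10 ** 6
        assert abs(fs.harmonic_gap(S) - GAMMA) < 1 / (2 * S) + 1e-9

    def test_harmonic_gap_non_increasing_and_bounded(self):
        gaps = [fs.harmonic_gap(S) for S in range(1, 200)]
        assert all(a >= b for a, b in zip(gaps, gaps[1:]))
        assert all(g > GAMMA for g in gaps)

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            fs.effective_species_finite(1, 0)
        with pytest.raises(InvalidArgumentError):
            fs.harmonic_gap(0)
        with pytest.raises(InvalidArgumentError):
            fs.effective_species_infinite(2, tol=0)
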