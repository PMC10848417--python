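import math

import pytest
from hypothesis import given, settings, strategies as st

from raresub.errors import ValidationError
from raresub.evolution_model import (
    DEFAULT_MU,
    EvolutionParams,
    combine_patient_probabilities,
    p_sequence,
    p_sequence_bounded,
    passenger_upper_bound,
    passenger_vs_driver_ratio,
)


class TestPSequence:
    def test_pure_passenger_series_is_independent_of_expansion(self):
        for c in (0.1, 0.5, 1.0):
            p = p_sequence(EvolutionParams(mu=0.01, T=1e4, c=c, k=5, d=0))
            expected = 0.01 ** 4 * (1 - 0.99 ** 1e4)
            assert p.value == pytest.approx(expected, rel=1e-9)

    def test_single_mutation_case(self):
        p = p_sequence(EvolutionParams(mu=0.01, T=100, k=1, d=0))
        assert p.value == pytest.approx(1 - 0.99 ** 100, rel=1e-12)

    def test_matches_monte_carlo_acquisition_oracle(self, rng):
        """Small instance vs direct simulation of the per-cell hit process:
        initial hit anywhere in T cells, driver hit in the expanded T*c pool,
        remaining passenger forced into the same cell (probability mu)."""
        mu, T, c, k, d = 0.01, 1000, 1.0, 3, 1
        n_rep = 200_000
        first = rng.random(n_rep) < 1 - (1 - mu) ** T
        driver = rng.random(n_rep) < 1 - (1 - mu) ** (T * c)
        passenger = rng.random(n_rep) < mu
        freq = (first & driver & passenger).mean()
        p = p_sequence(EvolutionParams(mu=mu, T=T, c=c, k=k, d=d)).value
        se = math.sqrt(p * (1 - p) / n_rep)
        assert abs(freq - p) < 3 * se

    @settings(derandomize=True, max_examples=50)
    @given(mu=st.floats(1e-6, 0.05), T=st.floats(1e3, 1e9),
           c=st.floats(0.01, 1.0), k=st.floats(2, 50), d=st.floats(0, 1))
    def test_decreasing_in_k_increasing_in_d(self, mu, T, c, k, d):
        d = min(d * (k - 1), k - 1.5) if k > 1.5 else 0
        base = p_sequence(EvolutionParams(mu=mu, T=T, c=c, k=k, d=d)).log10
        more_k = p_sequence(EvolutionParams(mu=mu, T=T, c=c, k=k + 1, d=d)).log10
        assert more_k < base
        hit = 1 - (1 - mu) ** (T * c)
        if hit > mu and d + 0.5 <= k - 1:
            more_d = p_sequence(EvolutionParams(mu=mu, T=T, c=c, k=k, d=d + 0.5)).log10
            assert more_d > base

    def test_log_space_agrees_with_direct_evaluation(self):
        for mu, T, c, k, d in [(0.01, 1e3, 1.0, 4, 2), (1e-4, 1e6, 0.5, 10, 3)]:
            p = p_sequence(EvolutionParams(mu=mu, T=T, c=c, k=k, d=d))
            direct = ((1 - (1 - mu) ** (T * c)) ** d * mu ** (k - d - 1)
                      * (1 - (1 - mu) ** T))
            assert p.value == pytest.approx(direct, rel=1e-10)

    def test_extreme_exponents_do_not_underflow_in_log_space(self):
        p = p_sequence(EvolutionParams(mu=DEFAULT_MU, T=1e9, k=60, d=0))
        assert math.isfinite(p.log10)
        assert p.log10 == pytest.approx(59 * math.log10(DEFAULT_MU), abs=1e-6)
        assert p.value == pytest.approx(3.2e-266, rel=0.02)
        deeper = p_sequence(EvolutionParams(mu=DEFAULT_MU, T=1e9, k=200, d=0))
        assert math.isfinite(deeper.log10)   # log-space survives true underflow
        assert deeper.value == 0.0

    def test_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            EvolutionParams(mu=0.01, T=100, k=0.5, d=0)


class TestPassengerBound:
    def test_value_never_exceeds_bound(self):
        for k in (2, 4, 5, 10):
            p = p_sequence(EvolutionParams(mu=0.1, T=1e9, k=k, d=0))
            assert p.value <= passenger_upper_bound(k, 0.1) + 1e-15

    def test_printed_bounds_at_high_exomic_rate(self):
        assert passenger_upper_bound(4, 0.1) == pytest.approx(1e-3)
        assert passenger_upper_bound(5, 0.1) == pytest.approx(1e-4)


class TestRatio:
    def test_no_drivers_means_no_penalty(self):
        assert passenger_vs_driver_ratio(8, 0, DEFAULT_MU, saturated=True).value == 1.0

    def test_saturated_ratio_is_mu_to_the_d(self):
        r = passenger_vs_driver_ratio(8, 7, DEFAULT_MU, saturated=True)
        assert r.value == pytest.approx(3.2e-32, rel=0.02)

    def test_unsaturated_ratio_approaches_saturated_limit(self):
        r_big_t = passenger_vs_driver_ratio(8, 7, DEFAULT_MU, T=1e12, c=1.0)
        r_sat = passenger_vs_driver_ratio(8, 7, DEFAULT_MU, saturated=True)
        assert r_big_t.log10 == pytest.approx(r_sat.log10, abs=1e-6)


class TestBoundedExpansion:
    def test_ceiling_of_one_equals_unbounded(self):
        a = p_sequence_bounded(6, 3, 0.001, 1e5, f=1.0)
        b = p_sequence(EvolutionParams(mu=0.001, T=1e5, c=1.0, k=6, d=3))
        assert a.log10 == pytest.approx(b.log10, abs=1e-12)

    def test_monotone_in_ceiling(self):
        vals = [p_sequence_bounded(8, 7, DEFAULT_MU, 1e6, f=f).log10
                for f in (0.01, 0.03, 0.5, 1.0)]
        assert vals == sorted(vals)

    def test_long_series_below_detection_floor_is_improbable(self):
        # a long undetected series confined below a 3% detection floor in a
        # ~1e6 cell pool is orders of magnitude less probable than a short one
        short = p_sequence_bounded(3, 2, DEFAULT_MU, 1e6, f=0.03)
        long = p_sequence_bounded(33, 32, DEFAULT_MU, 1e6, f=0.03)
        assert long.log10 < -5
        assert long.log10 < short.log10 - 5
        assert short.value < 0.5


class TestCombine:
    def test_single_value_passthrough(self):
        assert combine_patient_probabilities([-5.0]) == -5.0

    def test_exponents_add(self):
        assert combine_patient_probabilities([-5.0, -6.0]) == pytest.approx(-11.0)

    def test_matches_sequential_summation(self, rng):
        vals = list(rng.uniform(-30, 0, 50))
        total = 0.0
        for v in vals:
            total += v
        assert combine_patient_probabilities(vals) == pytest.approx(total, abs=1e-9)
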