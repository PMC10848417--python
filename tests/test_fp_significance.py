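import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from raresub.errors import ValidationError
from raresub.fp_significance import (
    ArtifactModel,
    build_artifact_model,
    combined_significance,
    poisson_binomial_tail,
    prob_false_detections,
    sample_permutation_test,
)


def _model(q_panel, q_context=None):
    return ArtifactModel(q_panel=q_panel, q_context=q_context or {})


class TestArtifactModel:
    def test_zero_burden_gives_zero_q(self, tiny_panel):
        from raresub.ffpe_udg import rare_subclonal_burden

        prof = rare_subclonal_burden(
            pd.DataFrame(columns=["patient_id", "sample_id", "chrom", "pos", "ref",
                                  "alt", "mt_alt", "mt_total", "called", "vaf",
                                  "context"]),
            tiny_panel, sample_id="S")
        model = build_artifact_model(prof)
        assert model.q_panel == 0.0
        assert all(q == 0 for q in model.q_context.values())

    def test_direct_panel_rate(self):
        # 5 background variants over 2395 covered bases
        assert 5 / 2395 == pytest.approx(0.00209, abs=2e-5)

    def test_uncovered_context_falls_back_to_panel_rate(self):
        model = _model(0.01, {"A[C>T]G": 0.05})
        qs = model.q_for_contexts(["A[C>T]G", "T[C>T]T", None])
        assert list(qs) == [0.05, 0.01, 0.01]
        assert "T[C>T]T" in model.fallback_contexts


class TestTailProbability:
    def test_zero_rate_cannot_produce_detections(self):
        assert prob_false_detections(10, _model(0.0), 1) == 0.0

    def test_zero_detections_certain(self):
        assert prob_false_detections(10, _model(0.3), 0) == 1.0

    def test_exact_binomial_value(self):
        p = prob_false_detections(10, _model(0.01), 2)
        assert p == pytest.approx(1 - 0.99 ** 10 - 10 * 0.01 * 0.99 ** 9, abs=1e-10)
        assert p == pytest.approx(0.00427, abs=2e-5)

    def test_monotone_in_detections_and_rate(self):
        m = _model(0.02)
        assert (prob_false_detections(20, m, 1)
                >= prob_false_detections(20, m, 2)
                >= prob_false_detections(20, m, 3))
        assert (prob_false_detections(20, _model(0.05), 2)
                >= prob_false_detections(20, _model(0.01), 2))

    @pytest.mark.parametrize("q,n,k", [(0.01, 12, 2), (0.1, 8, 3), (0.5, 6, 6)])
    def test_poisson_binomial_reduces_to_binomial(self, q, n, k):
        dp = poisson_binomial_tail(np.full(n, q), k)
        assert dp == pytest.approx(float(binom.sf(k - 1, n, q)), abs=1e-12)

    def test_heterogeneous_rates_via_contexts(self):
        model = _model(0.01, {"A[C>T]G": 0.2})
        contexts = ["A[C>T]G"] * 2 + [None] * 3
        p = prob_false_detections(5, model, 1, contexts)
        manual = 1 - (0.8 ** 2) * (0.99 ** 3)
        assert p == pytest.approx(manual, abs=1e-12)


class TestCombined:
    def test_single_patient_passthrough(self):
        assert combined_significance([0.03]).p_fisher == pytest.approx(0.03, abs=1e-9)

    def test_all_ones_combine_to_one(self):
        assert combined_significance([1.0, 1.0]).p_fisher == pytest.approx(1.0)

    def test_zero_tail_flagged(self):
        res = combined_significance([0.5, 0.0])
        assert res.p_fisher == 0.0 and res.zero_flag

    def test_null_combined_p_is_calibrated(self, rng):
        """Under the null (detections drawn from the artifact model itself)
        the combined P rejects at most at the nominal rate; the discrete
        binomial tails make it conservative, never anti-conservative."""
        n_sim = 500
        q, n_assayed, n_patients = 0.02, 30, 8
        rejections_05 = rejections_10 = 0
        for _ in range(n_sim):
            tails = []
            for _ in range(n_patients):
                detected = rng.binomial(n_assayed, q)
                tails.append(prob_false_detections(n_assayed, _model(q), detected))
            combined = combined_significance(tails).p_fisher
            rejections_05 += combined <= 0.05
            rejections_10 += combined <= 0.10
        se = math.sqrt(0.05 * 0.95 / n_sim)
        assert rejections_05 / n_sim <= 0.05 + 3 * se
        assert rejections_10 / n_sim <= 0.10 + 3 * math.sqrt(0.1 * 0.9 / n_sim)


def _toy_cohort(detections):
    """Build site lists/call sets where patient i has detections[i] of its
    own 3 sites called in its own primary, and no cross-patient calls."""
    site_lists, calls = {}, {}
    for i, det in enumerate(detections):
        pid = f"P{i}"
        sites = pd.DataFrame({
            "chrom": [f"chr{i}"] * 3,
            "pos": [100, 200, 300],
            "ref": ["C"] * 3,
            "alt": ["T"] * 3,
        })
        site_lists[pid] = sites
        calls[pid] = {(f"chr{i}", p, "C", "T") for p in (100, 200, 300)[:det]}
    return site_lists, calls


class TestPermutation:
    def test_zero_observed_gives_p_one(self):
        site_lists, calls = _toy_cohort([0, 0, 0])
        res = sample_permutation_test(site_lists, calls, n_perm=100, seed=0)
        assert res.p_value == 1.0

    def test_exact_enumeration_matches_brute_force(self):
        site_lists, calls = _toy_cohort([3, 1, 0])
        res = sample_permutation_test(site_lists, calls, seed=0)
        assert res.method == "exact"
        # brute force: patient i's list assigned to primary perm(i); a list
        # only scores in its own primary here, so the statistic is the sum of
        # detections over fixed points of the permutation
        det = [3, 1, 0]
        stats = []
        for perm in itertools.permutations(range(3)):
            stats.append(sum(det[i] for i in range(3) if perm[i] == i))
        expected = np.mean([s >= res.observed for s in stats])
        assert res.p_value == pytest.approx(expected)

    def test_monte_carlo_approaches_exact(self):
        site_lists, calls = _toy_cohort([2, 1, 0, 1, 0, 0, 0, 0, 1])
        exact = sample_permutation_test(site_lists, calls, seed=0, exact_limit=10**6)
        mc = sample_permutation_test(site_lists, calls, seed=1, n_perm=20_000,
                                     exact_limit=1)
        assert mc.method == "monte_carlo"
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)
        assert mc.p_value >= 1 / (20_000 + 1)

    def test_needs_three_patients(self):
        site_lists, calls = _toy_cohort([1, 0])
        with pytest.raises(ValidationError):
            sample_permutation_test(site_lists, calls)

    def test_type_one_error_on_null_cohorts(self, rng):
        """With detections spread independently of patient identity, the
        permutation test rejects at most at the nominal rate."""
        n_sim = 300
        rejections = 0
        for _ in range(n_sim):
            # null: every primary calls each assayed site with the same prob
            n_pat = 6
            site_lists, calls = {}, {}
            for i in range(n_pat):
                pid = f"P{i}"
                site_lists[pid] = pd.DataFrame({
                    "chrom": [f"chr{i}"] * 4, "pos": [100, 200, 300, 400],
                    "ref": ["C"] * 4, "alt": ["T"] * 4})
            for j in range(n_pat):
                pid = f"P{j}"
                called = set()
                for i in range(n_pat):
                    for p in (100, 200, 300, 400):
                        if rng.random() < 0.05:
                            called.add((f"chr{i}", p, "C", "T"))
                calls[pid] = called
            res = sample_permutation_test(site_lists, calls, n_perm=200, seed=rng)
            rejections += res.p_value <= 0.05
        rate = rejections / n_sim
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_sim)
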