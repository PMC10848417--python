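import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from raresub.ccf_engine import CCFEstimate
from raresub.clonal_inference import (
    classify_subclone,
    clustered_mutation_fraction,
    detect_metspec_in_primary,
    metspec_truncal_ratio,
    nested_subclone_upper_bound,
    pigeonhole_from_estimates,
    pigeonhole_sum_test,
    sequential_lineage_set,
)
from raresub.errors import AmbiguousMultiplicityError
from raresub.io_model import CNProfile, CNSegment, TumorSample


class TestClassify:
    def test_high_vaf_high_ccf_is_major(self):
        assert classify_subclone(0.4, 0.96, True).stratum == "major"

    def test_low_vaf_is_rare(self):
        assert classify_subclone(0.05, 0.15, True).stratum == "rare"

    def test_uncalled_is_undetected_with_limit(self):
        call = classify_subclone(None, None, False, min_ccf=0.02)
        assert call.stratum == "undetected"
        assert call.min_ccf == 0.02

    def test_intermediate_is_minor(self):
        assert classify_subclone(0.15, 0.35, True).stratum == "minor"

    def test_rare_takes_precedence_with_flag(self):
        # low purity can push CCF above 0.5 while VAF stays below 0.10
        call = classify_subclone(0.08, 0.6, True)
        assert call.stratum == "rare"
        assert call.conflict_flag


class TestDetectMetspec:
    def _inputs(self):
        muts = pd.DataFrame({
            "patient_id": ["P1"] * 4,
            "chrom": ["chr1", "chr1", "chr2", "chr3"],
            "pos": [100, 200, 300, 400],
            "ref": ["C", "A", "G", "C"],
            "alt": ["T", "G", "A", "A"],
        })
        prim = pd.DataFrame({
            "patient_id": ["P1"] * 3,
            "sample_id": ["P1_P"] * 3,
            "chrom": ["chr1", "chr1", "chr2"],
            "pos": [100, 200, 300],
            "ref": ["C", "A", "G"],
            "alt": ["T", "G", "A"],
            "mt_alt": [24, 0, 2],
            "mt_total": [1160, 2000, 80],
            "called": [True, False, False],
        })
        prim["vaf"] = prim["mt_alt"] / prim["mt_total"]
        sample = TumorSample("P1", "P1_P", "B", "primary", 0.7, 2.0, "FFPE", True)
        cn = CNProfile([CNSegment(c, 1, 10_000, 1, 1) for c in ("chr1", "chr2", "chr3")])
        return muts, prim, sample, cn

    def test_strata_and_exclusions(self):
        muts, prim, sample, cn = self._inputs()
        detail, summary = detect_metspec_in_primary(muts, prim, sample, cn)
        by_id = detail.set_index("mutation_id")
        assert by_id.loc["chr1:100:C>T", "stratum"] == "rare"  # vaf ~0.021
        assert by_id.loc["chr1:200:A>G", "stratum"] == "undetected"
        assert by_id.loc["chr1:200:A>G", "min_ccf"] > 0
        assert by_id.loc["chr2:300:G>A", "excluded_reason"] == "low_coverage"
        assert by_id.loc["chr3:400:C>A", "excluded_reason"] == "absent_from_primary_table"
        assert summary.n_assayed == 2
        assert summary.n_detected_rare == 1
        assert summary.n_undetected == 1
        assert summary.n_excluded == 2


class TestPigeonhole:
    def test_point_masses_summing_past_one(self):
        res = pigeonhole_sum_test(np.array([0.65]), np.array([0.81]), n_draws=1000, seed=0)
        assert res.p_value == 0.0
        assert res.co_lineage

    def test_point_masses_summing_below_one(self):
        res = pigeonhole_sum_test(np.array([0.3]), np.array([0.3]), n_draws=1000, seed=0)
        assert res.p_value == 1.0
        assert not res.co_lineage

    def test_monte_carlo_matches_gaussian_tail(self, rng):
        a = rng.normal(0.65, 0.05, 200_000)
        b = rng.normal(0.43, 0.05, 200_000)
        res = pigeonhole_sum_test(a, b, n_draws=400_000, seed=1)
        analytic = norm.cdf((1 - 0.65 - 0.43) / np.sqrt(2 * 0.05 ** 2))
        se = np.sqrt(analytic * (1 - analytic) / 400_000)
        assert abs(res.p_value - analytic) < 3 * se + 1e-3

    def test_monotone_in_posterior_means(self, rng):
        base = rng.normal(0.0, 0.03, 50_000)
        p = [pigeonhole_sum_test(base + m, base + 0.5, n_draws=100_000, seed=2).p_value
             for m in (0.3, 0.45, 0.6)]
        assert p[0] >= p[1] >= p[2]

    def test_ambiguous_multiplicity_refused(self):
        amb = CCFEstimate("a", per_s={1: 0.8, 2: 0.4}, s_candidates=[1, 2])
        ok = CCFEstimate("b", per_s={1: 0.7}, s_candidates=[1],
                         posterior_draws={1: np.array([0.7])})
        with pytest.raises(AmbiguousMultiplicityError):
            pigeonhole_from_estimates(amb, ok)


class TestSequentialSet:
    def test_selects_ccf_above_half(self):
        chosen, k = sequential_lineage_set({"a": 0.9, "b": 0.6, "c": 0.3})
        assert chosen == {"a", "b"} and k == 2

    def test_empty_when_all_subclonal(self):
        chosen, k = sequential_lineage_set({"a": 0.2, "b": 0.45})
        assert chosen == set() and k == 0


class TestNestedBound:
    def test_detection_limit_tightens_the_bound(self):
        bound, empty = nested_subclone_upper_bound(0.19, [0.01, 0.02, 0.05])
        assert bound == pytest.approx(0.01)
        assert not empty

    def test_ancestral_ccf_can_be_the_binding_constraint(self):
        bound, _ = nested_subclone_upper_bound(0.005, [0.01, 0.01])
        assert bound == pytest.approx(0.005)

    def test_idempotent_and_never_exceeds_inputs(self):
        bound, _ = nested_subclone_upper_bound(0.19, [0.013])
        again, _ = nested_subclone_upper_bound(bound, [0.013])
        assert again == bound <= 0.013

    def test_empty_undetected_set_flagged(self):
        bound, empty = nested_subclone_upper_bound(0.19, [])
        assert bound == 0.19 and empty


class TestRatioAndClustering:
    def test_metspec_truncal_ratio(self):
        df = pd.DataFrame({
            "mutation_class": ["metspec_driver"] * 6 + ["truncal"] * 2 + ["truncal"],
            "ccf": [0.9] * 6 + [0.8, 0.7] + [0.2],
        })
        assert metspec_truncal_ratio(df) == pytest.approx(3.0)

    def test_ratio_undefined_without_truncal(self):
        df = pd.DataFrame({"mutation_class": ["metspec_driver"], "ccf": [0.9]})
        assert np.isnan(metspec_truncal_ratio(df))

    def test_neighbors_within_window(self):
        df = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [1000, 1500]})
        assert clustered_mutation_fraction(df) == 1.0

    def test_different_chromosomes_never_cluster(self):
        df = pd.DataFrame({"chrom": ["chr1", "chr2", "chr3"], "pos": [1000, 1000, 1200]})
        assert clustered_mutation_fraction(df) == 0.0

    def test_uniform_positions_match_poisson_expectation(self, rng):
        genome = 50_000_000
        n = 600
        window = 1000
        fracs = []
        for _ in range(30):
            pos = rng.integers(1, genome, n)
            df = pd.DataFrame({"chrom": ["chr1"] * n, "pos": pos})
            fracs.append(clustered_mutation_fraction(df, window))
        density = n / genome
        expected = 1 - np.exp(-2 * density * window)
        assert np.mean(fracs) == pytest.approx(expected, abs=0.01)
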