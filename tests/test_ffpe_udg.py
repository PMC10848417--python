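import numpy as np
import pandas as pd
import pytest

from raresub.errors import UndefinedEstimateError
from raresub.ffpe_udg import (
    context_spectrum,
    rare_subclonal_burden,
    udg_depletion,
)
from raresub.synthetic_data import SimConfig, simulate_cohort


def _variants(rows):
    df = pd.DataFrame(rows, columns=[
        "patient_id", "sample_id", "chrom", "pos", "ref", "alt",
        "mt_alt", "mt_total", "called", "context"])
    df["vaf"] = df["mt_alt"] / df["mt_total"]
    return df


def burden_profiles(cohort):
    treated, untreated = [], []
    for sid, sample in cohort.samples.items():
        if sample.role != "primary":
            continue
        v = cohort.variants[cohort.variants["sample_id"] == sid]
        prof = rare_subclonal_burden(v, cohort.panel, sample_id=sid)
        (treated if sample.udg_treated else untreated).append(prof)
    return treated, untreated


class TestBurden:
    def test_no_rare_variants_gives_zero_rates(self, tiny_panel):
        v = _variants([("P", "S", "chr1", 101, "C", "T", 200, 1000, True, "A[C>T]G")])
        prof = rare_subclonal_burden(v, tiny_panel, sample_id="S")  # vaf 0.2 not rare
        assert prof.panel_wide_rate == 0
        assert prof.n_rare_variants == 0

    def test_counts_over_covered_context_sites(self, tiny_panel):
        rows = [("P", "S", "chr1", pos, "C", "T", 10, 1000, True, "A[C>T]G")
                for pos in (101, 105, 109)]
        prof = rare_subclonal_burden(_variants(rows), tiny_panel, sample_id="S")
        # 6 covered sites canonicalise to ACG (3 C-strand + 3 G-strand)
        assert prof.n_covered_sites["A[C>T]G"] == 6
        assert prof.per_context_rate["A[C>T]G"] == pytest.approx(3 / 6)
        assert prof.panel_wide_rate == pytest.approx(3 / 12)
        # rate x covered sites recovers the integer count
        assert prof.per_context_rate["A[C>T]G"] * prof.n_covered_sites["A[C>T]G"] == 3

    def test_vaf_ceiling_is_strict(self, tiny_panel):
        rows = [("P", "S", "chr1", 101, "C", "T", 100, 1000, True, "A[C>T]G")]
        prof = rare_subclonal_burden(_variants(rows), tiny_panel, sample_id="S")
        assert prof.n_rare_variants == 0  # vaf exactly 0.10 excluded

    def test_uncovered_context_rate_is_undefined_not_zero(self, tiny_panel):
        prof = rare_subclonal_burden(_variants([]), tiny_panel, sample_id="S")
        assert np.isnan(prof.per_context_rate["T[C>T]T"])
        assert prof.per_context_rate["A[C>T]G"] == 0.0


class TestUdgDepletion:
    def test_equal_excess_gives_zero_depletion(self, small_cohort):
        treated, _ = burden_profiles(small_cohort)
        est = udg_depletion(treated, treated, n_boot=50, seed=0)
        assert est.depletion == pytest.approx(0.0, abs=1e-12)

    def test_recovers_injected_efficiency(self):
        cohort = simulate_cohort(SimConfig(
            n_patients=5, n_untreated_replicates=5, udg_efficiency=0.9, seed=11))
        treated, untreated = burden_profiles(cohort)
        est = udg_depletion(treated, untreated, n_boot=300, seed=1)
        assert est.ci_low <= 0.9 <= est.ci_high
        assert est.depletion == pytest.approx(0.9, abs=0.08)

    def test_invariant_to_uniform_site_rescaling(self, small_cohort):
        treated, untreated = burden_profiles(small_cohort)
        est1 = udg_depletion(treated, untreated, n_boot=10, seed=0)
        import copy

        scaled_t = [copy.copy(p) for p in treated]
        scaled_u = [copy.copy(p) for p in untreated]
        for p in scaled_t + scaled_u:
            p.site_counts = pd.concat([p.site_counts, p.site_counts], ignore_index=True)
        est2 = udg_depletion(scaled_t, scaled_u, n_boot=10, seed=0)
        assert est2.raw == pytest.approx(est1.raw, rel=1e-12)

    def test_undemonstrable_burden_is_explicit(self, tiny_panel):
        clean = rare_subclonal_burden(_variants([]), tiny_panel, sample_id="S")
        with pytest.raises(UndefinedEstimateError):
            udg_depletion([clean], [clean], n_boot=10)


class TestContextSpectrum:
    def test_point_mass_spectrum(self, tiny_panel):
        rows = [("P", "S", "chr1", pos, "C", "T", 10, 1000, True, "A[C>T]G")
                for pos in (101, 105)]
        site_frac, call_frac = context_spectrum(_variants(rows), tiny_panel)
        assert call_frac["A[C>T]G"] == 1.0
        assert call_frac.sum() == pytest.approx(1.0)
        assert site_frac.sum() == pytest.approx(1.0)

    def test_untreated_ffpe_dominated_by_ct(self):
        cohort = simulate_cohort(SimConfig(
            n_patients=3, n_untreated_replicates=3, seed=5))
        untreated_ids = [sid for sid, s in cohort.samples.items() if not s.udg_treated]
        v = cohort.variants[cohort.variants["sample_id"].isin(untreated_ids)]
        _, call_frac = context_spectrum(v, cohort.panel)
        ct_mass = call_frac[[c for c in call_frac.index if "[C>T]" in c]].sum()
        assert ct_mass > 0.5

    def test_empty_spectrum_signalled(self, tiny_panel):
        with pytest.raises(UndefinedEstimateError):
            context_spectrum(_variants([]), tiny_panel)
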