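"""Subclone classification, pigeonhole co-clonality, and sampling bounds.

Stratum definitions follow the clonal-composition conventions for
ultra-deep UMI sequencing of tumors: mutations with CCF >= 0.50 sit in the
major subclone, CCF < 0.50 in a minor subclone, and VAF < 0.10 in a *rare*
subclone (the VAF-based definition corresponds to CCF of roughly <= 0.2 at
full cellularity). A mutation whose site passed coverage requirements but
was not called is *undetected*, and carries the site's detection limit
(minCCF95) as the strongest statement available about its abundance.

The pigeonhole test: two mutations whose CCFs sum to more than 1 must
co-occur in some cells, hence lie on one clonal lineage. Given posterior
CCF distributions for both (with unambiguous multiplicity), the test
reports P(CCF_a + CCF_b <= 1) by Monte-Carlo, with an analytic Gaussian
tail available below Monte-Carlo resolution.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ccf_engine import CCFEstimate, estimate_ccf
from .detection_power import TechModel, UDS_UMI_MODEL, min_detectable_vaf
from .ccf_engine import vaf_to_ccf
from .errors import AmbiguousMultiplicityError, ValidationError
from .io_model import CNSegment, TumorSample

STRATA = ("major", "minor", "rare", "undetected")


@dataclass(frozen=True)
class SubcloneCall:
    mutation_id: str
    stratum: str
    vaf: float | None = None
    ccf: float | None = None
    min_ccf: float | None = None      # attached when undetected
    conflict_flag: bool = False       # rare by VAF but major-range CCF


def classify_subclone(
    vaf: float | None,
    ccf_median: float | None,
    called: bool,
    mutation_id: str = "",
    min_ccf: float | None = None,
    vaf_ceiling: float = 0.10,
    major_ccf: float = 0.50,
) -> SubcloneCall:
    """Assign a mutation to major / minor / rare / undetected.

    Rare (VAF-based) takes precedence over major (CCF-based) when low purity
    makes both rules fire; the conflict is flagged rather than hidden.
    """
    if not called:
        return SubcloneCall(mutation_id, "undetected", min_ccf=min_ccf)
    if vaf is None or ccf_median is None:
        raise ValidationError("called mutations need both vaf and ccf_median")
    if vaf < vaf_ceiling:
        return SubcloneCall(mutation_id, "rare", vaf=vaf, ccf=ccf_median,
                            conflict_flag=ccf_median >= major_ccf)
    if ccf_median >= major_ccf:
        return SubcloneCall(mutation_id, "major", vaf=vaf, ccf=ccf_median)
    return SubcloneCall(mutation_id, "minor", vaf=vaf, ccf=ccf_median)


@dataclass
class PatientSummary:
    """Detection tally of metastasis-specific mutations in one primary."""

    patient_id: str
    n_assayed: int
    n_detected_high_vaf: int     # detected at VAF >= 0.10 (major/minor strata)
    n_detected_rare: int
    n_undetected: int
    n_excluded: int
    excluded_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def undetected_fraction(self) -> float:
        return self.n_undetected / self.n_assayed if self.n_assayed else np.nan


def detect_metspec_in_primary(
    met_mutations: pd.DataFrame,
    primary_variants: pd.DataFrame,
    sample: TumorSample,
    cn_lookup,
    model: TechModel = UDS_UMI_MODEL,
    coverage_floor: int = 100,
    vaf_ceiling: float = 0.10,
    major_ccf: float = 0.50,
) -> tuple[pd.DataFrame, PatientSummary]:
    """Decide the primary-tumor detection status of each metastasis-specific
    mutation.

    ``met_mutations`` needs (chrom, pos, ref, alt); sites absent from the
    primary table or covered by fewer than ``coverage_floor`` molecular tags
    are excluded with a reason. Undetected mutations carry the site's
    minCCF95.
    """
    key_cols = ["chrom", "pos", "ref", "alt"]
    prim = primary_variants.set_index(
        pd.MultiIndex.from_frame(primary_variants[key_cols].astype({"pos": int}))
    )
    rows = []
    counts = {"major": 0, "minor": 0, "rare": 0, "undetected": 0}
    excluded: dict[str, int] = {}
    for r in met_mutations.itertuples(index=False):
        mut_id = f"{r.chrom}:{int(r.pos)}:{r.ref}>{r.alt}"
        key = (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        if key not in prim.index:
            excluded["absent_from_primary_table"] = excluded.get("absent_from_primary_table", 0) + 1
            rows.append((mut_id, "excluded", np.nan, np.nan, np.nan, "absent_from_primary_table"))
            continue
        hit = prim.loc[[key]].iloc[0]
        depth = int(hit["mt_total"])
        if depth < coverage_floor:
            excluded["low_coverage"] = excluded.get("low_coverage", 0) + 1
            rows.append((mut_id, "excluded", np.nan, np.nan, np.nan, "low_coverage"))
            continue
        seg = cn_lookup.lookup(str(r.chrom), int(r.pos)) or CNSegment(
            str(r.chrom), int(r.pos), int(r.pos), 1, 1)
        vaf = float(hit["vaf"])
        called = bool(hit["called"])
        if called:
            est = estimate_ccf(mut_id, vaf, sample.purity, seg)
            call = classify_subclone(vaf, est.median_across_s, True, mut_id,
                                     vaf_ceiling=vaf_ceiling, major_ccf=major_ccf)
        else:
            use_depth = model.depth if model.depth is not None else depth
            min_ccf = vaf_to_ccf(min_detectable_vaf(use_depth, model),
                                 sample.purity, seg.total_cn, s=1)
            call = classify_subclone(None, None, False, mut_id, min_ccf=min_ccf)
        counts[call.stratum] += 1
        rows.append((mut_id, call.stratum, call.vaf, call.ccf, call.min_ccf, ""))
    detail = pd.DataFrame(
        rows, columns=["mutation_id", "stratum", "vaf", "ccf", "min_ccf", "excluded_reason"])
    detail = detail.astype({"vaf": float, "ccf": float, "min_ccf": float})
    n_assayed = sum(counts.values())
    summary = PatientSummary(
        patient_id=str(met_mutations["patient_id"].iloc[0]) if len(met_mutations) else "",
        n_assayed=n_assayed,
        n_detected_high_vaf=counts["major"] + counts["minor"],
        n_detected_rare=counts["rare"],
        n_undetected=counts["undetected"],
        n_excluded=sum(excluded.values()),
        excluded_reasons=excluded,
    )
    return detail, summary


# ---------------------------------------------------------------------------
# pigeonhole co-clonality

@dataclass(frozen=True)
class PigeonholeResult:
    p_value: float
    ci_low: float
    ci_high: float
    method: str                  # "monte_carlo" | "gaussian"
    n_draws: int
    co_lineage: bool
    p_gaussian: float | None = None


def _wilson(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    phat = k / n
    denom = 1 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def pigeonhole_sum_test(
    posterior_a: np.ndarray,
    posterior_b: np.ndarray,
    n_draws: int = 10_000_000,
    seed: int | np.random.Generator | None = 0,
    alpha: float = 0.05,
    threshold: float = 1.0,
) -> PigeonholeResult:
    """P(CCF_a + CCF_b <= threshold) for two independent CCF posteriors.

    Monte-Carlo over independently resampled posterior draws, with a Wilson
    interval on the tail; when the Monte-Carlo estimate is 0 the analytic
    Gaussian tail (matched to the posterior moments) is reported instead,
    since printed co-clonality tails can lie below Monte-Carlo resolution.
    Co-lineage is declared when p < ``alpha``.
    """
    a = np.asarray(posterior_a, dtype=float)
    b = np.asarray(posterior_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("posterior draws must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    remaining = int(n_draws)
    chunk = 2_000_000
    while remaining > 0:
        m = min(chunk, remaining)
        sums = a[rng.integers(0, a.size, m)] + b[rng.integers(0, b.size, m)]
        hits += int((sums <= threshold).sum())
        remaining -= m
    p_mc = hits / n_draws
    lo, hi = _wilson(hits, n_draws)
    mu = a.mean() + b.mean()
    sd = float(np.sqrt(a.var() + b.var()))
    p_gauss = float(norm.cdf((threshold - mu) / sd)) if sd > 0 else float(mu <= threshold)
    if hits == 0:
        return PigeonholeResult(p_gauss, lo, hi, "gaussian", n_draws,
                                p_gauss < alpha, p_gaussian=p_gauss)
    return PigeonholeResult(p_mc, lo, hi, "monte_carlo", n_draws,
                            p_mc < alpha, p_gaussian=p_gauss)


def pigeonhole_from_estimates(
    est_a: CCFEstimate,
    est_b: CCFEstimate,
    **kwargs,
) -> PigeonholeResult:
    """Pigeonhole test gated on unambiguous multiplicity for both mutations."""
    for est in (est_a, est_b):
        if not est.unambiguous:
            raise AmbiguousMultiplicityError(
                f"{est.mutation_id}: multiplicity ambiguous (candidates {est.s_candidates})"
            )
    s_a, = est_a.s_candidates
    s_b, = est_b.s_candidates
    return pigeonhole_sum_test(est_a.posterior_draws[s_a], est_b.posterior_draws[s_b], **kwargs)


def sequential_lineage_set(ccfs: dict[str, float], ccf_floor: float = 0.50) -> tuple[set[str], int]:
    """Mutations at CCF > 0.50 in one sample: by the pigeonhole principle any
    two of them share cells, so the whole set was sequentially acquired
    within one clonal lineage. Returns (set, k)."""
    chosen = {m for m, c in ccfs.items() if c > ccf_floor}
    return chosen, len(chosen)


def nested_subclone_upper_bound(
    ancestral_ccf: float,
    min_ccfs: list[float] | np.ndarray,
) -> tuple[float, bool]:
    """Upper bound on the CCF of a hypothetical nested subclone carrying every
    undetected mutation: the detected ancestral subclone's CCF, tightened by
    the best detection limit among the undetected mutations. The second
    element flags an empty undetected set (bound = ancestral CCF alone)."""
    min_ccfs = np.asarray(min_ccfs, dtype=float)
    if min_ccfs.size == 0:
        return float(ancestral_ccf), True
    return float(min(ancestral_ccf, min_ccfs.min())), False


def metspec_truncal_ratio(
    mutations: pd.DataFrame,
    ccf_floor: float = 0.50,
    label_col: str = "mutation_class",
    ccf_col: str = "ccf",
) -> float:
    """Ratio of sequentially arising (CCF > floor) metastasis-specific to
    truncal mutations; NaN (flagged undefined) when no truncal mutation
    passes the floor."""
    seq = mutations[mutations[ccf_col] > ccf_floor]
    n_met = int(seq[label_col].astype(str).str.startswith("metspec").sum())
    n_truncal = int((seq[label_col] == "truncal").sum())
    if n_truncal == 0:
        return float("nan")
    return n_met / n_truncal


def clustered_mutation_fraction(mutations: pd.DataFrame, window: int = 1000) -> float:
    """Fraction of mutations with >= 1 neighbour within ``window`` bp on the
    same chromosome (a proxy for simultaneous, kataegis-like events)."""
    if len(mutations) == 0:
        return 0.0
    clustered = 0
    for _, grp in mutations.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy(dtype=np.int64))
        if len(pos) == 1:
            continue
        gaps_left = np.diff(pos, prepend=pos[0] - window - 1)
        gaps_right = np.diff(pos, append=pos[-1] + window + 1)
        clustered += int(((gaps_left <= window) | (gaps_right <= window)).sum())
    return clustered / len(mutations)
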