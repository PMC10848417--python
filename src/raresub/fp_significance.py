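"""False-positive significance: could the rare-subclone detections be artifacts?

Two complementary nulls are tested. The *artifact model* asks: given the
background rare-subclonal mutation rate of the same sample (panel-wide, or
per trinucleotide context), how probable is it that at least the observed
number of assayed metastasis-specific sites would carry an artifactual call?
Panel-wide the count is Binomial; with per-site context rates it is
Poisson-binomial, whose exact tail is computed by dynamic programming.

The *sample permutation* null reassigns each patient's assayed site list to
unrelated primary tumors and asks how often at least the observed total
number of detections occurs.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, combine_pvalues

from .errors import ValidationError
from .ffpe_udg import BurdenProfile


@dataclass
class ArtifactModel:
    """Per-assayed-site artifact probabilities from a background burden."""

    q_panel: float
    q_context: dict[str, float]
    fallback_contexts: list[str] = field(default_factory=list)
    source_sample: str = ""

    def q_for_contexts(self, contexts: list[str | None]) -> np.ndarray:
        """Per-site q, falling back to the panel-wide rate for missing or
        uncovered contexts (recorded in ``fallback_contexts``)."""
        qs = np.empty(len(contexts))
        for i, ctx in enumerate(contexts):
            q = self.q_context.get(ctx) if ctx else None
            if q is None or not np.isfinite(q):
                if ctx and ctx not in self.fallback_contexts:
                    self.fallback_contexts.append(ctx)
                q = self.q_panel
            qs[i] = q
        return qs


def build_artifact_model(burden: BurdenProfile) -> ArtifactModel:
    """Artifact probabilities from the background (non-target) burden of the
    same sample; undefined context rates propagate as missing and fall back
    to the panel-wide rate at query time."""
    q_context = {
        cls: float(rate)
        for cls, rate in burden.per_context_rate.items()
        if np.isfinite(rate)
    }
    return ArtifactModel(
        q_panel=float(burden.panel_wide_rate),
        q_context=q_context,
        source_sample=burden.sample_id,
    )


def poisson_binomial_tail(qs: np.ndarray, k: int) -> float:
    """Exact P(X >= k) for X a sum of independent Bernoulli(q_i), by the
    standard dynamic-programming convolution (O(n^2), n is small here)."""
    qs = np.asarray(qs, dtype=float)
    n = qs.size
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for q in qs:
        pmf[1:] = pmf[1:] * (1 - q) + pmf[:-1] * q
        pmf[0] *= 1 - q
    return float(pmf[k:].sum())


def prob_false_detections(
    n_assayed: int,
    model: ArtifactModel,
    n_detected: int,
    contexts: list[str | None] | None = None,
) -> float:
    """Tail probability that >= ``n_detected`` of ``n_assayed`` sites carry
    artifactual calls. Panel-wide mode uses a Binomial tail; passing the
    assayed sites' contexts switches to the exact Poisson-binomial tail over
    context-specific rates."""
    if n_detected > n_assayed:
        raise ValidationError("n_detected cannot exceed n_assayed")
    if n_detected == 0:
        return 1.0
    if contexts is None:
        return float(binom.sf(n_detected - 1, n_assayed, model.q_panel))
    if len(contexts) != n_assayed:
        raise ValidationError("contexts must have one entry per assayed site")
    return poisson_binomial_tail(model.q_for_contexts(contexts), n_detected)


@dataclass(frozen=True)
class CombinedSignificance:
    p_fisher: float
    log10_product: float        # raw likelihood product, for comparison
    n_patients: int
    zero_flag: bool             # some per-patient tail was exactly 0


def combined_significance(p_values: list[float]) -> CombinedSignificance:
    """Combine per-patient tail probabilities.

    Fisher's method is the default (it yields a calibrated combined P); the
    raw product is emitted alongside, in log10. A tail of exactly 0 forces
    the combination to 0 and is flagged.
    """
    if not p_values:
        raise ValidationError("need at least one per-patient tail probability")
    ps = np.asarray(p_values, dtype=float)
    if (ps == 0).any():
        return CombinedSignificance(0.0, -math.inf, len(ps), True)
    _, p_fisher = combine_pvalues(ps, method="fisher")
    return CombinedSignificance(float(p_fisher), float(np.log10(ps).sum()), len(ps), False)


@dataclass
class PermutationResult:
    p_value: float
    observed: int
    n_perm: int
    method: str                       # "exact" | "monte_carlo"
    statistic: str                    # "total" | "per_patient_indicator"
    null_distribution: np.ndarray | None = None
    n_unassayable: int = 0            # site/primary combinations lacking coverage


def _detection_matrix(
    site_lists: dict[str, pd.DataFrame],
    primary_calls: dict[str, set],
    primary_covered: dict[str, set] | None,
) -> tuple[np.ndarray, list[str], int]:
    patients = sorted(site_lists)
    n = len(patients)
    D = np.zeros((n, n), dtype=int)
    unassayable = 0
    for i, pi in enumerate(patients):
        sites = site_lists[pi]
        keys = [
            (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in sites.itertuples(index=False)
        ]
        for j, pj in enumerate(patients):
            calls = primary_calls[pj]
            covered = primary_covered.get(pj) if primary_covered else None
            det = 0
            for key in keys:
                if covered is not None and key not in covered:
                    unassayable += 1
                    continue
                if key in calls:
                    det += 1
            D[i, j] = det
    return D, patients, unassayable


def sample_permutation_test(
    site_lists: dict[str, pd.DataFrame],
    primary_calls: dict[str, set],
    primary_covered: dict[str, set] | None = None,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = 0,
    statistic: str = "total",
    exact_limit: int = 40_320,  # 8!
) -> PermutationResult:
    """Permutation null for the number of metastasis-specific detections.

    The assignment of each patient's assayed site list to a primary tumor is
    permuted; the default statistic is the total detection count (the number
    of patients with >= 1 detection is available as
    ``statistic="per_patient_indicator"``). Site/primary combinations without
    coverage in the permuted primary are counted as unassayable and recorded.
    Exhaustive enumeration is used when the number of assignments is small;
    otherwise Monte-Carlo with the add-one estimator
    ``P = (#{stat >= observed} + 1) / (n_perm + 1)``.
    """
    if len(site_lists) < 3:
        raise ValidationError("permutation test needs >= 3 patients")
    if set(site_lists) != set(primary_calls):
        raise ValidationError("site_lists and primary_calls must cover the same patients")
    D, patients, n_unassayable = _detection_matrix(site_lists, primary_calls, primary_covered)
    n = len(patients)

    def stat(assignment: tuple[int, ...] | np.ndarray) -> int:
        vals = D[np.arange(n), np.asarray(assignment)]
        if statistic == "per_patient_indicator":
            return int((vals > 0).sum())
        return int(vals.sum())

    observed = stat(np.arange(n))
    if math.factorial(n) <= exact_limit:
        stats = np.array([stat(perm) for perm in itertools.permutations(range(n))])
        p = float((stats >= observed).mean())
        return PermutationResult(p, observed, len(stats), "exact", statistic,
                                 stats, n_unassayable)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stats = np.array([stat(rng.permutation(n)) for _ in range(n_perm)])
    p = (int((stats >= observed).sum()) + 1) / (n_perm + 1)
    return PermutationResult(float(p), observed, n_perm, "monte_carlo", statistic,
                             stats, n_unassayable)
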