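"""VAF -> cancer cell fraction conversion with multiplicity handling.

The cancer cell fraction (CCF) of a mutation is the fraction of tumor cells
carrying it. Under the standard mixture model, the expected VAF of a mutation
present on ``s`` of the tumor alleles at a locus with tumor total copy number
``n_t``, in a sample with tumor purity ``p`` and normal copy number ``n_n``,
is::

    VAF = CCF * p * s / (p * n_t + (1 - p) * n_n)

which inverts to the conversion implemented here. Because ``s`` is unknown a
priori (bounded above by the major allele copy number), estimates are
produced for every feasible ``s`` and summarised by their median.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_model import CNSegment


def vaf_to_ccf(
    vaf: float,
    purity: float,
    total_cn_tumor: float,
    normal_cn: float = 2.0,
    s: float = 1.0,
) -> float:
    """Convert a VAF to a CCF; values above 1 are returned unclamped.

    >>> vaf_to_ccf(0.5, 1.0, 2, s=1)
    1.0
    """
    if not 0 < purity <= 1:
        raise ValidationError(f"purity must be in (0,1], got {purity}")
    if total_cn_tumor < 1:
        raise ValidationError(f"total_cn_tumor must be >= 1, got {total_cn_tumor}")
    if s < 1:
        raise ValidationError(f"multiplicity s must be >= 1, got {s}")
    return vaf * (purity * total_cn_tumor + (1 - purity) * normal_cn) / (purity * s)


def ccf_to_vaf(
    ccf: float,
    purity: float,
    total_cn_tumor: float,
    normal_cn: float = 2.0,
    s: float = 1.0,
) -> float:
    """Inverse of :func:`vaf_to_ccf` (used by the simulator)."""
    return ccf * purity * s / (purity * total_cn_tumor + (1 - purity) * normal_cn)


def enumerate_multiplicities(cn: CNSegment) -> list[int]:
    """Feasible multiplicity factors {1..major_cn} at a locus.

    A single candidate means the estimate is unambiguous (only one allele
    could carry the mutation). major_cn == 0 is a homozygous deletion, where
    no somatic point mutation can reside.
    """
    if cn.major_cn < 1:
        raise ValidationError(
            f"homozygous deletion at {cn.chrom}:{cn.start}-{cn.end}: no mutable allele"
        )
    return list(range(1, cn.major_cn + 1))


@dataclass
class CCFEstimate:
    """Per-multiplicity CCF values for one mutation.

    ``per_s[s] == per_s[1] / s`` exactly, by construction of the conversion.
    ``clamped_flag`` marks estimates exceeding 1 (reported unclamped).
    """

    mutation_id: str
    per_s: dict[int, float]
    s_candidates: list[int]
    median_across_s: float = field(init=False)
    unambiguous: bool = field(init=False)
    clamped_flag: bool = field(init=False)
    posterior_draws: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.per_s:
            raise ValidationError("CCFEstimate needs at least one multiplicity candidate")
        self.median_across_s = float(np.median(list(self.per_s.values())))
        self.unambiguous = len(self.s_candidates) == 1
        self.clamped_flag = any(v > 1 for v in self.per_s.values())


def estimate_ccf(
    mutation_id: str,
    vaf: float,
    purity: float,
    cn: CNSegment,
    normal_cn: float = 2.0,
) -> CCFEstimate:
    """Point CCF estimates for every feasible multiplicity at a locus."""
    candidates = enumerate_multiplicities(cn)
    base = vaf_to_ccf(vaf, purity, cn.total_cn, normal_cn, s=1)
    per_s = {s: base / s for s in candidates}
    return CCFEstimate(mutation_id=mutation_id, per_s=per_s, s_candidates=candidates)


def median_ccf_across_s(estimate: CCFEstimate) -> float:
    """Median of the per-multiplicity CCF values (the reporting convention)."""
    return estimate.median_across_s


def ccf_posterior(
    mt_alt: int,
    mt_total: int,
    purity: float,
    total_cn_tumor: float,
    s: float = 1.0,
    normal_cn: float = 2.0,
    n_draws: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Posterior draws of CCF from molecular-tag counts.

    The VAF posterior is Beta(mt_alt + 1/2, mt_total - mt_alt + 1/2) — a
    Jeffreys prior, whose influence vanishes at UMI depths — and each draw is
    mapped through the deterministic VAF->CCF conversion. Only count
    uncertainty is propagated; purity and copy number are treated as fixed.
    """
    if not 0 <= mt_alt <= mt_total or mt_total < 1:
        raise ValidationError(f"invalid counts mt_alt={mt_alt}, mt_total={mt_total}")
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vafs = rng.beta(mt_alt + 0.5, mt_total - mt_alt + 0.5, size=n_draws)
    factor = (purity * total_cn_tumor + (1 - purity) * normal_cn) / (purity * s)
    return vafs * factor
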