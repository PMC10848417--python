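"""Detection-power (limit of detection) statistics for sequencing models.

For a site covered by ``n`` effective independent observations (molecular
tags for UMI-corrected ultra-deep sequencing, reads for WES) and a caller
requiring at least ``m`` alternate observations, the smallest VAF detectable
with confidence ``gamma`` is the smallest ``v`` with::

    P[Binomial(n, v) >= m] >= gamma

found here by bisection (the tail is continuous and strictly increasing in
``v``). minCCF95 is that VAF pushed through the VAF->CCF conversion at the
site's purity and copy number, evaluated at multiplicity s = 1 — the
conservative choice, since higher multiplicity only lowers the detectable
CCF.

Default calling rules: the UMI model requires 8 alternate molecular tags,
which at a typical purity of ~0.7 yields a median minCCF95 of ~3% at ~1200x
MT depth and ~0.9% above 4000x; the WES model uses 50x coverage and 5
alternate reads, yielding minCCF95 ~ 0.5 at the same purity.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import binom

from .ccf_engine import vaf_to_ccf
from .errors import DetectionImpossibleError, ValidationError
from .io_model import CNSegment, TumorSample

__all__ = [
    "TechModel", "DetectionPower", "UDS_UMI_MODEL", "WES_MODEL",
    "min_detectable_vaf", "min_detectable_ccf", "power_table",
]


@dataclass(frozen=True)
class TechModel:
    """A named sequencing-technology detection model.

    ``depth`` is the fixed effective depth for technologies sequenced to a
    nominal coverage (WES); ``None`` means use each site's observed depth.
    """

    name: str
    min_alt_obs: int
    confidence: float = 0.95
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.min_alt_obs < 1:
            raise ValidationError("min_alt_obs must be >= 1")
        if not 0 < self.confidence < 1:
            raise ValidationError("confidence must be in (0,1)")

    def with_depth(self, depth: int) -> "TechModel":
        return replace(self, depth=int(depth))


UDS_UMI_MODEL = TechModel(name="UDS-UMI", min_alt_obs=8)
WES_MODEL = TechModel(name="WES", min_alt_obs=5, depth=50)


@dataclass(frozen=True)
class DetectionPower:
    """Per-site detection limits under one technology model."""

    site_id: str
    tech: str
    depth: int
    min_vaf: float
    min_ccf: float


def min_detectable_vaf(depth: int, model: TechModel, tol: float = 1e-6) -> float:
    """Smallest VAF detectable with the model's confidence at ``depth``.

    Bisection to absolute tolerance ``tol``; at the returned value the exact
    binomial tail meets or exceeds the confidence target.
    """
    depth = int(depth)
    m = model.min_alt_obs
    if depth < m:
        raise DetectionImpossibleError(
            f"depth {depth} cannot yield {m} alternate observations"
        )
    gamma = model.confidence

    def tail(v: float) -> float:
        return float(binom.sf(m - 1, depth, v))

    lo, hi = 0.0, 1.0
    # tail(1.0) == 1 >= gamma always (depth >= m), so hi stays feasible
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if tail(mid) >= gamma:
            hi = mid
        else:
            lo = mid
    return hi


def min_detectable_ccf(
    depth: int,
    sample: TumorSample,
    cn: CNSegment,
    model: TechModel,
    s: int = 1,
    normal_cn: float = 2.0,
) -> float:
    """minCCF at a site: the detection-limit VAF converted to a CCF."""
    use_depth = model.depth if model.depth is not None else depth
    v = min_detectable_vaf(use_depth, model)
    return vaf_to_ccf(v, sample.purity, cn.total_cn, normal_cn, s=s)


def power_table(
    sites: pd.DataFrame,
    samples: dict[str, TumorSample],
    cn_lookup,
    uds_model: TechModel = UDS_UMI_MODEL,
    wes_model: TechModel = WES_MODEL,
) -> pd.DataFrame:
    """Per-site detection-power table for both technology models.

    ``sites`` needs columns sample_id, chrom, pos, mt_total. ``cn_lookup``
    is either a single :class:`~raresub.io_model.CNProfile` or a mapping
    from patient_id to profile. Sites whose depth cannot support the UMI
    calling rule get NaN limits.
    """
    rows = []
    for r in sites.itertuples(index=False):
        sample = samples[str(r.sample_id)]
        profile = (cn_lookup[sample.patient_id] if isinstance(cn_lookup, dict)
                   else cn_lookup)
        seg = profile.lookup(str(r.chrom), int(r.pos))
        if seg is None:
            seg = CNSegment(str(r.chrom), int(r.pos), int(r.pos), 1, 1)
        try:
            uds_vaf = min_detectable_vaf(int(r.mt_total), uds_model)
            uds_ccf = vaf_to_ccf(uds_vaf, sample.purity, seg.total_cn, s=1)
        except DetectionImpossibleError:
            uds_vaf = uds_ccf = np.nan
        wes_vaf = min_detectable_vaf(wes_model.depth, wes_model)
        wes_ccf = vaf_to_ccf(wes_vaf, sample.purity, seg.total_cn, s=1)
        rows.append((r.sample_id, r.chrom, r.pos, int(r.mt_total),
                     uds_vaf, uds_ccf, wes_vaf, wes_ccf))
    return pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "pos", "mt_total",
        "min_vaf_uds", "min_ccf_uds", "min_vaf_wes", "min_ccf_wes",
    ])
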