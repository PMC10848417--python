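"""Rare-subclonal background burden and UDG artifact-depletion estimation.

Formalin fixation deaminates cytosine to uracil, which sequences as a C>T
substitution at low VAF; uracil-DNA glycosylase (UDG) pre-treatment digests
the damaged strands. The depletion estimator compares the *excess* of the
per-site C>T rare-subclonal mutation rate over the mean non-C>T rate (the
deamination-specific burden) between UDG-treated and untreated sequencing of
the same blocks::

    depletion = 1 - excess_treated / excess_untreated

Counts are pooled across matched pairs before taking the ratio, for
stability at low counts; uncertainty comes from a seeded bootstrap over
covered sites.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedEstimateError, ValidationError
from .io_model import CONTEXT_CLASSES, RoiPanel, parse_context_class

#: pyrimidine substitution types, in fixed order; index 2 is the FFPE class
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_TYPE_INDEX = {t: i for i, t in enumerate(SUBSTITUTION_TYPES)}


@dataclass
class BurdenProfile:
    """Rare-subclonal mutation burden of one sample over the panel.

    ``per_context_rate`` maps each of the 96 context classes to variants per
    covered site (NaN where the panel covers no site of that context — an
    undefined rate, deliberately distinct from 0). ``site_counts`` holds one
    row per covered site with per-substitution-type variant counts, the unit
    resampled by the depletion bootstrap.
    """

    sample_id: str
    panel_wide_rate: float
    per_context_rate: pd.Series
    n_covered_sites: pd.Series
    n_rare_variants: int
    n_sites: int
    site_counts: pd.DataFrame  # columns: canonical, center, n_ca .. n_tg

    def rate_by_subtype(self) -> pd.Series:
        """Variants per covered site for each of the 6 substitution types."""
        centers = self.site_counts["center"].to_numpy()
        n_c = int((centers == "C").sum())
        n_t = int((centers == "T").sum())
        rates = {}
        for sub, col in zip(SUBSTITUTION_TYPES, _COUNT_COLS):
            denom = n_c if sub[0] == "C" else n_t
            rates[sub] = self.site_counts[col].sum() / denom if denom else np.nan
        return pd.Series(rates)


_COUNT_COLS = ("n_ca", "n_cg", "n_ct", "n_ta", "n_tc", "n_tg")


def _empty_site_counts(panel: RoiPanel) -> pd.DataFrame:
    sites = panel.sites[["chrom", "pos", "canonical"]].copy()
    sites["center"] = sites["canonical"].str[1]
    for col in _COUNT_COLS:
        sites[col] = 0
    return sites


def rare_subclonal_burden(
    variants: pd.DataFrame,
    panel: RoiPanel,
    vaf_ceiling: float = 0.10,
    sample_id: str | None = None,
) -> BurdenProfile:
    """Panel-wide and per-context rare-subclonal mutation rates of one sample.

    Counts called variants with VAF strictly below ``vaf_ceiling`` whose
    class is background (or unlabeled), at covered panel sites; the context
    column must already hold canonical classes.
    """
    if sample_id is None:
        ids = variants["sample_id"].unique()
        if len(ids) > 1:
            raise ValidationError(
                "variants span multiple samples; pass sample_id explicitly"
            )
        sample_id = str(ids[0]) if len(ids) else "<empty>"
    v = variants[variants["sample_id"] == sample_id]
    v = v[v["called"] & (v["vaf"] < vaf_ceiling)]
    if "mutation_class" in v.columns:
        v = v[v["mutation_class"].isna() | (v["mutation_class"] == "background")]

    site_counts = _empty_site_counts(panel)
    key = pd.MultiIndex.from_frame(site_counts[["chrom", "pos"]])
    locator = pd.Series(np.arange(len(site_counts)), index=key)

    class_counts = pd.Series(0, index=list(CONTEXT_CLASSES), dtype=int)
    n_counted = 0
    for row in v.itertuples(index=False):
        ctx = getattr(row, "context", None)
        if not isinstance(ctx, str) or not ctx:
            continue
        try:
            i = locator[(str(row.chrom), int(row.pos))]
        except KeyError:
            continue  # outside the covered panel: not part of the denominator
        _, _, alt = parse_context_class(ctx)
        sub = f"{ctx[2]}>{alt}"
        site_counts.iloc[int(i), site_counts.columns.get_loc(_COUNT_COLS[_TYPE_INDEX[sub]])] += 1
        class_counts[ctx] += 1
        n_counted += 1

    covered = panel.covered_sites_per_triplet()
    n_covered = pd.Series(
        {cls: int(covered[cls[0] + cls[2] + cls[6]]) for cls in CONTEXT_CLASSES}
    )
    rate = class_counts / n_covered.replace(0, np.nan)
    return BurdenProfile(
        sample_id=sample_id,
        panel_wide_rate=n_counted / panel.n_sites,
        per_context_rate=rate,
        n_covered_sites=n_covered,
        n_rare_variants=n_counted,
        n_sites=panel.n_sites,
        site_counts=site_counts,
    )


@dataclass(frozen=True)
class DepletionEstimate:
    depletion: float            # clipped to [0, 1]
    raw: float                  # unclipped point estimate
    ci_low: float
    ci_high: float
    n_boot: int


def _ct_excess(counts: np.ndarray, centers: np.ndarray) -> float:
    """C>T rate minus the mean non-C>T substitution-type rate.

    ``counts`` is (n_sites, 6) in SUBSTITUTION_TYPES order; ``centers`` is a
    boolean array, True where the canonical center is C.
    """
    n_c = centers.sum()
    n_t = len(centers) - n_c
    if n_c == 0:
        return np.nan
    totals = counts.sum(axis=0)
    ct_rate = totals[2] / n_c
    baseline_rates = []
    for i, sub in enumerate(SUBSTITUTION_TYPES):
        if i == 2:
            continue
        denom = n_c if sub[0] == "C" else n_t
        if denom:
            baseline_rates.append(totals[i] / denom)
    return ct_rate - float(np.mean(baseline_rates)) if baseline_rates else ct_rate


def _pool(profiles: Sequence[BurdenProfile]) -> tuple[np.ndarray, np.ndarray]:
    frames = [p.site_counts for p in profiles]
    stacked = pd.concat(frames, ignore_index=True)
    counts = stacked[list(_COUNT_COLS)].to_numpy(dtype=float)
    centers = (stacked["center"] == "C").to_numpy()
    return counts, centers


def udg_depletion(
    treated: Sequence[BurdenProfile],
    untreated: Sequence[BurdenProfile],
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = 0,
    ci: float = 0.95,
) -> DepletionEstimate:
    """Fraction of FFPE C>T artifact burden removed by UDG treatment.

    Requires at least one matched treated/untreated profile pair. Raises
    :class:`UndefinedEstimateError` when the untreated samples show no
    demonstrable C>T excess (the artifact burden the estimator divides by).
    """
    if not treated or not untreated:
        raise ValidationError("need at least one treated and one untreated profile")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    counts_t, centers_t = _pool(treated)
    counts_u, centers_u = _pool(untreated)
    excess_u = _ct_excess(counts_u, centers_u)
    if not np.isfinite(excess_u) or excess_u <= 0:
        raise UndefinedEstimateError(
            "untreated C>T excess <= 0: FFPE artifact burden not demonstrable"
        )
    excess_t = _ct_excess(counts_t, centers_t)
    raw = 1.0 - excess_t / excess_u

    boots = np.empty(n_boot)
    n_t_sites, n_u_sites = len(centers_t), len(centers_u)
    for b in range(n_boot):
        it = rng.integers(0, n_t_sites, n_t_sites)
        iu = rng.integers(0, n_u_sites, n_u_sites)
        eu = _ct_excess(counts_u[iu], centers_u[iu])
        et = _ct_excess(counts_t[it], centers_t[it])
        boots[b] = 1.0 - et / eu if eu > 0 else np.nan
    alpha = (1 - ci) / 2
    finite = boots[np.isfinite(boots)]
    lo, hi = np.quantile(finite, [alpha, 1 - alpha]) if len(finite) else (np.nan, np.nan)
    return DepletionEstimate(
        depletion=float(np.clip(raw, 0.0, 1.0)),
        raw=float(raw), ci_low=float(lo), ci_high=float(hi), n_boot=n_boot,
    )


def context_spectrum(
    variants: pd.DataFrame,
    panel: RoiPanel | None = None,
    vaf_ceiling: float = 0.10,
) -> tuple[pd.Series | None, pd.Series]:
    """Normalised rare-subclonal mutation spectra over the 96 context classes.

    Returns ``(site_fraction, call_fraction)``: the proportion of covered
    sites mutated per class (None without a panel) and the proportion of
    rare-subclonal calls per class; each sums to 1.
    """
    v = variants[variants["called"] & (variants["vaf"] < vaf_ceiling)]
    v = v[v["context"].notna()] if "context" in v.columns else v.iloc[0:0]
    if len(v) == 0:
        raise UndefinedEstimateError("no rare-subclonal calls: spectrum undefined")
    counts = v["context"].value_counts().reindex(list(CONTEXT_CLASSES), fill_value=0)
    call_fraction = counts / counts.sum()
    site_fraction = None
    if panel is not None:
        covered = panel.covered_sites_per_triplet()
        denom = pd.Series(
            {cls: covered[cls[0] + cls[2] + cls[6]] for cls in CONTEXT_CLASSES}
        ).replace(0, np.nan)
        per_site = counts / denom
        total = per_site.sum(skipna=True)
        site_fraction = per_site / total if total > 0 else per_site
    return site_fraction, call_fraction
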