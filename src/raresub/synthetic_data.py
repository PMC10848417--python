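"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure of a paired
primary/metastasis UMI ultra-deep sequencing study: a targeted panel of
~200 short regions of interest (~2400 covered bases), a truncal clone plus
nested subclones with assigned CCFs, per-patient lists of assayed
metastasis-specific driver mutations of which a configurable fraction was
acquired only after dissemination (true primary CCF = 0), binomial
molecular-tag sampling at log-normal depth (median ~1160x, IQR ~600-2600x),
shallow 50x WES read sampling of the same mutations, and FFPE C>T artifact
injection by trinucleotide context with a UDG-depletion factor.

Subclone CCFs are specified directly rather than grown dynamically: the
pipeline's tests need controlled clone sizes, not growth kinetics (the
acquisition-likelihood framework has its own simulation oracle). Default
parameter values are the study conditions; see docs/methods.md for the
rationale behind each.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ccf_engine import ccf_to_vaf
from .errors import ConfigError
from .io_model import (
    CNProfile,
    CNSegment,
    RoiPanel,
    TumorSample,
    context_class,
    validate_variant_frame,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-scale defaults for the cohort simulator."""

    n_patients: int = 21
    seed: int = 0

    # panel geometry: ~204 regions of 11-22 bp, ~2400 covered bases
    n_roi: int = 204
    roi_len_min: int = 11
    roi_len_max: int = 22
    n_chroms: int = 22

    # sample composition
    purity_range: tuple[float, float] = (0.55, 0.85)
    ploidy: float = 2.0
    cn_gain_prob: float = 0.2          # chance a chromosome carries (2,1)

    # molecular-tag depth: log-normal, median 1160x, IQR ~599-2639x
    mt_depth_log_mean: float = math.log(1160.0)
    mt_depth_log_sigma: float = 1.1
    mt_depth_min: int = 100
    mt_depth_max: int = 6000
    met_mt_depth_log_mean: float = math.log(400.0)
    met_mt_depth_log_sigma: float = 0.8
    wes_depth: int = 50

    # mutation layout
    metspec_log_mean: float = math.log(3.0)   # per-patient assayed drivers,
    metspec_log_sigma: float = 1.0            # median 3, IQR ~1-8, max 33
    metspec_max: int = 33
    frac_post_dissemination: float = 0.925    # acquired after dissemination
    rare_ccf_range: tuple[float, float] = (0.015, 0.30)  # pre-dissemination,
    met_ccf_range: tuple[float, float] = (0.5, 1.0)      # log-uniform
    n_truncal_per_patient: int = 4
    background_rate: float = 0.002            # real rare somatic per site
    background_vaf_range: tuple[float, float] = (0.004, 0.09)

    # FFPE artifact model
    ffpe_ct_site_rate: float = 0.03   # untreated artifact prob per C-context site
    udg_efficiency: float = 0.9
    artifact_vaf_max: float = 0.05
    n_untreated_replicates: int = 0   # primaries re-sequenced without UDG

    # caller thresholds (simulated calling rule)
    min_alt_mts: int = 8
    wes_min_alt_reads: int = 5

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not 0 <= self.frac_post_dissemination <= 1:
            raise ConfigError("frac_post_dissemination must be in [0,1]")
        if not 0 <= self.udg_efficiency <= 1:
            raise ConfigError("udg_efficiency must be in [0,1]")
        if not 0 < self.rare_ccf_range[0] <= self.rare_ccf_range[1] <= 1:
            raise ConfigError("rare_ccf_range must be nested in (0,1]")
        if not 0 < self.met_ccf_range[0] <= self.met_ccf_range[1] <= 1:
            raise ConfigError("met_ccf_range must be nested in (0,1]")
        if self.rare_ccf_range[1] > 1 or self.met_ccf_range[1] > 1:
            raise ConfigError("clone CCFs cannot exceed the truncal clone (CCF 1)")
        if self.n_untreated_replicates > self.n_patients:
            raise ConfigError("more untreated replicates than patients")


@dataclass
class SimulatedCohort:
    config: SimConfig
    panel: RoiPanel
    samples: dict[str, TumorSample]
    cn: dict[str, CNProfile]                 # patient_id -> profile
    variants: pd.DataFrame                   # UMI variant table, all samples
    wes: pd.DataFrame                        # shallow WES observations
    truth: pd.DataFrame                      # per-mutation ground truth
    artifact_truth: pd.DataFrame             # injected FFPE artifacts


def make_panel(rng: np.random.Generator, config: SimConfig) -> RoiPanel:
    """Random targeted panel: short regions with random reference sequence."""
    lengths = rng.integers(config.roi_len_min, config.roi_len_max + 1, config.n_roi)
    rows = []
    for i, length in enumerate(lengths):
        chrom = f"chr{(i % config.n_chroms) + 1}"
        start = int(rng.integers(10_000, 100_000_000))
        seq = "".join(rng.choice(_BASES, size=length + 2))  # 1-bp flanks
        for off in range(length):
            pos = start + off
            rows.append((chrom, pos, seq[off + 1], seq[off:off + 3]))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref_base", "triplet"])
    sites = sites.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
    return RoiPanel(sites=sites)


def _draw_depth(rng, n, log_mean, log_sigma, lo, hi):
    d = np.exp(rng.normal(log_mean, log_sigma, n))
    return np.clip(np.round(d), lo, hi).astype(int)


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(0, 3))]


def simulate_cohort(config: SimConfig | None = None) -> SimulatedCohort:
    """Generate a full cohort; deterministic under ``config.seed``."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = make_panel(rng, config)
    n_sites = panel.n_sites
    site_triplets = panel.sites["triplet"].to_numpy()
    site_refs = panel.sites["ref_base"].to_numpy()
    site_chroms = panel.sites["chrom"].to_numpy()
    site_pos = panel.sites["pos"].to_numpy()

    samples: dict[str, TumorSample] = {}
    cn: dict[str, CNProfile] = {}
    truth_rows = []
    var_rows = []
    wes_rows = []

    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        purity_p = float(rng.uniform(*config.purity_range))
        purity_m = float(rng.uniform(*config.purity_range))
        prim_id, met_id = f"{pid}_P", f"{pid}_M"
        samples[prim_id] = TumorSample(pid, prim_id, "PI", "primary", purity_p,
                                       config.ploidy, "FFPE", True, 10.0)
        samples[met_id] = TumorSample(pid, met_id, "MI", "metastasis", purity_m,
                                      config.ploidy, "frozen", True, 1.0)
        if i < config.n_untreated_replicates:
            uid = f"{pid}_PU"
            samples[uid] = TumorSample(pid, uid, "PI", "primary", purity_p,
                                       config.ploidy, "FFPE", False, 10.0)

        segs = []
        for c in range(1, config.n_chroms + 1):
            major = 2 if rng.random() < config.cn_gain_prob else 1
            segs.append(CNSegment(f"chr{c}", 1, 300_000_000, major, 1))
        cn[pid] = CNProfile(segs)

        # mutation layout for this patient
        n_metspec = int(np.clip(round(
            float(np.exp(rng.normal(config.metspec_log_mean, config.metspec_log_sigma)))),
            1, config.metspec_max))
        n_targets = n_metspec + config.n_truncal_per_patient
        target_idx = rng.choice(n_sites, size=n_targets, replace=False)
        metspec_idx = target_idx[:n_metspec]
        truncal_idx = target_idx[n_metspec:]

        post = rng.random(n_metspec) < config.frac_post_dissemination
        lo, hi = config.rare_ccf_range
        pre_ccf = np.exp(rng.uniform(math.log(lo), math.log(hi), n_metspec))
        ccf_primary = np.where(post, 0.0, pre_ccf)
        mlo, mhi = config.met_ccf_range
        ccf_met = np.exp(rng.uniform(math.log(mlo), math.log(mhi), n_metspec))

        patient_muts = []
        for j, sidx in enumerate(metspec_idx):
            patient_muts.append((sidx, "metspec_driver",
                                 "post" if post[j] else "pre",
                                 float(ccf_primary[j]), float(ccf_met[j])))
        for sidx in truncal_idx:
            patient_muts.append((sidx, "truncal", "pre", 1.0, 1.0))

        # real rare somatic background, drawn per sample at panel sites
        target_mask = np.zeros(n_sites, dtype=bool)
        target_mask[target_idx] = True
        for sample_id, _role in [(prim_id, "primary"), (met_id, "metastasis")]:
            bg_sites = np.nonzero((rng.random(n_sites) < config.background_rate)
                                  & ~target_mask)[0]
            for sidx in bg_sites:
                bvaf = float(rng.uniform(*config.background_vaf_range))
                truth_rows.append((pid, sample_id, f"{pid}:bg:{sample_id}:{sidx}",
                                   site_chroms[sidx], int(site_pos[sidx]),
                                   site_refs[sidx], _alt_base(rng, site_refs[sidx]),
                                   "background", "na", np.nan, np.nan, bvaf))

        for sidx, mclass, phase, ccf_p, ccf_m in patient_muts:
            alt = _alt_base(rng, site_refs[sidx])
            mut_id = f"{pid}:{site_chroms[sidx]}:{int(site_pos[sidx])}:{site_refs[sidx]}>{alt}"
            truth_rows.append((pid, "", mut_id, site_chroms[sidx], int(site_pos[sidx]),
                               site_refs[sidx], alt, mclass, phase,
                               float(ccf_p), float(ccf_m), np.nan))

    truth = pd.DataFrame(truth_rows, columns=[
        "patient_id", "bg_sample_id", "mutation_id", "chrom", "pos", "ref", "alt",
        "mutation_class", "phase", "true_ccf_primary", "true_ccf_met", "true_vaf_bg",
    ])

    # ------------------------------------------------------------------
    # observation layer: molecular-tag sampling per (sample, mutation site)
    for sample_id, sample in samples.items():
        pid = sample.patient_id
        is_primary = sample.role == "primary"
        pat_truth = truth[truth["patient_id"] == pid]
        somatic = pat_truth[pat_truth["mutation_class"] != "background"]
        background = pat_truth[(pat_truth["mutation_class"] == "background")
                               & (pat_truth["bg_sample_id"].isin(
                                   [sample_id.replace("_PU", "_P")]))]
        if is_primary:
            log_mean, log_sigma = config.mt_depth_log_mean, config.mt_depth_log_sigma
        else:
            log_mean, log_sigma = config.met_mt_depth_log_mean, config.met_mt_depth_log_sigma

        for sub in (somatic, background):
            n = len(sub)
            if n == 0:
                continue
            depths = _draw_depth(rng, n, log_mean, log_sigma,
                                 config.mt_depth_min, config.mt_depth_max)
            for (row, depth) in zip(sub.itertuples(index=False), depths):
                seg = cn[pid].lookup(row.chrom, int(row.pos))
                if row.mutation_class == "background":
                    vaf_true = float(row.true_vaf_bg)
                else:
                    ccf = row.true_ccf_primary if is_primary else row.true_ccf_met
                    vaf_true = ccf_to_vaf(float(ccf), sample.purity, seg.total_cn, s=1)
                mt_alt = int(rng.binomial(depth, vaf_true))
                keep = (mt_alt > 0) or (row.mutation_class != "background")
                if keep:
                    var_rows.append((pid, sample_id, row.chrom, int(row.pos), row.ref,
                                     row.alt, mt_alt, int(depth),
                                     mt_alt >= config.min_alt_mts,
                                     row.mutation_class))
                # shallow WES of somatic mutations in both tumors
                if row.mutation_class != "background" and not sample_id.endswith("_PU"):
                    wes_alt = int(rng.binomial(config.wes_depth, vaf_true))
                    wes_rows.append((pid, sample_id, row.chrom, int(row.pos), row.ref,
                                     row.alt, wes_alt, config.wes_depth,
                                     wes_alt >= config.wes_min_alt_reads,
                                     row.mutation_class))

    variants = pd.DataFrame(var_rows, columns=[
        "patient_id", "sample_id", "chrom", "pos", "ref", "alt",
        "mt_alt", "mt_total", "called", "mutation_class",
    ])
    # annotate contexts from the panel reference
    tri_lookup = {(c, p): t for c, p, t in
                  zip(site_chroms, site_pos, site_triplets)}
    variants["context"] = [
        context_class(tri_lookup[(r.chrom, r.pos)], r.ref, r.alt)
        if len(r.ref) == 1 and len(r.alt) == 1 else None
        for r in variants.itertuples(index=False)
    ]
    variants = validate_variant_frame(variants)

    wes = pd.DataFrame(wes_rows, columns=[
        "patient_id", "sample_id", "chrom", "pos", "ref", "alt",
        "alt_reads", "total_reads", "called", "mutation_class",
    ])
    if len(wes):
        wes["vaf"] = wes["alt_reads"] / wes["total_reads"]

    cohort = SimulatedCohort(
        config=config, panel=panel, samples=samples, cn=cn,
        variants=variants, wes=wes, truth=truth,
        artifact_truth=pd.DataFrame(columns=[
            "sample_id", "chrom", "pos", "ref", "alt", "mt_alt", "mt_total", "vaf"]),
    )
    if config.ffpe_ct_site_rate > 0:
        augmented, art_truth = inject_ffpe_artifacts(
            cohort.variants, panel, samples,
            context_rates=config.ffpe_ct_site_rate,
            udg_efficiency=config.udg_efficiency,
            rng=rng,
            depth_log_mean=config.mt_depth_log_mean,
            depth_log_sigma=config.mt_depth_log_sigma,
            depth_clip=(config.mt_depth_min, config.mt_depth_max),
            artifact_vaf_max=config.artifact_vaf_max,
            min_alt_mts=config.min_alt_mts,
        )
        cohort.variants = augmented
        cohort.artifact_truth = art_truth
    return cohort


def inject_ffpe_artifacts(
    variants: pd.DataFrame,
    panel: RoiPanel,
    samples: dict[str, TumorSample],
    context_rates: float | dict[str, float],
    udg_efficiency: float,
    rng: np.random.Generator | int | None = 0,
    depth_log_mean: float = math.log(1160.0),
    depth_log_sigma: float = 1.1,
    depth_clip: tuple[int, int] = (100, 6000),
    artifact_vaf_max: float = 0.05,
    min_alt_mts: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject low-VAF C>T deamination artifacts into FFPE samples.

    ``context_rates`` is either a single per-C-site artifact probability or a
    map from canonical pyrimidine triplet to probability. UDG-treated samples
    receive ``rate * (1 - udg_efficiency)``. Artifact VAFs are drawn from
    Uniform(1/depth, ``artifact_vaf_max``). Returns the augmented variant
    table and the artifact ground truth.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if isinstance(context_rates, dict):
        bad = [v for v in context_rates.values() if not 0 <= v <= 1]
    else:
        bad = [] if 0 <= context_rates <= 1 else [context_rates]
    if bad:
        raise ConfigError(f"artifact rates must be in [0,1], got {bad[0]}")
    if not 0 <= udg_efficiency <= 1:
        raise ConfigError("udg_efficiency must be in [0,1]")

    sites = panel.sites
    c_mask = sites["canonical"].str[1].to_numpy() == "C"
    canonical = sites["canonical"].to_numpy()
    new_rows = []
    truth_rows = []
    occupied = set(zip(variants["sample_id"], variants["chrom"], variants["pos"],
                       variants["alt"]))
    for sample_id, sample in samples.items():
        if sample.preservation != "FFPE":
            continue
        factor = (1.0 - udg_efficiency) if sample.udg_treated else 1.0
        if isinstance(context_rates, dict):
            base = np.array([context_rates.get(t, 0.0) for t in canonical])
        else:
            base = np.full(len(sites), float(context_rates))
        prob = np.where(c_mask, base * factor, 0.0)
        hit = np.nonzero(rng.random(len(sites)) < prob)[0]
        if hit.size == 0:
            continue
        depths = _draw_depth(rng, hit.size, depth_log_mean, depth_log_sigma, *depth_clip)
        for sidx, depth in zip(hit, depths):
            row = sites.iloc[int(sidx)]
            ref = str(row["ref_base"])
            alt = "T" if ref == "C" else "A"   # C>T on the pyrimidine strand
            vaf = float(rng.uniform(1.0 / depth, artifact_vaf_max))
            mt_alt = int(rng.binomial(depth, vaf))
            if mt_alt == 0:
                continue
            key = (sample_id, row["chrom"], int(row["pos"]), alt)
            if key in occupied:
                continue
            ctx = context_class(str(row["triplet"]), ref, alt)
            new_rows.append((sample.patient_id, sample_id, row["chrom"], int(row["pos"]),
                             ref, alt, mt_alt, int(depth), mt_alt >= min_alt_mts,
                             "background", ctx))
            truth_rows.append((sample_id, row["chrom"], int(row["pos"]), ref, alt,
                               mt_alt, int(depth), vaf))
    if new_rows:
        add = pd.DataFrame(new_rows, columns=[
            "patient_id", "sample_id", "chrom", "pos", "ref", "alt",
            "mt_alt", "mt_total", "called", "mutation_class", "context"])
        augmented = pd.concat([variants, add], ignore_index=True)
        augmented = validate_variant_frame(augmented)
    else:
        augmented = variants
    artifact_truth = pd.DataFrame(truth_rows, columns=[
        "sample_id", "chrom", "pos", "ref", "alt", "mt_alt", "mt_total", "vaf"])
    return augmented, artifact_truth


def ground_truth_report(cohort: SimulatedCohort) -> pd.DataFrame:
    """Per-mutation truth with observation-join completeness checks.

    Verifies that every somatic (non-background) truth mutation has variant
    rows in both of its patient's UDG-treated samples, that per-class counts
    match the configuration, and that no injected artifact is labeled with a
    somatic mutation class.
    """
    truth = cohort.truth
    variants = cohort.variants
    somatic = truth[truth["mutation_class"] != "background"]
    obs_keys = set(zip(variants["patient_id"], variants["sample_id"],
                       variants["chrom"], variants["pos"], variants["alt"]))
    missing = []
    for r in somatic.itertuples(index=False):
        for suffix in ("_P", "_M"):
            key = (r.patient_id, f"{r.patient_id}{suffix}", r.chrom, r.pos, r.alt)
            if key not in obs_keys:
                missing.append(key)
    if missing:
        raise ConfigError(f"{len(missing)} somatic truth mutations lack observations; "
                          f"first: {missing[0]}")
    n_truncal = (somatic["mutation_class"] == "truncal").groupby(
        somatic["patient_id"]).sum()
    if (n_truncal != cohort.config.n_truncal_per_patient).any():
        raise ConfigError("truncal mutation counts do not match the configuration")
    if len(cohort.artifact_truth):
        art_keys = set(zip(cohort.artifact_truth["sample_id"],
                           cohort.artifact_truth["chrom"],
                           cohort.artifact_truth["pos"],
                           cohort.artifact_truth["alt"]))
        labeled = variants[[(s, c, p, a) in art_keys for s, c, p, a in
                            zip(variants["sample_id"], variants["chrom"],
                                variants["pos"], variants["alt"])]]
        if (labeled["mutation_class"] != "background").any():
            raise ConfigError("an injected artifact carries a somatic class label")
    return truth.copy()
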