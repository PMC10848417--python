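"""End-to-end orchestration: file IO, stage composition, summary emission.

Each stage reads and writes plain tables (TSV/JSON), is deterministic under
the configured seeds, and logs one structured line with its parameters and
record counts. No stage mutates an upstream artifact.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clonal_inference as ci
from . import detection_power as dp
from . import evolution_model as evo
from . import ffpe_udg
from . import fp_significance as fps
from .ccf_engine import estimate_ccf
from .errors import ValidationError
from .io_model import (
    CNProfile,
    CNSegment,
    RoiPanel,
    read_samples,
    read_variant_table,
    write_samples,
    write_variant_table,
)
from .synthetic_data import SimulatedCohort


@dataclass
class RunConfig:
    """Thresholds and seeds for a full pipeline run."""

    vaf_ceiling: float = 0.10       # rare-subclone VAF definition
    major_ccf: float = 0.50         # major/minor CCF split
    coverage_floor: int = 100       # minimum MTs for a site to be assayable
    alpha: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    detection_floor_ccf: float = 0.03   # assay's average rare-subclone floor
    evolution_mu: float = evo.DEFAULT_MU
    evolution_T: float = 1e6            # assayable cell pool for the bounded model

    def validate(self) -> None:
        for name in ("vaf_ceiling", "major_ccf", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        if self.coverage_floor < 1:
            raise ValidationError("coverage_floor must be >= 1")


# ---------------------------------------------------------------------------
# cohort disk round-trip (used by the CLI `simulate` and `run-all` stages)

def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_variant_table(cohort.variants, outdir / "variants.tsv")
    cohort.wes.to_csv(outdir / "wes.tsv", sep="\t", index=False)
    write_samples(cohort.samples, outdir / "samples.tsv")
    cohort.panel.sites.to_csv(outdir / "roi_sites.tsv", sep="\t", index=False)
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    cohort.artifact_truth.to_csv(outdir / "artifact_truth.tsv", sep="\t", index=False)
    rows = []
    for pid, profile in cohort.cn.items():
        for seg in profile:
            rows.append((pid, seg.chrom, seg.start, seg.end, seg.major_cn, seg.minor_cn))
    pd.DataFrame(rows, columns=["patient_id", "chrom", "start", "end",
                                "major_cn", "minor_cn"]).to_csv(
        outdir / "cn_segments.tsv", sep="\t", index=False)


@dataclass
class CohortBundle:
    variants: pd.DataFrame
    wes: pd.DataFrame | None
    samples: dict
    cn: dict[str, CNProfile]
    panel: RoiPanel
    truth: pd.DataFrame | None = None


def read_cohort(indir: str | Path) -> CohortBundle:
    indir = Path(indir)
    variants = read_variant_table(indir / "variants.tsv")
    samples = read_samples(indir / "samples.tsv")
    sites = pd.read_csv(indir / "roi_sites.tsv", sep="\t", dtype={"chrom": str})
    panel = RoiPanel(sites=sites)
    cn_df = pd.read_csv(indir / "cn_segments.tsv", sep="\t",
                        dtype={"chrom": str, "patient_id": str})
    cn = {
        pid: CNProfile(
            CNSegment(r.chrom, int(r.start), int(r.end), int(r.major_cn), int(r.minor_cn))
            for r in grp.itertuples(index=False))
        for pid, grp in cn_df.groupby("patient_id")
    }
    wes_path = indir / "wes.tsv"
    wes = pd.read_csv(wes_path, sep="\t", dtype={"chrom": str}) if wes_path.exists() else None
    truth_path = indir / "truth.tsv"
    truth = (pd.read_csv(truth_path, sep="\t", dtype={"chrom": str})
             if truth_path.exists() else None)
    return CohortBundle(variants, wes, samples, cn, panel, truth)


# ---------------------------------------------------------------------------
# analysis stages

def metspec_site_lists(bundle: CohortBundle) -> dict[str, pd.DataFrame]:
    """Per-patient assayed metastasis-specific mutation lists.

    Taken from ground truth when present, else from mutations called in the
    metastasis sample but labeled metastasis-specific.
    """
    if bundle.truth is not None:
        t = bundle.truth
        met = t[t["mutation_class"] == "metspec_driver"]
        return {pid: grp[["patient_id", "chrom", "pos", "ref", "alt"]]
                for pid, grp in met.groupby("patient_id")}
    v = bundle.variants
    met = v[v["called"] & v["mutation_class"].isin(["metspec_driver"])
            & v["sample_id"].str.endswith("_M")]
    return {pid: grp[["patient_id", "chrom", "pos", "ref", "alt"]]
            for pid, grp in met.groupby("patient_id")}


def run_detection_stage(bundle: CohortBundle, config: RunConfig,
                        log: list) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection status of every assayed metastasis-specific mutation in its
    antecedent primary; returns (per-mutation detail, per-patient summary)."""
    details, summaries = [], []
    for pid, muts in metspec_site_lists(bundle).items():
        prim_id = f"{pid}_P"
        prim = bundle.variants[bundle.variants["sample_id"] == prim_id]
        if prim_id not in bundle.samples or len(prim) == 0:
            continue
        detail, summary = ci.detect_metspec_in_primary(
            muts, prim, bundle.samples[prim_id], bundle.cn[pid],
            coverage_floor=config.coverage_floor,
            vaf_ceiling=config.vaf_ceiling, major_ccf=config.major_ccf)
        detail = detail.assign(patient_id=pid)
        details.append(detail)
        summaries.append({
            "patient_id": pid, "n_assayed": summary.n_assayed,
            "n_detected_high_vaf": summary.n_detected_high_vaf,
            "n_detected_rare": summary.n_detected_rare,
            "n_undetected": summary.n_undetected,
            "n_excluded": summary.n_excluded,
        })
    details = [d for d in details if len(d)]
    detail_df = pd.concat(details, ignore_index=True) if details else pd.DataFrame()
    summary_df = pd.DataFrame(summaries)
    log.append({"stage": "detect", "patients": len(summary_df),
                "assayed": int(summary_df["n_assayed"].sum()) if len(summary_df) else 0,
                "coverage_floor": config.coverage_floor})
    return detail_df, summary_df


def run_significance_stage(bundle: CohortBundle, config: RunConfig,
                           detection_detail: pd.DataFrame, log: list) -> dict:
    """Artifact-likelihood and sample-permutation significance of the
    rare-subclone detections."""
    per_patient_tails = {}
    rng = np.random.default_rng(config.seed)
    site_lists = metspec_site_lists(bundle)
    target_keys = {
        pid: set(zip(m["chrom"].astype(str), m["pos"].astype(int)))
        for pid, m in site_lists.items()
    }
    for pid, muts in site_lists.items():
        prim_id = f"{pid}_P"
        prim = bundle.variants[bundle.variants["sample_id"] == prim_id]
        if len(prim) == 0:
            continue
        # background burden excludes the assayed target sites themselves
        bg = prim[~prim.apply(
            lambda r: (str(r["chrom"]), int(r["pos"])) in target_keys[pid], axis=1)]
        burden = ffpe_udg.rare_subclonal_burden(
            bg, bundle.panel, vaf_ceiling=config.vaf_ceiling, sample_id=prim_id)
        model = fps.build_artifact_model(burden)
        det = detection_detail[detection_detail["patient_id"] == pid]
        n_assayed = int((det["stratum"] != "excluded").sum())
        n_rare = int((det["stratum"] == "rare").sum())
        if n_assayed:
            per_patient_tails[pid] = fps.prob_false_detections(n_assayed, model, n_rare)
    combined = fps.combined_significance(list(per_patient_tails.values()))

    primary_calls, primary_covered = {}, {}
    for pid in site_lists:
        prim = bundle.variants[bundle.variants["sample_id"] == f"{pid}_P"]
        adequately = prim[prim["mt_total"] >= config.coverage_floor]
        rare = adequately[adequately["called"] & (adequately["vaf"] < config.vaf_ceiling)]
        primary_calls[pid] = set(zip(rare["chrom"].astype(str), rare["pos"].astype(int),
                                     rare["ref"].astype(str), rare["alt"].astype(str)))
        primary_covered[pid] = set(zip(adequately["chrom"].astype(str),
                                       adequately["pos"].astype(int),
                                       adequately["ref"].astype(str),
                                       adequately["alt"].astype(str)))
    perm = None
    if len(site_lists) >= 3:
        perm = fps.sample_permutation_test(
            site_lists, primary_calls, primary_covered,
            n_perm=config.n_perm, seed=rng)
    log.append({"stage": "significance", "patients": len(per_patient_tails),
                "n_perm": config.n_perm, "seed": config.seed})
    return {
        "per_patient_tails": per_patient_tails,
        "combined_fisher": combined.p_fisher,
        "combined_log10_product": combined.log10_product,
        "permutation_p": None if perm is None else perm.p_value,
        "permutation_observed": None if perm is None else perm.observed,
    }


def run_evolution_stage(bundle: CohortBundle, config: RunConfig, log: list) -> dict:
    """Per-patient bounded sequential-acquisition probabilities for the
    metastasis-specific series, combined across the cohort (log10)."""
    per_patient = {}
    for pid, muts in metspec_site_lists(bundle).items():
        met_id = f"{pid}_M"
        met = bundle.variants[bundle.variants["sample_id"] == met_id]
        if met_id not in bundle.samples:
            continue
        sample = bundle.samples[met_id]
        key = set(zip(muts["chrom"].astype(str), muts["pos"].astype(int)))
        ccfs = {}
        for r in met.itertuples(index=False):
            if (str(r.chrom), int(r.pos)) not in key or not r.called:
                continue
            seg = bundle.cn[pid].lookup(str(r.chrom), int(r.pos))
            if seg is None:
                continue
            est = estimate_ccf(f"{r.chrom}:{r.pos}", float(r.vaf), sample.purity, seg)
            ccfs[f"{r.chrom}:{r.pos}"] = est.median_across_s
        _, k = ci.sequential_lineage_set(ccfs, ccf_floor=config.major_ccf)
        if k >= 1:
            p = evo.p_sequence_bounded(
                k=k, d=k - 1, mu=config.evolution_mu, T=config.evolution_T,
                f=config.detection_floor_ccf)
            per_patient[pid] = p.log10
    combined = (evo.combine_patient_probabilities(list(per_patient.values()))
                if per_patient else float("nan"))
    log.append({"stage": "evolve", "patients": len(per_patient),
                "mu": config.evolution_mu, "T": config.evolution_T,
                "f": config.detection_floor_ccf})
    return {"per_patient_log10": per_patient, "combined_log10": combined}


def run_full_analysis(indir: str | Path, outdir: str | Path,
                      config: RunConfig | None = None) -> dict:
    """Execute every stage on a cohort directory and write summary tables.

    Emits per-patient and cohort summaries, the per-site power table, and
    the figure-data analogues (detections per patient, detection by coverage
    bin, rare-subclone CCFs); deterministic given the config seed.
    """
    config = config or RunConfig()
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = read_cohort(indir)
    log: list[dict] = []

    detail, summary = run_detection_stage(bundle, config, log)
    significance = run_significance_stage(bundle, config, detail, log)
    evolution = run_evolution_stage(bundle, config, log)

    sites = bundle.variants[bundle.variants["mutation_class"] == "metspec_driver"]
    sites = sites[sites["sample_id"].str.endswith("_P")]
    power = dp.power_table(sites, bundle.samples, bundle.cn)
    log.append({"stage": "power", "sites": len(power)})

    n_assayed = int(summary["n_assayed"].sum()) if len(summary) else 0
    n_undetected = int(summary["n_undetected"].sum()) if len(summary) else 0
    cohort_summary = {
        "n_patients": int(len(summary)),
        "n_assayed": n_assayed,
        "n_undetected": n_undetected,
        "undetected_fraction": n_undetected / n_assayed if n_assayed else None,
        "n_detected_rare": int(summary["n_detected_rare"].sum()) if len(summary) else 0,
        "median_min_ccf_uds": float(power["min_ccf_uds"].median()) if len(power) else None,
        "significance": significance,
        "evolution": evolution,
        "thresholds": asdict(config),
    }

    detail.to_csv(outdir / "detection_detail.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "patient_summaries.tsv", sep="\t", index=False)
    power.to_csv(outdir / "power_table.tsv", sep="\t", index=False)
    rare = detail[detail["stratum"] == "rare"] if len(detail) else detail
    rare.to_csv(outdir / "rare_subclone_ccfs.tsv", sep="\t", index=False)
    cov = power.copy()
    cov["bin"] = pd.cut(cov["mt_total"], [100, 500, 1000, 2000, 4000, np.inf])
    cov.groupby("bin", observed=True)["min_ccf_uds"].median().to_csv(
        outdir / "power_by_coverage.tsv", sep="\t")
    with open(outdir / "cohort_summary.json", "w") as fh:
        json.dump(cohort_summary, fh, indent=2, default=float)
    with open(outdir / "run_log.jsonl", "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry, default=float) + "\n")
    return cohort_summary


@dataclass(frozen=True)
class ConcordanceReport:
    """Cross-technology concordance of shared calls."""

    n_wes_called: int
    n_recalled: int
    recall: float
    r_squared: float | None
    n_overlap_vaf: int


def concordance_report(wes_calls: pd.DataFrame, uds_calls: pd.DataFrame) -> ConcordanceReport:
    """Recall of WES calls by the UMI assay, and VAF agreement (R^2).

    Call sets are keyed by (sample, chrom, pos, ref, alt); R^2 is the squared
    Pearson correlation of the two technologies' VAFs on the doubly-called
    intersection (undefined — None — when the intersection is empty).
    """
    key = ["sample_id", "chrom", "pos", "ref", "alt"]
    wes = wes_calls[wes_calls["called"]].copy()
    uds = uds_calls[uds_calls["called"]].copy()
    if "vaf" not in wes.columns and "alt_reads" in wes.columns:
        wes["vaf"] = wes["alt_reads"] / wes["total_reads"]
    merged = wes.merge(uds[key + ["vaf"]], on=key, how="left",
                       suffixes=("_wes", "_uds"))
    n_wes = len(merged)
    recalled = merged["vaf_uds"].notna()
    n_recalled = int(recalled.sum())
    both = merged[recalled]
    r2 = None
    if len(both) >= 2 and both["vaf_wes"].std() > 0 and both["vaf_uds"].std() > 0:
        r = np.corrcoef(both["vaf_wes"], both["vaf_uds"])[0, 1]
        r2 = float(r * r)
    return ConcordanceReport(
        n_wes_called=n_wes, n_recalled=n_recalled,
        recall=n_recalled / n_wes if n_wes else float("nan"),
        r_squared=r2, n_overlap_vaf=int(len(both)),
    )
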