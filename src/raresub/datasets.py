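"""Bundled example datasets.

The rare-subclone input table is a *reconstruction*, not measured data: it
holds synthetic molecular-tag counts, purities and allele-specific copy
numbers for the nine metastasis-specific driver mutations detected within
rare primary-tumor subclones of the motivating cohort, chosen so that the
CCF engine reproduces the per-patient point estimates reported for that
cohort (e.g. PEAK1 K140Q at VAF 0.062 -> CCF 0.24 with a single mutable
allele). It exists so the worked examples and summary recomputations can
run without access to the original per-site supplementary data.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .ccf_engine import CCFEstimate, estimate_ccf
from .io_model import CNSegment


def load_rare_subclone_inputs() -> pd.DataFrame:
    """Reconstructed inputs for the nine rare-subclone driver detections."""
    ref = resources.files("raresub.data") / "rare_subclone_inputs_reconstructed.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df["vaf"] = df["mt_alt"] / df["mt_total"]
    return df


def rare_subclone_ccf_estimates() -> dict[str, CCFEstimate]:
    """CCF estimates (per multiplicity and median) for the bundled table."""
    df = load_rare_subclone_inputs()
    out: dict[str, CCFEstimate] = {}
    for r in df.itertuples(index=False):
        seg = CNSegment("chr1", 1, 2, int(r.major_cn), int(r.minor_cn))
        out[str(r.gene)] = estimate_ccf(str(r.gene), float(r.vaf), float(r.purity), seg)
    return out
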