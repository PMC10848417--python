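"""Domain types, readers/writers, and validation for pipeline inputs.

Conventions
-----------
* Variant positions are 1-based (VCF dialect). BED region files are 0-based
  half-open and converted to 1-based inclusive on read.
* Trinucleotide contexts are always reported on the strand where the
  reference base is a pyrimidine (C or T), the mutational-signature
  convention, giving 6 substitution types x 16 flank combinations = 96
  classes such as ``"A[C>T]G"``.
"""
from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import AnnotationError, SchemaError, ValidationError

# ---------------------------------------------------------------------------
# trinucleotide context machinery

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

PYRIMIDINE_SUBSTITUTIONS: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)

#: the 96 canonical (flank, substitution, flank) classes
CONTEXT_CLASSES: tuple[str, ...] = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in PYRIMIDINE_SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)

#: the 32 canonical pyrimidine-centered reference triplets
CANONICAL_TRIPLETS: tuple[str, ...] = tuple(
    f"{five}{center}{three}"
    for center in "CT"
    for five in "ACGT"
    for three in "ACGT"
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_triplet(triplet: str) -> str:
    """Map a reference triplet to its pyrimidine-centered representative."""
    triplet = triplet.upper()
    if len(triplet) != 3 or any(b not in "ACGT" for b in triplet):
        raise AnnotationError(f"not a DNA triplet: {triplet!r}")
    return triplet if triplet[1] in "CT" else revcomp(triplet)


def context_class(triplet: str, ref: str, alt: str) -> str:
    """Canonical context class for a single-base substitution.

    ``triplet`` is the reference triplet centered on the mutated base, on
    either strand; purine-reference sites are reverse-complemented so the
    result is always one of the 96 pyrimidine-centered classes.

    >>> context_class("ACG", "C", "T")
    'A[C>T]G'
    >>> context_class("TGA", "G", "A")
    'T[C>T]A'
    """
    triplet = triplet.upper()
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        raise AnnotationError(f"context classes are defined for SNVs only: {ref}>{alt}")
    if len(triplet) != 3 or triplet[1] != ref:
        raise AnnotationError(
            f"triplet {triplet!r} does not have reference base {ref!r} at its center"
        )
    if ref in "GA":
        triplet, ref, alt = revcomp(triplet), revcomp(ref), revcomp(alt)
    cls = f"{triplet[0]}[{ref}>{alt}]{triplet[2]}"
    if cls not in _CONTEXT_SET:
        raise AnnotationError(f"invalid substitution {ref}>{alt}")
    return cls


_CONTEXT_SET = frozenset(CONTEXT_CLASSES)


def parse_context_class(cls: str) -> tuple[str, str, str]:
    """Split ``"A[C>T]G"`` into (canonical triplet, ref, alt)."""
    if cls not in _CONTEXT_SET:
        raise AnnotationError(f"not a canonical context class: {cls!r}")
    return cls[0] + cls[2] + cls[6], cls[2], cls[4]


# ---------------------------------------------------------------------------
# domain types

MUTATION_CLASSES = ("metspec_driver", "metspec_other", "truncal", "background")


@dataclass(frozen=True)
class VariantCall:
    """One UMI-collapsed observation of a candidate variant at a site.

    ``mt_alt``/``mt_total`` are molecular-tag (unique pre-amplification
    molecule) counts; ``called`` records whether the observation passed the
    upstream caller's thresholds.
    """

    patient_id: str
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mt_alt: int
    mt_total: int
    called: bool
    vaf: float = float("nan")
    context: str | None = None
    mutation_class: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.mt_total < 1:
            raise ValidationError(f"mt_total must be positive, got {self.mt_total}")
        if not 0 <= self.mt_alt <= self.mt_total:
            raise ValidationError(
                f"mt_alt={self.mt_alt} outside [0, mt_total={self.mt_total}]"
            )
        expected = self.mt_alt / self.mt_total
        if math.isnan(self.vaf):
            object.__setattr__(self, "vaf", expected)
        elif abs(self.vaf - expected) > 1e-6:
            raise ValidationError(
                f"vaf={self.vaf} inconsistent with mt_alt/mt_total={expected:.8f}"
            )
        if self.mutation_class is not None and self.mutation_class not in MUTATION_CLASSES:
            raise ValidationError(f"unknown mutation_class {self.mutation_class!r}")


@dataclass(frozen=True)
class TumorSample:
    """Block-level sample metadata."""

    patient_id: str
    sample_id: str
    block_id: str
    role: str  # "primary" | "metastasis"
    purity: float
    ploidy: float
    preservation: str  # "FFPE" | "frozen"
    udg_treated: bool
    block_age_years: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ("primary", "metastasis"):
            raise ValidationError(f"role must be primary|metastasis, got {self.role!r}")
        if not 0 < self.purity <= 1:
            raise ValidationError(f"purity must be in (0,1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValidationError(f"ploidy must be > 0, got {self.ploidy}")
        if self.preservation not in ("FFPE", "frozen"):
            raise ValidationError(f"preservation must be FFPE|frozen, got {self.preservation!r}")
        if self.block_age_years is not None and self.block_age_years < 0:
            raise ValidationError("block_age_years must be non-negative")


@dataclass(frozen=True)
class CNSegment:
    """Allele-specific copy-number segment, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"segment start {self.start} > end {self.end}")
        if not 0 <= self.minor_cn <= self.major_cn:
            raise ValidationError(
                f"need major_cn >= minor_cn >= 0, got {self.major_cn}/{self.minor_cn}"
            )

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn


class CNProfile:
    """Point-queryable collection of non-overlapping CN segments."""

    def __init__(self, segments: Iterable[CNSegment]):
        self._by_chrom: dict[str, tuple[list[int], list[CNSegment]]] = {}
        grouped: dict[str, list[CNSegment]] = {}
        for seg in segments:
            grouped.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in grouped.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValidationError(
                        f"overlapping CN segments on {chrom}: "
                        f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                    )
            self._by_chrom[chrom] = ([s.start for s in segs], segs)

    def lookup(self, chrom: str, pos: int) -> CNSegment | None:
        """Covering segment at (chrom, pos), or None when uncovered."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, segs = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and segs[i].start <= pos <= segs[i].end:
            return segs[i]
        return None

    def __iter__(self) -> Iterator[CNSegment]:
        for _, segs in self._by_chrom.values():
            yield from segs

    def __len__(self) -> int:
        return sum(len(segs) for _, segs in self._by_chrom.values())


@dataclass
class RoiPanel:
    """Per-site description of the targeted panel.

    ``sites`` has one row per covered base with columns ``chrom``, ``pos``
    (1-based), ``ref_base`` and ``triplet`` (reference triplet on the
    sequenced strand). ``canonical`` (pyrimidine-centered triplet) is derived
    on construction.
    """

    sites: pd.DataFrame
    depths: Mapping[str, pd.Series] = field(default_factory=dict)  # sample_id -> per-site MT depth

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ref_base", "triplet"}
        missing = required - set(self.sites.columns)
        if missing:
            raise SchemaError(f"ROI site table missing columns: {sorted(missing)}")
        if "canonical" not in self.sites.columns:
            self.sites = self.sites.assign(
                canonical=[canonical_triplet(t) for t in self.sites["triplet"]]
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def covered_sites_per_triplet(self) -> pd.Series:
        """Count of covered sites per canonical pyrimidine triplet (32 bins)."""
        return self.sites["canonical"].value_counts().reindex(CANONICAL_TRIPLETS, fill_value=0)


# ---------------------------------------------------------------------------
# variant tables

REQUIRED_VARIANT_COLUMNS = (
    "patient_id", "sample_id", "chrom", "pos", "ref", "alt",
    "mt_alt", "mt_total", "called",
)
OPTIONAL_VARIANT_COLUMNS = ("vaf", "context", "mutation_class")

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "t": True, "f": False, "yes": True, "no": False}


def _coerce_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    out = series.astype(str).str.strip().str.lower().map(_BOOL_MAP)
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise ValidationError(f"cannot interpret {bad!r} as a boolean in column 'called'")
    return out.astype(bool)


def validate_variant_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an in-memory variant table.

    Enforces the same invariants as :class:`VariantCall` row-wise; raises
    :class:`ValidationError` naming the first offending row (1-based data
    row number).
    """
    missing = [c for c in REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"variant table missing required column(s): {', '.join(missing)}")
    df = df.copy()
    df["pos"] = df["pos"].astype(int)
    df["mt_alt"] = df["mt_alt"].astype(int)
    df["mt_total"] = df["mt_total"].astype(int)
    df["called"] = _coerce_bool(df["called"])

    def _fail(mask: pd.Series, msg: str) -> None:
        if mask.any():
            row = int(mask.to_numpy().nonzero()[0][0]) + 1
            raise ValidationError(f"row {row}: {msg}")

    _fail(df["pos"] < 1, "pos must be >= 1")
    _fail(df["mt_total"] < 1, "mt_total must be positive")
    _fail((df["mt_alt"] < 0) | (df["mt_alt"] > df["mt_total"]),
          "mt_alt outside [0, mt_total]")
    _fail(df["ref"].astype(str) == df["alt"].astype(str), "ref equals alt")

    expected = df["mt_alt"] / df["mt_total"]
    if "vaf" in df.columns and df["vaf"].notna().any():
        df["vaf"] = df["vaf"].astype(float)
        filled = df["vaf"].fillna(expected)
        _fail((filled - expected).abs() > 1e-6, "vaf inconsistent with mt_alt/mt_total")
        df["vaf"] = filled
    else:
        df["vaf"] = expected
    if "mutation_class" in df.columns:
        known = df["mutation_class"].isna() | df["mutation_class"].isin(MUTATION_CLASSES)
        _fail(~known, "unknown mutation_class")
    return df


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV variant table, enforcing the schema and row invariants.

    Extra columns are preserved untouched (supplementary exports carry many);
    the ``vaf`` column is computed when absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "patient_id": str, "sample_id": str})
    try:
        return validate_variant_frame(df)
    except (SchemaError, ValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a variant table as TSV (round-trips with :func:`read_variant_table`)."""
    cols = [c for c in (*REQUIRED_VARIANT_COLUMNS, *OPTIONAL_VARIANT_COLUMNS) if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.12g")


def iter_variant_calls(df: pd.DataFrame) -> Iterator[VariantCall]:
    """Yield :class:`VariantCall` records from a validated variant frame."""
    for row in df.itertuples(index=False):
        yield VariantCall(
            patient_id=str(row.patient_id), sample_id=str(row.sample_id),
            chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref), alt=str(row.alt),
            mt_alt=int(row.mt_alt), mt_total=int(row.mt_total), called=bool(row.called),
            vaf=float(row.vaf),
            context=getattr(row, "context", None) if "context" in df.columns else None,
            mutation_class=(None if "mutation_class" not in df.columns
                            or pd.isna(row.mutation_class) else str(row.mutation_class)),
        )


# ---------------------------------------------------------------------------
# other readers

def read_cn_segments(path: str | Path) -> CNProfile:
    """Read allele-specific copy-number segments from TSV
    (columns: chrom, start, end, major_cn, minor_cn; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("chrom", "start", "end", "major_cn", "minor_cn")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: CN table missing column(s): {', '.join(missing)}")
    segs = [CNSegment(str(r.chrom), int(r.start), int(r.end), int(r.major_cn), int(r.minor_cn))
            for r in df.itertuples(index=False)]
    return CNProfile(segs)


def write_cn_segments(profile: CNProfile, path: str | Path) -> None:
    pd.DataFrame(
        [(s.chrom, s.start, s.end, s.major_cn, s.minor_cn) for s in profile],
        columns=["chrom", "start", "end", "major_cn", "minor_cn"],
    ).to_csv(path, sep="\t", index=False)


def read_roi_bed(path: str | Path) -> pd.DataFrame:
    """Read panel regions from BED (0-based half-open), returning a frame with
    1-based inclusive ``start``/``end`` and a ``length`` column."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start0", "end0"],
                     dtype={0: str})
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start0"].astype(int) + 1,
        "end": df["end0"].astype(int),
    })
    out["length"] = out["end"] - out["start"] + 1
    bad = (out["length"] < 1) | (out["length"] > 10_000)
    if bad.any():
        raise ValidationError(f"{path}: region length outside [1, 10000] at row {bad.idxmax() + 1}")
    return out


def write_roi_bed(regions: pd.DataFrame, path: str | Path) -> None:
    pd.DataFrame({
        "chrom": regions["chrom"],
        "start0": regions["start"].astype(int) - 1,
        "end0": regions["end"].astype(int),
    }).to_csv(path, sep="\t", index=False, header=False)


_SAMPLE_COLUMNS = ("patient_id", "sample_id", "block_id", "role", "purity",
                   "ploidy", "preservation", "udg_treated")


def read_samples(path: str | Path) -> dict[str, TumorSample]:
    """Read sample metadata from TSV or YAML, keyed by sample_id."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            records = yaml.safe_load(fh)
        if isinstance(records, dict):
            records = list(records.values())
    else:
        df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "sample_id": str,
                                                "block_id": str})
        missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: sample table missing column(s): {', '.join(missing)}")
        df["udg_treated"] = _coerce_bool(df["udg_treated"])
        records = df.to_dict("records")
    out: dict[str, TumorSample] = {}
    for rec in records:
        age = rec.get("block_age_years")
        if age is not None and pd.isna(age):
            age = None
        sample = TumorSample(
            patient_id=str(rec["patient_id"]), sample_id=str(rec["sample_id"]),
            block_id=str(rec["block_id"]), role=str(rec["role"]),
            purity=float(rec["purity"]), ploidy=float(rec["ploidy"]),
            preservation=str(rec["preservation"]), udg_treated=bool(rec["udg_treated"]),
            block_age_years=None if age is None else float(age),
        )
        out[sample.sample_id] = sample
    return out


def write_samples(samples: Mapping[str, TumorSample], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in samples.values()]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# context annotation

def annotate_context(df: pd.DataFrame, reference: str | Path | None = None) -> pd.DataFrame:
    """Attach canonical trinucleotide context classes to SNV rows.

    Rows with an existing ``context`` entry are canonicalised in place; the
    remainder are resolved against an indexed FASTA when ``reference`` is
    given. A stated ref base that disagrees with the FASTA raises
    :class:`AnnotationError` listing the site. Non-SNV rows keep a null
    context.
    """
    df = df.copy()
    if "context" not in df.columns:
        df["context"] = pd.Series([None] * len(df), dtype=object)
    fasta = None
    if reference is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(reference))
    contexts: list[str | None] = []
    for i, row in enumerate(df.itertuples(index=False)):
        ref, alt = str(row.ref), str(row.alt)
        if len(ref) != 1 or len(alt) != 1:
            contexts.append(None)
            continue
        existing = getattr(row, "context", None)
        if isinstance(existing, str) and existing:
            if existing in _CONTEXT_SET:
                contexts.append(existing)
            else:
                # raw triplet form: canonicalise
                contexts.append(context_class(existing, ref, alt))
            continue
        if fasta is None:
            raise AnnotationError(
                f"row {i + 1} ({row.chrom}:{row.pos}) has no context and no reference was given"
            )
        pos = int(row.pos)
        triplet = str(fasta[str(row.chrom)][pos - 2:pos + 1]).upper()
        if triplet[1] != ref.upper():
            raise AnnotationError(
                f"reference mismatch at {row.chrom}:{pos}: table says {ref}, FASTA has {triplet[1]}"
            )
        contexts.append(context_class(triplet, ref, alt))
    df["context"] = contexts
    return df


def write_vcf(df: pd.DataFrame, path: str | Path) -> None:
    """Export called variants as a minimal VCF with MT counts in INFO."""
    called = df[df["called"]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MTA,Number=1,Type=Integer,Description="Alt molecular tags">\n')
        fh.write('##INFO=<ID=MTT,Number=1,Type=Integer,Description="Total molecular tags">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in called.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"MTA={row.mt_alt};MTT={row.mt_total}\n"
            )
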