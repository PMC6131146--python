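"""Readers and writers for the pipeline's external formats.

Internal coordinates are 0-based half-open everywhere; conversions happen at
the boundary only (SEG is 1-based inclusive, VCF POS is 1-based).

Formats
-------
* segment tables: BED (``chrom start end state``) and SEG-like TSV
  (``sample chrom start end state log_ratio [copy_number]``)
* somatic calls: a VCF v4.2 subset with TUMOR/NORMAL sample columns carrying
  ``DP``/``AD``/``ADF``/``ADR`` and per-alt ``MBQ`` (mean base quality) and
  ``CSQCLASS`` (consequence class) INFO fields
* a sample-sheet TSV describing patients, lesions and sampling times
* the longitudinal fixture transcribed from the published per-sample table
  of the sarcoma cohort (``ND`` = not done, distinct from 0)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam

from .genome import HG19_AUTOSOMES
from .intervals import GenomicInterval, SegmentProfile, STATES
from .variants import CONSEQUENCES, VariantRecord

LESION_TYPES = ("PT", "LR", "Met")
DIAGNOSIS_GROUPS = ("WDLS", "MLS", "CXS")
ASSAYS = ("WES", "SNP", "CA")


@dataclass(frozen=True)
class SampleMeta:
    patient_id: str
    sample_id: str
    lesion_id: str
    lesion_type: str
    months_from_dx: float
    diagnosis_group: str
    assays: tuple[str, ...] = ("WES", "SNP")

    def __post_init__(self):
        if self.lesion_type not in LESION_TYPES:
            raise ValueError(f"lesion_type must be one of {LESION_TYPES}")
        if self.diagnosis_group not in DIAGNOSIS_GROUPS:
            raise ValueError(f"diagnosis_group must be one of {DIAGNOSIS_GROUPS}")
        if self.months_from_dx < 0:
            raise ValueError("months_from_dx must be non-negative")
        if self.lesion_type == "PT" and self.months_from_dx != 0:
            raise ValueError("primary tumor must have months_from_dx == 0")
        bad = set(self.assays) - set(ASSAYS)
        if bad:
            raise ValueError(f"unknown assays {sorted(bad)}")


@dataclass(frozen=True)
class CytoSummary:
    """Per-cell cytogenetic counts for one sample (or pooled samples)."""

    cells_assessed: int
    cells_nonclonal_structural: int = 0
    cells_deviating_stemline_count: int = 0

    def __post_init__(self):
        if self.cells_assessed < 0:
            raise ValueError("cells_assessed must be non-negative")
        if not (0 <= self.cells_nonclonal_structural <= self.cells_assessed):
            raise ValueError("cells_nonclonal_structural exceeds cells_assessed")
        if not (0 <= self.cells_deviating_stemline_count <= self.cells_assessed):
            raise ValueError("cells_deviating_stemline_count exceeds cells_assessed")


@dataclass
class Lesion:
    """One anatomical lesion with its samples and attached per-sample data."""

    lesion_id: str
    lesion_type: str
    months_from_dx: float
    samples: list[SampleMeta] = field(default_factory=list)
    segments: dict[str, SegmentProfile] = field(default_factory=dict)
    variants: dict[str, list[VariantRecord]] = field(default_factory=dict)
    cyto: dict[str, CytoSummary] = field(default_factory=dict)


@dataclass
class PatientHistory:
    """A patient's lesions in chronological order (PT first)."""

    patient_id: str
    lesions: list[Lesion] = field(default_factory=list)
    has_pt: bool = True

    def lesion(self, lesion_id: str) -> Lesion:
        for l in self.lesions:
            if l.lesion_id == lesion_id:
                return l
        raise KeyError(f"no lesion {lesion_id!r} in patient {self.patient_id}")


# ---------------------------------------------------------------------------
# segment tables

def read_segments(path, dialect: str = "SEG",
                  sample_id: Optional[str] = None) -> SegmentProfile:
    """Read a BED or SEG segment table into a (normalised) SegmentProfile.

    BED rows are native 0-based half-open; SEG rows are 1-based inclusive and
    converted on the way in.
    """
    dialect = dialect.upper()
    if dialect not in ("SEG", "BED"):
        raise ValueError(f"dialect must be 'SEG' or 'BED', got {dialect!r}")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    seen_sample = sample_id
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "BED":
                    chrom, start, end, state = fields[0], int(fields[1]), int(fields[2]), fields[3]
                    cn = float(fields[4]) if len(fields) > 4 and fields[4] != "" else None
                else:
                    if lineno == 1 and not fields[2].lstrip("-").isdigit():
                        continue  # header row
                    sample, chrom = fields[0], fields[1]
                    start, end = int(fields[2]) - 1, int(fields[3])
                    state = fields[4]
                    cn = None
                    if len(fields) > 6 and fields[6] != "":
                        cn = float(fields[6])
                    if seen_sample is None:
                        seen_sample = sample
                if state not in STATES:
                    raise ValueError(f"unknown copy-state label {state!r}")
                intervals.append(GenomicInterval(chrom, start, end, state, cn))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    return SegmentProfile(seen_sample or path.stem, tuple(intervals)).normalized()


def write_segments(profile: SegmentProfile, path, dialect: str = "SEG") -> None:
    dialect = dialect.upper()
    lines = []
    if dialect == "SEG":
        lines.append("sample\tchrom\tstart\tend\tstate\tlog_ratio\tcopy_number")
    for iv in sorted(profile.intervals):
        if dialect == "BED":
            cn = "" if iv.copy_number is None else repr(iv.copy_number)
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.state}\t{cn}")
        elif dialect == "SEG":
            lr = "" if iv.copy_number in (None, 0) else \
                f"{math.log2(iv.copy_number / 2):.4f}" if iv.copy_number > 0 else ""
            cn = "" if iv.copy_number is None else repr(iv.copy_number)
            lines.append(f"{profile.sample_id}\t{iv.chrom}\t{iv.start + 1}\t"
                         f"{iv.end}\t{iv.state}\t{lr}\t{cn}")
        else:
            raise ValueError(f"dialect must be 'SEG' or 'BED', got {dialect!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER_TEMPLATE = """##fileformat=VCFv4.2
{contigs}##patient={patient}
##tumor_sample_name={sample}
##INFO=<ID=MBQ,Number=A,Type=Float,Description="Mean base quality of reads supporting the alt allele">
##INFO=<ID=CSQCLASS,Number=A,Type=String,Description="Consequence class">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="Allele depths, forward strand">
##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="Allele depths, reverse strand">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
"""


def write_variants(records: Iterable[VariantRecord], path,
                   contigs: Optional[dict[str, int]] = None) -> None:
    """Write one sample's call records as an uncompressed VCF v4.2 subset."""
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    if not records:
        raise ValueError("refusing to write a VCF with no records")
    sample_ids = {r.sample_id for r in records}
    patient_ids = {r.patient_id for r in records}
    if len(sample_ids) != 1 or len(patient_ids) != 1:
        raise ValueError("write_variants expects records from exactly one sample")
    contigs = contigs or HG19_AUTOSOMES
    contig_lines = "".join(f"##contig=<ID={c},length={l}>\n"
                           for c, l in contigs.items())
    out = [_VCF_HEADER_TEMPLATE.format(contigs=contig_lines,
                                       patient=patient_ids.pop(),
                                       sample=sample_ids.pop()).rstrip("\n")]
    for r in records:
        t_ref_f = (r.tumor_depth - r.tumor_alt) // 2
        t_ref_r = r.tumor_depth - r.tumor_alt - t_ref_f
        info = f"MBQ={r.mean_base_quality:.2f};CSQCLASS={r.consequence}"
        tumor = (f"{r.tumor_depth}:{r.tumor_depth - r.tumor_alt},{r.tumor_alt}:"
                 f"{t_ref_f},{r.tumor_alt_fwd}:{t_ref_r},{r.tumor_alt_rev}")
        n_ref = r.normal_depth - r.normal_alt
        n_alt_f = r.normal_alt // 2
        normal = (f"{r.normal_depth}:{n_ref},{r.normal_alt}:"
                  f"{n_ref // 2},{n_alt_f}:{n_ref - n_ref // 2},{r.normal_alt - n_alt_f}")
        out.append(f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                   f"{info}\tDP:AD:ADF:ADR\t{tumor}\t{normal}")
    Path(path).write_text("\n".join(out) + "\n")


def read_variants(path, sample_id: Optional[str] = None,
                  patient_id: Optional[str] = None) -> list[VariantRecord]:
    """Read a VCF v4.2 subset into VariantRecords (multiallelic rows split).

    Requires TUMOR and NORMAL sample columns with DP/AD/ADF/ADR and per-alt
    MBQ and CSQCLASS INFO fields; a missing field raises an error naming it.
    """
    if sample_id is None or patient_id is None:
        with open(path) as fh:
            for line in fh:
                if not line.startswith("##"):
                    break
                if line.startswith("##patient=") and patient_id is None:
                    patient_id = line.strip().split("=", 1)[1]
                if line.startswith("##tumor_sample_name=") and sample_id is None:
                    sample_id = line.strip().split("=", 1)[1]
    if sample_id is None or patient_id is None:
        raise ValueError("sample_id/patient_id not given and not found in header")

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        names = list(vcf.header.samples)
        for need in ("TUMOR", "NORMAL"):
            if need not in names:
                raise ValueError(f"VCF is missing required sample column {need!r}")
        for rec in vcf:
            tumor, normal = rec.samples["TUMOR"], rec.samples["NORMAL"]
            for fmt in ("DP", "AD", "ADF", "ADR"):
                if tumor.get(fmt) is None:
                    raise ValueError(f"record {rec.chrom}:{rec.pos} missing FORMAT field {fmt!r}")
            for info in ("MBQ", "CSQCLASS"):
                if info not in rec.info:
                    raise ValueError(f"record {rec.chrom}:{rec.pos} missing INFO field {info!r}")
            mbq = rec.info["MBQ"]
            csq = rec.info["CSQCLASS"]
            if isinstance(csq, str):
                csq = (csq,)
            for i, alt in enumerate(rec.alts or ()):
                records.append(VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.start,  # 0-based
                    ref=rec.ref,
                    alt=alt,
                    tumor_depth=int(tumor["DP"]),
                    normal_depth=int(normal["DP"]),
                    tumor_alt_fwd=int(tumor["ADF"][i + 1]),
                    tumor_alt_rev=int(tumor["ADR"][i + 1]),
                    normal_alt=int(normal["AD"][i + 1]),
                    # MBQ is serialised at 2 dp; undo float32 widening
                    mean_base_quality=round(float(mbq[i]), 2),
                    consequence=str(csq[i]),
                    sample_id=sample_id,
                    patient_id=patient_id,
                ))
    return records


# ---------------------------------------------------------------------------
# sample sheet

SHEET_COLUMNS = ["patient_id", "sample_id", "lesion_id", "lesion_type",
                 "months_from_dx", "diagnosis_group", "assays"]


def write_sample_sheet(samples: Iterable[SampleMeta], path) -> None:
    rows = [{**{c: getattr(s, c) for c in SHEET_COLUMNS[:-1]},
             "assays": ",".join(s.assays)} for s in samples]
    pd.DataFrame(rows, columns=SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> list[PatientHistory]:
    """Read a sample-sheet TSV into chronologically ordered patient histories.

    Rows may arrive in any order. A duplicate (patient_id, sample_id) is an
    error; a patient without a PT is admitted with ``has_pt=False`` so that
    analyses requiring a primary can refuse.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    if df.duplicated(subset=["patient_id", "sample_id"]).any():
        dup = df[df.duplicated(subset=["patient_id", "sample_id"])].iloc[0]
        raise ValueError(f"duplicate sample id {dup.sample_id!r} "
                         f"for patient {dup.patient_id!r}")
    histories: list[PatientHistory] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        lesions: dict[str, Lesion] = {}
        for _, row in grp.iterrows():
            meta = SampleMeta(
                patient_id=pid, sample_id=row.sample_id,
                lesion_id=row.lesion_id, lesion_type=row.lesion_type,
                months_from_dx=float(row.months_from_dx),
                diagnosis_group=row.diagnosis_group,
                assays=tuple(a for a in str(row.assays).split(",") if a),
            )
            lesion = lesions.setdefault(row.lesion_id, Lesion(
                row.lesion_id, row.lesion_type, meta.months_from_dx))
            lesion.samples.append(meta)
        ordered = sorted(lesions.values(), key=lambda l: (l.months_from_dx, l.lesion_id))
        has_pt = any(l.lesion_type == "PT" for l in ordered)
        if not has_pt:
            import warnings
            warnings.warn(f"patient {pid} has no primary tumor sample",
                          stacklevel=2)
        histories.append(PatientHistory(pid, ordered, has_pt=has_pt))
    return histories


# ---------------------------------------------------------------------------
# in-package longitudinal cohort fixture

def load_table1() -> pd.DataFrame:
    """The packaged per-sample cohort table (20 sarcoma patients).

    Columns ``esv``/``gcs`` are numeric with ND (not done) as NaN; ``gband``
    stays a string because some entries are censored (">10") or not
    assessable ("NA").
    """
    with resources.files("sarclone.data").joinpath("table1.tsv").open() as fh:
        # keep "NA"/"ND" literal; only ND in numeric columns becomes missing
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    for col in ("esv", "gcs"):
        df[col] = pd.to_numeric(df[col].replace({"ND": None}), errors="raise")
    df["months"] = pd.to_numeric(df["months"])
    df["case"] = df["case"].astype(int)
    return df
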