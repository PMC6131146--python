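"""Cohort summaries and plain-text/TSV reports.

``summarize_groups`` reproduces the per-diagnosis-group medians and ranges of
mutation burdens (ESV per sample, GCS per sample, GCS per lesion) from a
per-sample table — either the packaged cohort fixture or pipeline output.
``render_report`` writes a deterministic TSV + human-readable summary per
patient: lesion timeline, pairwise similarity, trunk counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .metrics import ComparisonResult
from .variants import VariantKey

#: metric name -> (value column, unit column used to form one observation)
_METRICS = {
    "esv_per_sample": ("esv", "sample_id"),
    "gcs_per_sample": ("gcs", "sample_id"),
    "gcs_per_lesion": ("gcs", "lesion"),
}


@dataclass(frozen=True)
class GroupSummary:
    group: str
    metric: str
    median: float
    min: float
    max: float
    n: int
    n_missing: int


def summarize_groups(table: pd.DataFrame,
                     metrics: Iterable[str] = tuple(_METRICS)) -> list[GroupSummary]:
    """Median / min / max / n per diagnosis group for each burden metric.

    ``table`` needs columns ``group``, ``sample_id`` and the metric value
    columns (``esv``, ``gcs``) with missing values (ND) as NaN — the layout of
    :func:`sarclone.io.load_table1`. Per-lesion metrics additionally need a
    ``lesion`` column (with ``case`` to disambiguate patients); the lesion
    value is the median over its samples. Medians use the midpoint of the two
    central order statistics for even n; missing values are excluded, and an
    all-missing metric is reported as absent rather than zero.
    """
    out: list[GroupSummary] = []
    for metric in metrics:
        col, unit = _METRICS[metric]
        if col not in table.columns:
            continue
        for group, grp in table.groupby("group", sort=True):
            if unit == "lesion" and "lesion" in grp.columns:
                keys = ["case", "lesion"] if "case" in grp.columns else ["lesion"]
                values = grp.groupby(keys)[col].median()
            else:
                values = grp[col]
            n_missing = int(values.isna().sum())
            values = values.dropna()
            if values.empty:
                continue
            out.append(GroupSummary(
                group=str(group), metric=metric,
                median=float(values.median()),
                min=float(values.min()), max=float(values.max()),
                n=int(values.size), n_missing=n_missing))
    return out


def summaries_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries],
                        columns=["group", "metric", "median", "min", "max",
                                 "n", "n_missing"])


@dataclass
class PatientReport:
    """Everything the text/TSV report prints for one patient."""

    patient_id: str
    timeline: list[tuple[str, str, float]]  # (lesion_id, type, months)
    comparisons: list[ComparisonResult]
    trunk_classification: Optional[Mapping[VariantKey, str]] = None

    def trunk_counts(self) -> dict[str, int]:
        counts = {"trunk": 0, "shared": 0, "private": 0}
        for label in (self.trunk_classification or {}).values():
            counts[label] += 1
        return counts


def build_patient_report(patient_id: str,
                         lesions: Sequence[tuple[str, str, float]],
                         segments: Mapping[str, "object"],
                         lesion_variants: Mapping[str, set[VariantKey]],
                         tolerance: Optional[int] = None) -> PatientReport:
    """Assemble the pairwise comparisons + trunk classes for one patient.

    ``lesions`` is (lesion_id, lesion_type, months) in chronological order;
    ``segments`` maps lesion_id to a SegmentProfile (may be missing entries);
    ``lesion_variants`` maps lesion_id to its kept variant identity set.
    """
    from .metrics import classify_trunk, compare_pair

    comparisons = []
    ids = [l[0] for l in lesions]
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            comparisons.append(compare_pair(
                a, b, segments.get(a), segments.get(b),
                lesion_variants.get(a), lesion_variants.get(b),
                tolerance=tolerance))
    trunk = None
    with_vars = {l: v for l, v in lesion_variants.items() if v is not None}
    if len(with_vars) >= 2:
        trunk = classify_trunk(with_vars)
    return PatientReport(patient_id, list(lesions), comparisons, trunk)


def render_report(reports: Sequence[PatientReport], outdir,
                  group_summaries: Sequence[GroupSummary] = ()) -> list[Path]:
    """Write ``comparisons.tsv``, ``trunk.tsv``, ``groups.tsv``, ``summary.txt``.

    Output is deterministic: rerunning on identical inputs reproduces the
    files byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comp_rows, trunk_rows = [], []
    for rep in sorted(reports, key=lambda r: r.patient_id):
        for c in rep.comparisons:
            comp_rows.append({
                "patient": rep.patient_id,
                "a": c.sample_pair[0], "b": c.sample_pair[1],
                "jaccard": round(c.jaccard, 6),
                "shared_breakpoints": c.shared_breakpoint_count,
                "shared_bp_fraction_a": round(c.shared_breakpoint_fraction_a, 6),
                "shared_bp_fraction_b": round(c.shared_breakpoint_fraction_b, 6),
                "shared_esv": len(c.shared_esv),
                "private_esv_a": len(c.private_esv_a),
                "private_esv_b": len(c.private_esv_b),
            })
        for key, label in sorted((rep.trunk_classification or {}).items()):
            trunk_rows.append({
                "patient": rep.patient_id,
                "variant": f"{key[0]}:{key[1]}:{key[2]}:{key[3]}",
                "class": label,
            })
    comp_cols = ["patient", "a", "b", "jaccard", "shared_breakpoints",
                 "shared_bp_fraction_a", "shared_bp_fraction_b",
                 "shared_esv", "private_esv_a", "private_esv_b"]
    trunk_cols = ["patient", "variant", "class"]
    files = []
    p = outdir / "comparisons.tsv"
    pd.DataFrame(comp_rows, columns=comp_cols).to_csv(p, sep="\t", index=False)
    files.append(p)
    p = outdir / "trunk.tsv"
    pd.DataFrame(trunk_rows, columns=trunk_cols).to_csv(p, sep="\t", index=False)
    files.append(p)
    p = outdir / "groups.tsv"
    summaries_frame(list(group_summaries)).to_csv(p, sep="\t", index=False)
    files.append(p)

    lines = ["sarclone patient report", "======================="]
    for rep in sorted(reports, key=lambda r: r.patient_id):
        lines.append("")
        lines.append(f"Patient {rep.patient_id}")
        for lid, ltype, months in rep.timeline:
            lines.append(f"  {lid:<8s} {ltype:<4s} {months:g} months")
        tc = rep.trunk_counts()
        if rep.trunk_classification is not None:
            lines.append(f"  variants: {tc['trunk']} trunk, {tc['shared']} shared, "
                         f"{tc['private']} private")
        for c in rep.comparisons:
            lines.append(f"  {c.sample_pair[0]} vs {c.sample_pair[1]}: "
                         f"Jaccard {c.jaccard:.3f}, "
                         f"{c.shared_breakpoint_count} shared breakpoints, "
                         f"{len(c.shared_esv)} shared ESV")
    p = outdir / "summary.txt"
    p.write_text("\n".join(lines) + "\n")
    files.append(p)
    return files
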