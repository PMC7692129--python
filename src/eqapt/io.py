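"""Readers and writers for designs, submissions and interval files.

Canonical interchange formats:

* benchmark design — one YAML document (documented in the README);
* participant submissions — UTF-8 tab-separated table, one row per reported
  variant per replicate, with a permissive header (common synonyms such as
  ``lab``/``vaf``/``coverage`` are accepted);
* replicate validity — small TSV of explicitly invalidated replicates;
* ROI and panel intervals — BED3+ (0-based half-open).
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Union

import pandas as pd
import yaml

from .schemas import (
    BenchmarkDesign,
    GenomicInterval,
    ReplicateStatus,
    ReportedVariant,
)

PathLike = Union[str, os.PathLike]

SUBMISSION_COLUMNS = [
    "participant", "sample_id", "replicate", "gene", "chrom", "pos",
    "ref_nt", "obs_nt", "c_hgvs", "transcript", "p_hgvs", "protein_ref",
    "variant_type", "interpretation", "af", "depth",
]

# Header synonyms seen in the wild; maps lower-cased alias -> canonical name.
_HEADER_SYNONYMS = {
    "lab": "participant", "laboratory": "participant", "lab_id": "participant",
    "sample": "sample_id", "rep": "replicate", "triplicate": "replicate",
    "chromosome": "chrom", "chr": "chrom", "position": "pos",
    "ref": "ref_nt", "obs": "obs_nt", "alt": "obs_nt", "reference": "ref_nt",
    "observed": "obs_nt", "nm": "transcript", "np": "protein_ref",
    "p_hgvs_raw": "p_hgvs", "protein_hgvs": "p_hgvs", "dna_hgvs": "c_hgvs",
    "allelic_frequency": "af", "allele_frequency": "af", "vaf": "af",
    "frequency": "af", "coverage": "depth", "read_coverage": "depth",
    "type": "variant_type",
}


class SubmissionFormatError(ValueError):
    """A submission table violates the documented schema."""


def read_design(path: PathLike) -> BenchmarkDesign:
    """Load and validate a benchmark design from its YAML document."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"design file {path} is not a mapping")
    return BenchmarkDesign.model_validate(raw)


def write_design(design: BenchmarkDesign, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(design.model_dump(mode="json"), fh, sort_keys=False)


def _canonical_header(columns: Iterable[str]) -> dict[str, str]:
    mapping = {}
    for col in columns:
        norm = col.strip().lower().replace(" ", "_")
        mapping[col] = _HEADER_SYNONYMS.get(norm, norm)
    return mapping


def read_submissions(
    path: PathLike,
    statuses_path: Optional[PathLike] = None,
    design: Optional[BenchmarkDesign] = None,
) -> tuple[list[ReportedVariant], list[ReplicateStatus]]:
    """Read a participant-submission table (and optional replicate statuses).

    Missing replicate rows are tolerated: absence means nothing was
    reported. When a design is given, sample identifiers are checked
    against it. Row-level problems raise with the 1-based line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return [], _read_statuses(statuses_path)
    if df.empty:
        return [], _read_statuses(statuses_path)
    df = df.rename(columns=_canonical_header(df.columns))
    missing = {"participant", "sample_id", "replicate", "gene", "af"} - set(df.columns)
    if missing:
        raise SubmissionFormatError(f"missing required columns: {sorted(missing)}")

    known_samples = {s.sample_id for s in design.samples} if design else None
    reports: list[ReportedVariant] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        payload = {k: row[k] for k in df.columns if k in SUBMISSION_COLUMNS and row[k] != ""}
        payload.setdefault("variant_type", "other")
        payload["p_hgvs_raw"] = payload.pop("p_hgvs", "")
        try:
            rv = ReportedVariant.model_validate(payload)
        except Exception as exc:
            raise SubmissionFormatError(f"line {line}: {exc}") from exc
        if known_samples is not None and rv.sample_id not in known_samples:
            raise SubmissionFormatError(
                f"line {line}: unknown sample_id {rv.sample_id!r}"
            )
        reports.append(rv)
    return reports, _read_statuses(statuses_path)


def _read_statuses(path: Optional[PathLike]) -> list[ReplicateStatus]:
    if path is None:
        return []
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            ReplicateStatus(
                participant=row["participant"],
                sample_id=row["sample_id"],
                replicate=int(row["replicate"]),
                valid=str(row.get("valid", "true")).strip().lower()
                in ("1", "true", "yes"),
                reason=row.get("reason") or None,
            )
        )
    return out


def write_submissions(
    reports: list[ReportedVariant],
    path: PathLike,
    statuses: Optional[list[ReplicateStatus]] = None,
    statuses_path: Optional[PathLike] = None,
) -> None:
    rows = []
    for rv in reports:
        d = rv.model_dump(mode="json")
        d["p_hgvs"] = d.pop("p_hgvs_raw")
        rows.append({c: ("" if d.get(c) is None else d.get(c, "")) for c in SUBMISSION_COLUMNS})
    pd.DataFrame(rows, columns=SUBMISSION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )
    if statuses_path is not None:
        srows = [s.model_dump(mode="json") for s in (statuses or [])]
        pd.DataFrame(
            srows, columns=["participant", "sample_id", "replicate", "valid", "reason"]
        ).to_csv(statuses_path, sep="\t", index=False)


def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read BED3+ intervals, returned sorted per chromosome then start."""
    intervals: list[GenomicInterval] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 and fields[3] else None
            intervals.append(
                GenomicInterval(chrom=chrom, start=start, end=end, name=name)
            )
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals: list[GenomicInterval], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            name = f"\t{iv.name}" if iv.name else ""
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{name}\n")
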