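"""Reconstruction of the three 2017-2018 Belgian benchmark rounds.

The published global report prints only anonymized marginals: per-variant
MAF/SD, Z-citation counts over allocated reporters, per-variant success
counts, the per-participant success-rate stratification, masking totals and
the false-negative cause tally. This module rebuilds full synthetic
submissions whose pipeline evaluation reproduces every one of those
marginals exactly. Lab-level assignment of misses, masks and citations is
not recoverable from the anonymized report, so it is fixed
deterministically: masked observations and misses go to the
lexicographically last laboratories (consistent with the stratification),
citations to the first reporting laboratories. All aggregates are invariant
to that choice.

Allele frequencies are planted so the trimmed statistics come out exactly
at the printed values: non-cited reporters sit on a symmetric evenly-spaced
grid around the printed MAF rescaled to the printed SD; cited laboratories
sit on a graded ladder of extreme values that iterative Grubbs trimming
peels off one at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .evaluation import Annotations
from .nomenclature import key_for, parse_protein_hgvs
from .schemas import (
    BenchmarkDesign,
    Enrichment,
    GenomicInterval,
    LabPolicy,
    Origin,
    OrderedVariant,
    PanelDefinition,
    ReplicateStatus,
    ReportedVariant,
    SampleSpec,
    Validation,
)
from .simulate import CASSETTE_LENGTH, Dialect, _variant_type, render_dialect
from .stats import AllocationMode

BENCHMARKS = ("2017/1", "2017/2", "2018/1")

_CHROM = {
    "BRAF": "chr7", "KRAS": "chr12", "NRAS": "chr1", "EGFR": "chr7",
    "TP53": "chr17", "KIT": "chr4", "IDH1": "chr2", "IDH2": "chr15",
    "FLT3": "chr13", "JAK2": "chr9", "SF3B1": "chr2", "TET2": "chr4",
    "ASXL1": "chr20", "BRCA1": "chr17", "BRCA2": "chr13",
}
_BASE = {g: 10_000_000 + 1_000_000 * i for i, g in enumerate(_CHROM)}
_NM = {
    "BRAF": "NM_004333.4", "KRAS": "NM_033360.3", "NRAS": "NM_002524.4",
    "EGFR": "NM_005228.4", "TP53": "NM_000546.5", "KIT": "NM_000222.2",
    "IDH1": "NM_005896.3", "IDH2": "NM_002168.3", "FLT3": "NM_004119.2",
    "JAK2": "NM_004972.3", "SF3B1": "NM_012433.3", "TET2": "NM_001127208.2",
    "ASXL1": "NM_015338.5", "BRCA1": "NM_007294.3", "BRCA2": "NM_000059.3",
}


@dataclass(frozen=True)
class _Row:
    """One printed per-variant result row."""

    sample: str
    gene: str
    p_hgvs: str
    maf: float
    sd: float
    cited: int
    reporters: int          # == Z denominator in global mode, success numerator
    inserted: bool = False
    evaluative: bool = True
    validation: Validation = Validation.DDPCR
    was_ordered: bool = True
    missing_labs: tuple[str, ...] = ()   # labs that did not report (incl. masked)
    masked_labs: tuple[str, ...] = ()    # subset of missing_labs


# --- benchmark 2017/1: solid tumors, 16 participants, global Z mode --------
_L = [f"L{i:02d}" for i in range(1, 17)]
_ROWS_2017_1 = [
    _Row("NGS-2017-001", "BRAF", "p.(Val600Glu)", 13.21, 0.60, 1, 16),
    _Row("NGS-2017-001", "KRAS", "p.(Gly13Asp)", 32.94, 0.64, 1, 16),
    _Row("NGS-2017-001", "NRAS", "p.(Gln61Lys)", 21.55, 1.17, 1, 16,
         validation=Validation.WES, was_ordered=False),
    _Row("NGS-2017-002", "BRAF", "p.(Val600Arg)", 11.26, 1.13, 1, 16),
    _Row("NGS-2017-002", "KRAS", "p.(Ala146Thr)", 20.07, 2.31, 3, 15,
         inserted=True, missing_labs=("L16",), masked_labs=("L16",)),
    _Row("NGS-2017-002", "NRAS", "p.(Gly12Asp)", 19.42, 2.24, 1, 16),
    _Row("NGS-2017-003", "BRAF", "p.(Val600Lys)", 48.50, 2.95, 0, 16),
    _Row("NGS-2017-003", "EGFR", "p.(Glu746-Ala750del)", 35.70, 2.89, 2, 15,
         missing_labs=("L10",)),
    _Row("NGS-2017-003", "EGFR", "p.(Gly719Ser)", 11.10, 1.38, 1, 15,
         validation=Validation.WES, was_ordered=False, missing_labs=("L14",)),
    _Row("NGS-2017-003", "KRAS", "p.(Gly12Ala)", 18.24, 1.36, 1, 15,
         inserted=True, missing_labs=("L16",), masked_labs=("L16",)),
    _Row("NGS-2017-004", "BRAF", "p.(Val600Met)", 19.73, 0.83, 2, 16),
    _Row("NGS-2017-004", "EGFR", "p.(Gly719Ser)", 3.73, 0.50, 0, 12,
         missing_labs=("L11", "L12", "L13", "L14")),
    _Row("NGS-2017-004", "EGFR", "p.(Leu858Arg)", 38.13, 0.96, 1, 16,
         validation=Validation.WES, was_ordered=False),
    _Row("NGS-2017-004", "EGFR", "p.(Thr790Met)", 38.00, 1.10, 3, 16,
         validation=Validation.WES, was_ordered=False),
    _Row("NGS-2017-004", "KRAS", "p.(Gly12Cys)", 5.16, 0.42, 1, 15,
         inserted=True, missing_labs=("L15",), masked_labs=("L15",)),
    _Row("NGS-2017-004", "KRAS", "p.(Gly13Asp)", 29.07, 0.95, 0, 16),
]

# --- benchmark 2017/2: hematological malignancies, 15 participants ---------
_M = [f"M{i:02d}" for i in range(1, 16)]
_ROWS_2017_2 = [
    _Row("NGS-2017-005", "TP53", "p.(Glu171*)", 34.30, 1.76, 1, 15),
    _Row("NGS-2017-005", "KIT", "p.(Asp816Val)", 19.03, 1.67, 1, 15),
    _Row("NGS-2017-005", "IDH2", "p.(Arg140Gln)", 20.88, 1.11, 3, 15),
    _Row("NGS-2017-005", "IDH1", "p.(Arg132Gly)", 5.30, 0.60, 1, 15),
    _Row("NGS-2017-005", "FLT3", "p.(Asp835Tyr)", 11.46, 0.86, 1, 14,
         inserted=True, missing_labs=("M15",), masked_labs=("M15",)),
    _Row("NGS-2017-006", "JAK2", "p.(Val617Phe)", 21.00, 0.87, 2, 15),
    _Row("NGS-2017-006", "IDH2", "p.(Arg172Ser)", 30.95, 0.83, 1, 14,
         missing_labs=("M09",)),
    _Row("NGS-2017-006", "IDH1", "p.(Arg132Ser)", 11.05, 1.12, 1, 14,
         missing_labs=("M10",)),
    _Row("NGS-2017-006", "SF3B1", "p.(Lys700Glu)", 10.65, 1.24, 2, 12,
         inserted=True, missing_labs=("M12", "M13", "M14"),
         masked_labs=("M13", "M14")),
    _Row("NGS-2017-007", "SF3B1", "p.(Lys666Asn)", 24.76, 2.63, 2, 15,
         inserted=True),
    _Row("NGS-2017-007", "TP53", "p.(Ala161Asp)", 47.45, 2.73, 2, 14,
         missing_labs=("M12",)),
    _Row("NGS-2017-007", "TP53", "p.(Tyr220Cys)", 5.12, 0.63, 1, 13,
         missing_labs=("M11", "M12")),
    # two of the 29 unvalidated in-ROI extras, carried as informative
    _Row("NGS-2017-005", "TET2", "p.(Ser268*)", 27.00, 1.21, 0, 15,
         evaluative=False, validation=Validation.NONE, was_ordered=False),
    _Row("NGS-2017-005", "ASXL1", "p.(Leu764Tyrfs*8)", 40.20, 0.96, 0, 13,
         evaluative=False, validation=Validation.NONE, was_ordered=False,
         missing_labs=("M14", "M15")),
]

# --- benchmark 2018/1: BRCA1/2, 12 participants, peer-group Z mode ---------
_N = [f"N{i:02d}" for i in range(1, 13)]
_PEER_A = ("N01", "N02", "N03", "N04", "N05", "N06", "N07", "N12")
_PEER_B = ("N08", "N09", "N10", "N11")
_N12_MISSES = ("N12",)
_ROWS_2018_1 = [
    _Row("NGS-2018-001", "BRCA1", "p.(Arg1443*)", 11.0, 0.22, 1, 12,
         validation=Validation.BOTH),
    _Row("NGS-2018-001", "BRCA2", "p.(Asn1784Thrfs*7)", 12.0, 0.13, 1, 11,
         validation=Validation.BOTH, missing_labs=_N12_MISSES),
    _Row("NGS-2018-001", "BRCA2", "p.(Lys1691Asnfs*15)", 13.0, 0.23, 1, 11,
         validation=Validation.BOTH, missing_labs=_N12_MISSES),
    _Row("NGS-2018-002", "BRCA2", "p.(Asn1784Thrfs*7)", 20.7, 0.43, 1, 11,
         validation=Validation.BOTH, missing_labs=_N12_MISSES),
    _Row("NGS-2018-003", "BRCA2", "p.(Asn1784Thrfs*7)", 25.6, 0.61, 0, 11,
         validation=Validation.WES, was_ordered=False, missing_labs=_N12_MISSES),
    _Row("NGS-2018-003", "BRCA2", "p.(Ile2675Aspfs*6)", 24.0, 0.68, 1, 11,
         validation=Validation.WES, was_ordered=False, missing_labs=_N12_MISSES),
    # WES-validated extras below the consensus bar -> informative
    _Row("NGS-2018-002", "BRCA1", "p.(Asp435Tyr)", 30.0, 0.50, 0, 5,
         evaluative=False, validation=Validation.WES, was_ordered=False),
    _Row("NGS-2018-003", "BRCA1", "p.(Asp435Tyr)", 30.0, 0.50, 0, 5,
         evaluative=False, validation=Validation.WES, was_ordered=False),
    # ordered variants never reported by anyone -> not assessed
    _Row("NGS-2018-001", "BRCA1", "p.(Gln356Arg)", 5.0, 0.0, 0, 0,
         validation=Validation.BOTH),
    _Row("NGS-2018-002", "BRCA2", "p.(Thr3033Asnfs*11)", 8.0, 0.0, 0, 0,
         validation=Validation.BOTH),
]

_FIXTURE_TABLES: dict[str, dict] = {
    "2017/1": {
        "labs": _L, "rows": _ROWS_2017_1,
        "samples": ["NGS-2017-001", "NGS-2017-002", "NGS-2017-003", "NGS-2017-004"],
        "accepted": [Validation.DDPCR, Validation.WES, Validation.BOTH],
        "mode": AllocationMode.GLOBAL,
    },
    "2017/2": {
        "labs": _M, "rows": _ROWS_2017_2,
        "samples": ["NGS-2017-005", "NGS-2017-006", "NGS-2017-007"],
        "accepted": [Validation.DDPCR, Validation.BOTH],
        "mode": AllocationMode.GLOBAL,
    },
    "2018/1": {
        "labs": _N, "rows": _ROWS_2018_1,
        "samples": ["NGS-2018-001", "NGS-2018-002", "NGS-2018-003"],
        "accepted": [Validation.DDPCR, Validation.WES, Validation.BOTH],
        "mode": AllocationMode.PEER_GROUP,
    },
}


@dataclass
class FixtureBundle:
    benchmark_id: str
    design: BenchmarkDesign
    reports: list[ReportedVariant]
    statuses: list[ReplicateStatus]
    annotations: Annotations
    mode: AllocationMode
    rows: list[_Row] = field(default_factory=list)


def _position(gene: str, p_hgvs: str) -> int:
    """Deterministic fictional genomic position, unique per protein change.

    Distinct changes at the same codon (Gly12Ala/Cys/Asp) are spread far
    enough apart that their 2 kb cassette footprints never overlap, so a
    spanning amplicon for one variant cannot mask another.
    """
    change = parse_protein_hgvs(p_hgvs)
    alt = (change.alt_residues or (change.fs_new_residue or "Xaa",))[0]
    return _BASE[gene] + 3 * change.ref_residues[0][1] + 3000 * (ord(alt[0]) - 65)


def _planted_values(row: _Row, reporters: list[str],
                    allocated_pool: list[str]) -> dict[str, float]:
    """AF per reporter such that trimmed stats hit the printed MAF/SD.

    The allocated pool (all reporters in global mode, the qualifying peer
    group in peer mode) splits into cited laboratories - planted on a
    ladder of extreme values that sequential Grubbs trimming removes - and
    retained laboratories on a symmetric grid with exact median ``maf`` and
    exact n-1 SD ``sd``. Reporters outside the pool get near-consensus
    values; they enter no statistic.
    """
    cited = allocated_pool[: row.cited]
    retained = [p for p in allocated_pool if p not in cited]
    values: dict[str, float] = {}

    m = len(retained)
    if m <= 1:
        offsets = np.zeros(m)
    else:
        grid = np.linspace(-1.0, 1.0, m)
        s0 = grid.std(ddof=1)
        offsets = grid * (row.sd / s0) if row.sd > 0 else np.zeros(m)
    for lab, off in zip(retained, offsets):
        values[lab] = row.maf + float(off)

    # Cited labs alternate above/below the consensus (several extremes on
    # one side would mask each other in the Grubbs statistic); magnitudes
    # are fractions of the head-room to the [0, 100] AF bounds.
    room_up, room_down = 100.0 - row.maf, row.maf
    plan = [(room_up, 0.9), (-room_down, 0.9), (room_up, 0.5)]
    if row.maf > 50.0:
        plan = [(-room_down, 0.9), (room_up, 0.9), (-room_down, 0.5)]
    for lab, (room, frac) in zip(cited, plan):
        values[lab] = row.maf + room * frac

    outside = [p for p in reporters if p not in allocated_pool]
    for j, lab in enumerate(outside):
        values[lab] = row.maf + ((-1) ** j) * 0.3 * max(row.sd, 0.1)
    return values


def _repeatability_plan(benchmark_id: str) -> dict[tuple[str, str, str], set[int]]:
    """Replicate subsets for the published repeatability narratives."""
    if benchmark_id == "2017/2":
        return {
            ("M01", "NGS-2017-005", "FLT3 p.(Asp835Tyr)"): {1, 2},
            ("M01", "NGS-2017-006", "JAK2 p.(Val617Phe)"): {1, 3},
            ("M01", "NGS-2017-005", "KIT p.(Asp816Val)"): {2},
            ("M02", "NGS-2017-006", "JAK2 p.(Val617Phe)"): {1, 2},
            ("M02", "NGS-2017-006", "SF3B1 p.(Lys700Glu)"): {2, 3},
            ("M02", "NGS-2017-007", "TP53 p.(Tyr220Cys)"): {1, 2},
        }
    if benchmark_id == "2018/1":
        return {
            ("N01", "NGS-2018-001", "BRCA2 p.(Asn1784Thrfs*7)"): {2, 3},
            ("N01", "NGS-2018-001", "BRCA2 p.(Lys1691Asnfs*15)"): {1, 3},
        }
    return {}


def _build_design(benchmark_id: str) -> tuple[BenchmarkDesign, list[_Row]]:
    spec = _FIXTURE_TABLES[benchmark_id]
    labs: list[str] = spec["labs"]
    rows: list[_Row] = spec["rows"]
    samples = [SampleSpec(sample_id=s, replicate_count=3) for s in spec["samples"]]

    variants: list[OrderedVariant] = []
    for row in rows:
        pos = _position(row.gene, row.p_hgvs)
        cassette = (
            GenomicInterval(
                chrom=_CHROM[row.gene],
                start=pos - CASSETTE_LENGTH // 2 - 1,
                end=pos + CASSETTE_LENGTH // 2 - 1,
                name="cassette",
            )
            if row.inserted
            else None
        )
        variants.append(
            OrderedVariant(
                sample_id=row.sample,
                gene=row.gene,
                transcript=_NM[row.gene],
                p_hgvs=row.p_hgvs,
                chrom=_CHROM[row.gene],
                pos=pos,
                expected_af=row.maf,
                validation=row.validation,
                origin=Origin.INSERTED if row.inserted else Origin.ENDOGENOUS,
                cassette=cassette,
                was_ordered=row.was_ordered,
            )
        )

    roi_positions = sorted({(v.chrom, v.pos) for v in variants})
    roi = [
        GenomicInterval(chrom=c, start=p - 51, end=p + 50, name=f"roi_{i}")
        for i, (c, p) in enumerate(roi_positions)
    ]

    if benchmark_id == "2018/1":
        shared = {
            "brca_panel_A": (_PEER_A, Enrichment.AMPLICON),
            "brca_panel_B": (_PEER_B, Enrichment.PROBE),
        }
        panels = {}
        for pid, (members, enrich) in shared.items():
            panel = PanelDefinition(
                panel_id=pid,
                intervals=[
                    GenomicInterval(chrom=v.chrom, start=v.pos - 76, end=v.pos + 75)
                    for v in variants
                ],
                enrichment=enrich,
            )
            for lab in members:
                panels[lab] = panel
    else:
        panels = {}
        for lab in labs:
            intervals = []
            for row, v in zip(rows, variants):
                if lab in row.masked_labs and v.cassette is not None:
                    intervals.append(
                        GenomicInterval(
                            chrom=v.chrom,
                            start=v.cassette.start - 100,
                            end=v.cassette.end + 100,
                            name="amp_spanning",
                        )
                    )
                else:
                    intervals.append(
                        GenomicInterval(chrom=v.chrom, start=v.pos - 76, end=v.pos + 75)
                    )
            panels[lab] = PanelDefinition(
                panel_id=f"panel_{lab}", intervals=intervals,
                enrichment=Enrichment.AMPLICON,
            )

    design = BenchmarkDesign(
        benchmark_id=benchmark_id,
        samples=samples,
        participants=labs,
        ordered_variants=variants,
        roi=roi,
        panels=panels,
        accepted_validation=spec["accepted"],
    )
    return design, rows


def _annotations(benchmark_id: str, design: BenchmarkDesign) -> Annotations:
    ann = Annotations()
    low_lod = {"L11", "L12", "L13"}  # the three LOD-5% labs of the narrative
    for lab in design.participants:
        lod = 5.0
        if lab in ("L14", "N12"):
            lod = 1.0
        panel = design.panels.get(lab)
        ann.policies[lab] = LabPolicy(
            participant=lab, lod_af=lod, lod_depth=100,
            panel_id=panel.panel_id if panel else None,
        )
    if benchmark_id == "2017/1":
        ident = ("L10", "NGS-2017-003", "EGFR p.(Glu746_Ala750del)")
        ann.operator_error.add(ident)
        ann.evidence_in_reads[ident] = True
        for lab in sorted(low_lod):
            ann.evidence_in_reads[(lab, "NGS-2017-004", "EGFR p.(Gly719Ser)")] = True
    if benchmark_id == "2017/2":
        ann.vus_policy.add(("M12", "NGS-2017-007", "TP53 p.(Ala161Asp)"))
    return ann


def table3_fixture(benchmark_id: str) -> FixtureBundle:
    """Full design + submissions whose evaluation reproduces the printed marginals."""
    if benchmark_id not in _FIXTURE_TABLES:
        raise KeyError(f"unknown benchmark {benchmark_id!r}; "
                       f"choose from {sorted(_FIXTURE_TABLES)}")
    design, rows = _build_design(benchmark_id)
    spec = _FIXTURE_TABLES[benchmark_id]
    labs: list[str] = spec["labs"]
    dialects = list(Dialect)
    rep_plan = _repeatability_plan(benchmark_id)

    reports: list[ReportedVariant] = []
    for row, ov in zip(rows, design.ordered_variants):
        key = key_for(ov.gene, ov.p_hgvs)
        if row.missing_labs:
            reporters = [lab for lab in labs if lab not in row.missing_labs]
        else:
            reporters = labs[: row.reporters]
        if benchmark_id == "2018/1":
            pool = [p for p in _PEER_A if p in reporters]
            pool = pool if len(pool) >= design.peer_group_min else []
        else:
            pool = reporters
        values = _planted_values(row, reporters, pool or reporters)
        for lab in reporters:
            reps = rep_plan.get((lab, row.sample, key.label), {1, 2, 3})
            if benchmark_id == "2017/2" and lab == "M03" and row.sample == "NGS-2017-007":
                reps = reps & {1, 2}
            dialect = dialects[labs.index(lab) % len(dialects)]
            for rep in sorted(reps):
                reports.append(
                    ReportedVariant(
                        participant=lab,
                        sample_id=row.sample,
                        replicate=rep,
                        gene=ov.gene,
                        chrom=ov.chrom,
                        pos=ov.pos,
                        ref_nt="A",
                        obs_nt="T",
                        transcript=ov.transcript or "",
                        p_hgvs_raw=render_dialect(ov.p_hgvs, dialect),
                        variant_type=_variant_type(ov.p_hgvs),
                        af=round(values[lab], 4),
                        depth=800 + 7 * labs.index(lab),
                    )
                )

    statuses: list[ReplicateStatus] = []
    if benchmark_id == "2017/2":
        # one participant's third replicate of NGS-2017-007 failed routine QC
        statuses.append(
            ReplicateStatus(participant="M03", sample_id="NGS-2017-007",
                            replicate=3, valid=False, reason="QC fail"))
    if benchmark_id == "2017/1":
        # operator transcription error: the missing EGFR deletion was
        # submitted as a delins by the affected laboratory
        del_variant = next(v for v in design.ordered_variants
                           if v.p_hgvs == "p.(Glu746-Ala750del)")
        for rep in (1, 2, 3):
            reports.append(
                ReportedVariant(
                    participant="L10", sample_id="NGS-2017-003", replicate=rep,
                    gene="EGFR", chrom=del_variant.chrom, pos=del_variant.pos,
                    ref_nt="A", obs_nt="T", transcript=_NM["EGFR"],
                    p_hgvs_raw="p.(Glu746_Ala750delinsIlePro)",
                    variant_type=_variant_type("p.(Glu746_Ala750delinsIlePro)"),
                    af=35.2, depth=900,
                )
            )

    return FixtureBundle(
        benchmark_id=benchmark_id,
        design=design,
        reports=reports,
        statuses=statuses,
        annotations=_annotations(benchmark_id, design),
        mode=spec["mode"],
        rows=rows,
    )
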