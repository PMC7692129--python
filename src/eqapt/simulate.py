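"""Synthetic laboratory cohorts with a planted ground-truth ledger.

The generator emulates what a proficiency-testing round actually receives:
per-replicate variant reports from laboratories that differ in HGVS
dialect, limit of detection (LOD), allele-frequency noise, panel
compatibility with insertion cassettes, and occasional replicate failure.
Every intended outcome is recorded in a ledger so the pipeline's
classifications can be checked against the planted truth.

Defaults mirror the observed cohort: LOD 1-10% AF and 100-1000 reads,
inter-laboratory AF spread of roughly 0.4-3 percentage points, expected
allele frequencies between 5% and 50%, three replicates per sample.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .nomenclature import (
    THREE_TO_ONE,
    ChangeKind,
    ProteinChange,
    canonicalize,
    key_for_ordered,
    parse_protein_hgvs,
)
from .schemas import (
    BenchmarkDesign,
    Enrichment,
    GenomicInterval,
    Origin,
    OrderedVariant,
    PanelDefinition,
    ReplicateStatus,
    ReportedVariant,
    SampleSpec,
    Validation,
    VariantType,
)
from .truth import mask_incompatible

_AA3 = [a for a in THREE_TO_ONE if a != "Ter"]

# (gene, chromosome, fictional locus base) pool for generated designs.
_GENE_POOL = [
    ("BRAF", "chr7", 140_400_000), ("KRAS", "chr12", 25_350_000),
    ("NRAS", "chr1", 115_250_000), ("EGFR", "chr7", 55_200_000),
    ("TP53", "chr17", 7_570_000), ("KIT", "chr4", 55_550_000),
    ("IDH1", "chr2", 209_100_000), ("IDH2", "chr15", 90_620_000),
    ("FLT3", "chr13", 28_570_000), ("JAK2", "chr9", 5_020_000),
    ("SF3B1", "chr2", 198_250_000), ("BRCA1", "chr17", 41_190_000),
    ("BRCA2", "chr13", 32_880_000), ("TET2", "chr4", 106_050_000),
    ("ASXL1", "chr20", 30_940_000), ("RUNX1", "chr21", 36_160_000),
]

CASSETTE_LENGTH = 2000  # ~2 kb insertion construct footprint


class Dialect(str, enum.Enum):
    """Protein-HGVS rendering styles observed across laboratories."""

    CANONICAL = "canonical"            # p.(Val600Arg)
    NO_DOT = "no_dot"                  # p(Val600Arg)
    NO_PARENS = "no_parens"            # p.Val600Arg
    ONE_LETTER = "one_letter"          # p.V600R
    DELINS = "delins"                  # p.Val600delinsArg
    ONE_LETTER_DELINS = "one_letter_delins"  # p.V600delinsR
    HYPHEN_RANGE = "hyphen_range"      # p.(Glu746-Ala750del)


def _one_letter(aa3: str) -> str:
    return THREE_TO_ONE[aa3]


def _render_body(change: ProteinChange, one_letter: bool) -> str:
    conv = _one_letter if one_letter else (lambda a: a)
    star = (lambda a: "*" if a == "Ter" else conv(a))
    refs = change.ref_residues
    if change.kind in (ChangeKind.SUBSTITUTION, ChangeKind.NONSENSE):
        return f"{conv(refs[0][0])}{refs[0][1]}{star(change.alt_residues[0])}"
    if change.kind is ChangeKind.FRAMESHIFT:
        new = conv(change.fs_new_residue) if change.fs_new_residue else ""
        tail = f"fs*{change.fs_term_offset}" if change.fs_term_offset else "fs"
        return f"{conv(refs[0][0])}{refs[0][1]}{new}{tail}"
    span = (
        f"{conv(refs[0][0])}{refs[0][1]}"
        if len(refs) == 1
        else f"{conv(refs[0][0])}{refs[0][1]}_{conv(refs[-1][0])}{refs[-1][1]}"
    )
    alt = "".join(star(a) for a in change.alt_residues)
    op = {
        ChangeKind.DELETION: "del", ChangeKind.DUPLICATION: "dup",
        ChangeKind.INSERTION: "ins", ChangeKind.DELINS: "delins",
    }[change.kind]
    return f"{span}{op}{alt}"


def render_dialect(p_hgvs: str, dialect: Dialect) -> str:
    """Re-render a canonical(izable) protein HGVS string in a lab's dialect.

    Styles that do not apply to a variant kind (a delins rewrite of a
    frameshift, say) degrade to the closest applicable style, as real
    submissions do.
    """
    change = parse_protein_hgvs(p_hgvs)
    is_subst = change.kind in (ChangeKind.SUBSTITUTION, ChangeKind.NONSENSE)
    if dialect is Dialect.CANONICAL:
        return canonicalize(change)
    if dialect is Dialect.NO_DOT:
        return f"p({_render_body(change, one_letter=False)})"
    if dialect is Dialect.NO_PARENS:
        return f"p.{_render_body(change, one_letter=False)}"
    if dialect is Dialect.ONE_LETTER:
        return f"p.{_render_body(change, one_letter=True)}"
    if dialect in (Dialect.DELINS, Dialect.ONE_LETTER_DELINS):
        if not is_subst:
            fallback = dialect is Dialect.ONE_LETTER_DELINS
            return f"p.{_render_body(change, one_letter=fallback)}"
        one = dialect is Dialect.ONE_LETTER_DELINS
        conv = _one_letter if one else (lambda a: a)
        (aa, pos), = change.ref_residues
        alt = change.alt_residues[0]
        alt_s = "*" if alt == "Ter" else conv(alt)
        return f"p.{conv(aa)}{pos}delins{alt_s}"
    if dialect is Dialect.HYPHEN_RANGE:
        body = _render_body(change, one_letter=False)
        return f"p.({body.replace('_', '-')})"
    raise ValueError(dialect)


class LabProfile(BaseModel):
    """Simulation parameters for one synthetic laboratory."""

    participant: str
    lod_af: float = Field(default=5.0, gt=0, le=100)
    lod_depth: int = Field(default=100, ge=0)
    panel_id: Optional[str] = None
    af_noise_sd: float = Field(default=1.0, ge=0)
    af_bias: float = 0.0
    miss_prob: float = Field(default=0.0, ge=0, le=1)
    dialect: Dialect = Dialect.CANONICAL
    replicate_dropout_prob: float = Field(default=0.0, ge=0, le=1)
    vus_policy: bool = False


@dataclass
class PlantedLedger:
    """Ground truth of intended outcomes, keyed like the evaluation output."""

    outcomes: dict[tuple[str, str, str], str] = field(default_factory=dict)
    true_af: dict[tuple[str, str], float] = field(default_factory=dict)


def _random_protein_change(rng: np.random.Generator) -> str:
    kind = rng.choice(["substitution", "nonsense", "frameshift"], p=[0.7, 0.15, 0.15])
    pos = int(rng.integers(30, 900))
    ref = str(rng.choice(_AA3))
    if kind == "substitution":
        alt = str(rng.choice([a for a in _AA3 if a != ref]))
        return f"p.({ref}{pos}{alt})"
    if kind == "nonsense":
        return f"p.({ref}{pos}*)"
    new = str(rng.choice(_AA3))
    return f"p.({ref}{pos}{new}fs*{int(rng.integers(2, 30))})"


def generate_design(
    n_labs: int,
    n_samples: int,
    variants_per_sample: int,
    af_range: tuple[float, float] = (5.0, 50.0),
    inserted_fraction: float = 0.0,
    seed: int = 0,
    benchmark_id: str = "SIM/1",
    spanning: Optional[dict[str, set[int]]] = None,
    replicate_count: int = 3,
) -> BenchmarkDesign:
    """Deterministically generate a benchmark design.

    ``spanning`` optionally maps a participant to catalogue indices of
    inserted variants for which that laboratory's amplicon flanks the
    cassette (the panel-incompatibility failure mode).
    """
    if min(n_labs, n_samples, variants_per_sample) < 1:
        raise ValueError("cohort dimensions must be positive")
    rng = np.random.default_rng(seed)
    labs = [f"LAB{i + 1:02d}" for i in range(n_labs)]
    samples = [
        SampleSpec(sample_id=f"SIM-{i + 1:03d}", cancer_context="synthetic",
                   replicate_count=replicate_count)
        for i in range(n_samples)
    ]
    variants: list[OrderedVariant] = []
    used_pos: set[tuple[str, int]] = set()
    for s_idx, sample in enumerate(samples):
        for v_idx in range(variants_per_sample):
            gene, chrom, base = _GENE_POOL[
                (s_idx * variants_per_sample + v_idx) % len(_GENE_POOL)
            ]
            p_hgvs = _random_protein_change(rng)
            pos = int(base + rng.integers(1, 200_000))
            while (chrom, pos) in used_pos:
                pos += 1
            used_pos.add((chrom, pos))
            inserted = bool(rng.random() < inserted_fraction)
            cassette = (
                GenomicInterval(
                    chrom=chrom,
                    start=pos - CASSETTE_LENGTH // 2 - 1,
                    end=pos + CASSETTE_LENGTH // 2 - 1,
                    name="cassette",
                )
                if inserted
                else None
            )
            variants.append(
                OrderedVariant(
                    sample_id=sample.sample_id,
                    gene=gene,
                    p_hgvs=p_hgvs,
                    chrom=chrom,
                    pos=pos,
                    expected_af=float(np.round(rng.uniform(*af_range), 2)),
                    validation=Validation.DDPCR,
                    origin=Origin.INSERTED if inserted else Origin.ENDOGENOUS,
                    cassette=cassette,
                )
            )
    roi = [
        GenomicInterval(chrom=ov.chrom, start=ov.pos - 51, end=ov.pos + 50,
                        name=f"roi_{i}")
        for i, ov in enumerate(variants)
    ]
    # decoy ROI stretches that contain no truth variant
    roi.append(GenomicInterval(chrom="chr22", start=10_000, end=20_000, name="decoy"))
    spanning = spanning or {}
    panels = {}
    for lab in labs:
        intervals = []
        for i, ov in enumerate(variants):
            if i in spanning.get(lab, set()) and ov.cassette is not None:
                intervals.append(
                    GenomicInterval(
                        chrom=ov.chrom,
                        start=ov.cassette.start - 100,
                        end=ov.cassette.end + 100,
                        name=f"amp_span_{i}",
                    )
                )
            else:
                intervals.append(
                    GenomicInterval(chrom=ov.chrom, start=ov.pos - 76,
                                    end=ov.pos + 75, name=f"amp_{i}")
                )
        panels[lab] = PanelDefinition(
            panel_id=f"panel_{lab}", intervals=intervals,
            enrichment=Enrichment.AMPLICON,
        )
    return BenchmarkDesign(
        benchmark_id=benchmark_id,
        samples=samples,
        participants=labs,
        ordered_variants=variants,
        roi=roi,
        panels=panels,
    )


def default_profiles(
    design: BenchmarkDesign, seed: int = 0, **overrides
) -> dict[str, LabProfile]:
    """Draw a profile per participant from the observed cohort ranges."""
    rng = np.random.default_rng(seed)
    dialects = list(Dialect)
    profiles = {}
    for i, lab in enumerate(design.participants):
        profiles[lab] = LabProfile(
            participant=lab,
            lod_af=float(np.round(rng.uniform(1.0, 10.0), 1)),
            lod_depth=int(rng.integers(100, 1001)),
            panel_id=design.panels[lab].panel_id if lab in design.panels else None,
            af_noise_sd=float(np.round(rng.uniform(0.4, 3.0), 2)),
            dialect=dialects[i % len(dialects)],
            **overrides,
        )
    return profiles


def _variant_type(p_hgvs: str) -> VariantType:
    kind = parse_protein_hgvs(p_hgvs).kind
    return {
        ChangeKind.SUBSTITUTION: VariantType.MISSENSE,
        ChangeKind.NONSENSE: VariantType.NONSENSE,
        ChangeKind.FRAMESHIFT: VariantType.FRAMESHIFT,
    }.get(kind, VariantType.OTHER)


def generate_submissions(
    design: BenchmarkDesign,
    profiles: dict[str, LabProfile],
    seed: int = 0,
) -> tuple[list[ReportedVariant], list[ReplicateStatus], PlantedLedger]:
    """Simulate every laboratory's per-replicate submission.

    Deterministic for identical (design, profiles, seed). A variant drops
    out of a replicate when the panel is cassette-incompatible, when its
    noisy AF falls below the laboratory's LOD, on a whole-variant miss
    (``miss_prob``), or when the entire replicate fails QC
    (``replicate_dropout_prob``, recorded as an invalid replicate).
    """
    missing = [p for p in design.participants if p not in profiles]
    if missing:
        raise ValueError(f"profiles missing for participants: {missing}")
    rng = np.random.default_rng(seed)
    mask = mask_incompatible(design)
    ledger = PlantedLedger()
    reports: list[ReportedVariant] = []
    statuses: list[ReplicateStatus] = []

    for ov in design.ordered_variants:
        ledger.true_af[(ov.sample_id, key_for_ordered(ov).label)] = ov.expected_af

    for lab in design.participants:
        prof = profiles[lab]
        for sample in design.samples:
            n_rep = sample.replicate_count
            dropped = {
                r + 1
                for r in range(n_rep)
                if rng.random() < prof.replicate_dropout_prob
            }
            for r in sorted(dropped):
                statuses.append(
                    ReplicateStatus(
                        participant=lab, sample_id=sample.sample_id, replicate=r,
                        valid=False, reason="simulated QC failure",
                    )
                )
            for ov in design.ordered_variants:
                if ov.sample_id != sample.sample_id:
                    continue
                key = key_for_ordered(ov)
                ident = (lab, sample.sample_id, key.label)
                if mask.is_masked(lab, sample.sample_id, key):
                    ledger.outcomes[ident] = "cassette_incompatibility"
                    continue
                center = ov.expected_af + prof.af_bias
                if center < prof.lod_af:
                    ledger.outcomes[ident] = "below_lod"
                    # censored at zero noise; with noise, replicates may
                    # still sporadically clear the threshold below
                if rng.random() < prof.miss_prob:
                    ledger.outcomes.setdefault(ident, "missed")
                    continue
                reported_any = False
                for rep in range(1, n_rep + 1):
                    if rep in dropped:
                        continue
                    af = center + rng.normal(0.0, prof.af_noise_sd) if prof.af_noise_sd else center
                    af = float(min(100.0, max(0.0, af)))
                    # depth drawn before the LOD gate so the RNG stream is
                    # identical across runs that differ only in lod_af
                    depth = int(rng.integers(max(prof.lod_depth, 100), 5000))
                    if af < prof.lod_af:
                        continue
                    reported_any = True
                    reports.append(
                        ReportedVariant(
                            participant=lab,
                            sample_id=sample.sample_id,
                            replicate=rep,
                            gene=ov.gene,
                            chrom=ov.chrom,
                            pos=ov.pos,
                            ref_nt="A",
                            obs_nt="T",
                            c_hgvs=ov.c_hgvs or "",
                            transcript=ov.transcript or "",
                            p_hgvs_raw=render_dialect(ov.p_hgvs, prof.dialect),
                            variant_type=_variant_type(ov.p_hgvs),
                            af=round(af, 2),
                            depth=depth,
                        )
                    )
                if reported_any:
                    ledger.outcomes[ident] = "detected"
                else:
                    ledger.outcomes.setdefault(ident, "missed")
    return reports, statuses, ledger
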