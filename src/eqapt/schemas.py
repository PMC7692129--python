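"""Domain types for NGS proficiency-testing benchmarks.

Everything downstream of I/O speaks these types. Genomic positions on
variants are 1-based (VCF convention); intervals are 0-based half-open
(BED convention). Allele frequencies are percentages on the 0-100 scale
throughout, matching how clinical laboratories report them.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator


class Validation(str, enum.Enum):
    """Orthogonal evidence certifying a benchmark variant's presence."""

    DDPCR = "ddPCR"
    WES = "WES"
    BOTH = "both"
    NONE = "none"


class Origin(str, enum.Enum):
    ENDOGENOUS = "endogenous"
    INSERTED = "inserted"


class Enrichment(str, enum.Enum):
    AMPLICON = "amplicon"
    PROBE = "probe"


class GenomicInterval(BaseModel):
    """0-based half-open interval, the BED convention."""

    chrom: str
    start: int = Field(ge=0)
    end: int
    name: Optional[str] = None

    @model_validator(mode="after")
    def _check_bounds(self) -> "GenomicInterval":
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        return self

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos_1based: int) -> bool:
        """Membership of a 1-based genomic position in this interval."""
        p = pos_1based - 1
        return self.start <= p < self.end


class SampleSpec(BaseModel):
    sample_id: str
    cancer_context: str = ""
    replicate_count: int = Field(default=3, ge=1)
    targeted_genes: list[tuple[str, str]] = Field(default_factory=list)


class OrderedVariant(BaseModel):
    """A certified truth-candidate variant in one benchmark sample.

    The catalogue holds both vendor-ordered variants and extras later
    confirmed by WES on the production cell lines (``was_ordered=False``).
    """

    sample_id: str
    gene: str
    transcript: Optional[str] = None
    protein_ref: Optional[str] = None
    p_hgvs: str
    c_hgvs: Optional[str] = None
    chrom: str
    pos: int = Field(ge=1)
    expected_af: float = Field(gt=0, le=100)
    validation: Validation = Validation.NONE
    origin: Origin = Origin.ENDOGENOUS
    cassette: Optional[GenomicInterval] = None
    was_ordered: bool = True

    @model_validator(mode="after")
    def _cassette_iff_inserted(self) -> "OrderedVariant":
        if (self.origin is Origin.INSERTED) != (self.cassette is not None):
            raise ValueError(
                "origin=inserted requires a cassette footprint and vice versa"
            )
        return self


class PanelDefinition(BaseModel):
    panel_id: str
    intervals: list[GenomicInterval]
    enrichment: Enrichment = Enrichment.AMPLICON

    @field_validator("intervals")
    @classmethod
    def _non_empty(cls, v: list[GenomicInterval]) -> list[GenomicInterval]:
        if not v:
            raise ValueError("panel must define at least one interval")
        return v


class BenchmarkDesign(BaseModel):
    """One benchmark round: samples, participants, truth catalogue, ROI."""

    benchmark_id: str
    samples: list[SampleSpec]
    participants: list[str]
    ordered_variants: list[OrderedVariant] = Field(default_factory=list)
    roi: list[GenomicInterval] = Field(default_factory=list)
    panels: dict[str, PanelDefinition] = Field(default_factory=dict)
    accepted_validation: list[Validation] = Field(
        default_factory=lambda: [Validation.DDPCR, Validation.WES, Validation.BOTH]
    )
    consensus_fraction: float = Field(default=2.0 / 3.0, gt=0, le=1)
    z_acceptance: float = 3.0
    peer_group_min: int = Field(default=6, ge=2)

    @model_validator(mode="after")
    def _referential_integrity(self) -> "BenchmarkDesign":
        if len(set(self.participants)) != len(self.participants):
            raise ValueError("participant identifiers must be unique")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample identifiers must be unique")
        known = set(sample_ids)
        for ov in self.ordered_variants:
            if ov.sample_id not in known:
                raise ValueError(
                    f"variant {ov.gene} {ov.p_hgvs} references unknown "
                    f"sample {ov.sample_id!r}"
                )
        unknown_panel = set(self.panels) - set(self.participants)
        if unknown_panel:
            raise ValueError(f"panels assigned to unknown participants: {sorted(unknown_panel)}")
        return self

    def sample(self, sample_id: str) -> SampleSpec:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


class VariantType(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    OTHER = "other"


class ReportedVariant(BaseModel):
    """One variant row from one participant's submission for one replicate."""

    participant: str
    sample_id: str
    replicate: int = Field(ge=1)
    gene: str
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref_nt: str = ""
    obs_nt: str = ""
    c_hgvs: str = ""
    transcript: str = ""
    p_hgvs_raw: str = ""
    protein_ref: str = ""
    variant_type: VariantType = VariantType.OTHER
    interpretation: str = ""
    af: float = Field(ge=0, le=100)
    depth: int = Field(default=0, ge=0)


class ReplicateStatus(BaseModel):
    """Explicit validity flag for one replicate of one sample.

    Absence of any rows for a replicate means "nothing reported" and counts
    against repeatability; an explicit invalid status removes the replicate
    from all denominators (it was never a usable sequencing).
    """

    participant: str
    sample_id: str
    replicate: int = Field(ge=1)
    valid: bool = True
    reason: Optional[str] = None


class LabPolicy(BaseModel):
    """A laboratory's declared reporting thresholds and panel."""

    participant: str
    lod_af: float = Field(default=5.0, gt=0, le=100)
    lod_depth: int = Field(default=100, ge=0)
    panel_id: Optional[str] = None
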