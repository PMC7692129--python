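"""Consensus truth-set determination and assessability masking.

A catalogue variant becomes *evaluative* (scored ground truth) when it is
validated by accepted orthogonal evidence, lies inside the regions of
interest, and was reported by at least the consensus fraction (default
two-thirds) of enrolled participants. In-ROI variants that were reported
but fail the validation or consensus bar are *informative* (listed, never
scored). Variants reported by nobody, or outside the ROI, are not assessed.

Separately, artificially inserted variants carry a ~2 kb insertion-cassette
footprint. An amplicon whose primers flank the cassette amplifies a product
2 kb longer than designed and simply drops out; such (participant, variant)
observations are benchmark-material artifacts, masked out of every
denominator and never counted as false negatives.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .nomenclature import VariantKey, key_for_ordered, variants_equivalent
from .schemas import (
    BenchmarkDesign,
    Enrichment,
    GenomicInterval,
    Origin,
    OrderedVariant,
    ReplicateStatus,
    ReportedVariant,
)


class Classification(str, enum.Enum):
    EVALUATIVE = "evaluative"
    INFORMATIVE = "informative"
    NOT_ASSESSED = "not_assessed"


class MaskReason(str, enum.Enum):
    PANEL_GAP = "panel_gap"
    CASSETTE_INCOMPATIBILITY = "cassette_incompatibility"


@dataclass(frozen=True)
class TruthVariant:
    key: VariantKey
    sample_id: str
    classification: Classification
    reporting_count: int
    participant_total: int
    validated: bool
    in_roi: bool
    ordered: bool
    expected_af: Optional[float] = None
    source: Optional[OrderedVariant] = None


@dataclass
class AssessabilityMask:
    """Set of (participant, sample, key-label) observations excluded from scoring."""

    entries: dict[tuple[str, str, str], MaskReason] = field(default_factory=dict)

    def is_masked(self, participant: str, sample_id: str, key: VariantKey) -> bool:
        return (participant, sample_id, key.label) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def consensus_threshold(n_participants: int, fraction: float) -> int:
    """Smallest k with k/n >= fraction, i.e. ceil(fraction * n)."""
    if n_participants < 1:
        raise ValueError("need at least one participant")
    return math.ceil(fraction * n_participants - 1e-9)


def in_roi(chrom: Optional[str], pos: Optional[int],
           roi: list[GenomicInterval]) -> bool:
    """Membership of a 1-based position in any ROI interval.

    Protein-only reports without coordinates cannot be checked and count
    as outside the ROI, with a warning.
    """
    if chrom is None or pos is None:
        warnings.warn("variant without genomic coordinates cannot be ROI-checked")
        return False
    return any(iv.chrom == str(chrom) and iv.contains_pos(int(pos)) for iv in roi)


def _valid_replicates(design: BenchmarkDesign, statuses: list[ReplicateStatus],
                      participant: str, sample_id: str) -> set[int]:
    n = design.sample(sample_id).replicate_count
    invalid = {
        st.replicate
        for st in statuses
        if not st.valid and st.participant == participant and st.sample_id == sample_id
    }
    return set(range(1, n + 1)) - invalid


def count_reporting_participants(
    reports: list[ReportedVariant],
    ordered: OrderedVariant,
    design: BenchmarkDesign,
    statuses: Optional[list[ReplicateStatus]] = None,
) -> int:
    """Distinct participants reporting an equivalent variant in >=1 valid replicate."""
    statuses = statuses or []
    reporters = set()
    for rv in reports:
        if rv.sample_id != ordered.sample_id:
            continue
        if rv.replicate not in _valid_replicates(design, statuses, rv.participant, rv.sample_id):
            continue
        if variants_equivalent(rv, ordered):
            reporters.add(rv.participant)
    return len(reporters)


def classify_truth(
    design: BenchmarkDesign,
    reports: list[ReportedVariant],
    statuses: Optional[list[ReplicateStatus]] = None,
) -> list[TruthVariant]:
    """Classify every catalogue variant as evaluative/informative/not assessed."""
    n = len(design.participants)
    threshold = consensus_threshold(n, design.consensus_fraction)
    accepted = set(design.accepted_validation)
    out: list[TruthVariant] = []
    for ov in design.ordered_variants:
        count = count_reporting_participants(reports, ov, design, statuses)
        validated = ov.validation in accepted
        inside = in_roi(ov.chrom, ov.pos, design.roi)
        if count == 0 or not inside:
            cls = Classification.NOT_ASSESSED
        elif validated and count >= threshold:
            cls = Classification.EVALUATIVE
        else:
            cls = Classification.INFORMATIVE
        out.append(
            TruthVariant(
                key=key_for_ordered(ov),
                sample_id=ov.sample_id,
                classification=cls,
                reporting_count=count,
                participant_total=n,
                validated=validated,
                in_roi=inside,
                ordered=ov.was_ordered,
                expected_af=ov.expected_af,
                source=ov,
            )
        )
    return out


def _amplicon_spans_cassette(iv: GenomicInterval, cassette: GenomicInterval,
                             pos_1based: int) -> bool:
    # Masking requires the amplicon to contain the variant position AND to
    # strictly span both cassette boundaries; partial overlap still amplifies.
    return (
        iv.chrom == cassette.chrom
        and iv.contains_pos(pos_1based)
        and iv.start < cassette.start
        and iv.end > cassette.end
    )


def mask_incompatible(design: BenchmarkDesign) -> AssessabilityMask:
    """Mask observations where a panel amplicon flanks an insertion cassette."""
    mask = AssessabilityMask()
    inserted = [ov for ov in design.ordered_variants if ov.origin is Origin.INSERTED]
    for participant in design.participants:
        panel = design.panels.get(participant)
        if panel is None:
            if inserted:
                warnings.warn(f"no panel for participant {participant}; nothing masked")
            continue
        if panel.enrichment is Enrichment.PROBE:
            continue  # hybrid-capture probes tolerate the insert
        for ov in inserted:
            assert ov.cassette is not None
            if any(
                _amplicon_spans_cassette(iv, ov.cassette, ov.pos)
                for iv in panel.intervals
            ):
                key = key_for_ordered(ov)
                mask.entries[(participant, ov.sample_id, key.label)] = (
                    MaskReason.CASSETTE_INCOMPATIBILITY
                )
    return mask


def mask_audit_table(mask: AssessabilityMask) -> list[dict]:
    """Mask as a flat audit table (participant, sample, variant, reason)."""
    return [
        {"participant": p, "sample_id": s, "variant": v, "reason": r.value}
        for (p, s, v), r in sorted(mask.entries.items())
    ]
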