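"""Detection scoring, repeatability, false-negative taxonomy and aggregates.

A participant correctly identifies an evaluative variant when it appears in
at least one valid replicate; a variant absent from every valid replicate
is a false negative. Observations masked for cassette/panel incompatibility
are benchmark-material artifacts: they leave every denominator and are
never counted as false negatives (though the pre-masking miss list is kept
for audit). False positives are not scored - the truth set is purely a
positive target class - so non-truth reports are only listed descriptively.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .nomenclature import VariantKey, variants_equivalent
from .schemas import (
    BenchmarkDesign,
    LabPolicy,
    ReplicateStatus,
    ReportedVariant,
)
from .stats import (
    AllocationMode,
    PeerGroup,
    VariantStatistics,
    allocate_z,
    mraf,
)
from .truth import (
    AssessabilityMask,
    Classification,
    TruthVariant,
    classify_truth,
    mask_incompatible,
)


def round_half_up(x: float, digits: int = 2) -> float:
    """Display rounding: decimal half-up (so 96.605 -> 96.61)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DetectionRecord:
    participant: str
    sample_id: str
    key: VariantKey
    replicates_reported: int
    replicates_valid: int
    assessable: bool
    reported_afs: tuple[float, ...] = ()
    truth: Optional[TruthVariant] = None

    @property
    def detected(self) -> bool:
        return self.replicates_reported >= 1

    @property
    def mraf(self) -> Optional[float]:
        return mraf(self.reported_afs)


class FnCause(str, enum.Enum):
    OPERATOR_ERROR = "operator_error"
    BELOW_LOD = "below_lod"
    NEAR_LOD = "near_lod"
    VUS_POLICY = "vus_policy"
    CASSETTE_INCOMPATIBILITY = "cassette_incompatibility"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class FalseNegative:
    record: DetectionRecord
    cause: FnCause
    evidence_in_reads: Optional[bool] = None


@dataclass
class Annotations:
    """Curated inputs standing in for manual BAM/IGV review.

    Keys are ``(participant, sample_id, key.label)`` tuples.
    """

    policies: dict[str, LabPolicy] = field(default_factory=dict)
    operator_error: set[tuple[str, str, str]] = field(default_factory=set)
    vus_policy: set[tuple[str, str, str]] = field(default_factory=set)
    evidence_in_reads: dict[tuple[str, str, str], bool] = field(default_factory=dict)


@dataclass
class ParticipantScore:
    participant: str
    correct: int
    total: int

    @property
    def rate(self) -> float:
        return 100.0 * self.correct / self.total if self.total else float("nan")


@dataclass
class SuccessSummary:
    per_participant: dict[str, ParticipantScore]
    global_correct: int
    global_total: int

    @property
    def global_rate(self) -> float:
        if self.global_total == 0:
            raise ZeroDivisionError("no assessable observations")
        return 100.0 * self.global_correct / self.global_total

    def stratified(self) -> list[dict]:
        """Participants grouped by success rate, highest first (Table-5 shape)."""
        buckets: dict[float, list[ParticipantScore]] = {}
        for score in self.per_participant.values():
            buckets.setdefault(round_half_up(score.rate), []).append(score)
        n = len(self.per_participant)
        rows = []
        for rate in sorted(buckets, reverse=True):
            scores = buckets[rate]
            counts = sorted({f"{s.correct}/{s.total}" for s in scores})
            rows.append(
                {
                    "rate_pct": rate,
                    "counts": counts,
                    "participants": len(scores),
                    "participants_pct": round_half_up(100.0 * len(scores) / n),
                }
            )
        return rows


def _valid_replicates(design: BenchmarkDesign, statuses: Sequence[ReplicateStatus],
                      participant: str, sample_id: str) -> set[int]:
    n = design.sample(sample_id).replicate_count
    invalid = {
        st.replicate
        for st in statuses
        if not st.valid and st.participant == participant and st.sample_id == sample_id
    }
    return set(range(1, n + 1)) - invalid


def detection_matrix(
    reports: Sequence[ReportedVariant],
    truth: Sequence[TruthVariant],
    design: BenchmarkDesign,
    statuses: Sequence[ReplicateStatus] = (),
    mask: Optional[AssessabilityMask] = None,
) -> list[DetectionRecord]:
    """One record per (participant x sample x evaluative variant)."""
    mask = mask or AssessabilityMask()
    evaluative = [tv for tv in truth if tv.classification is Classification.EVALUATIVE]
    records: list[DetectionRecord] = []
    for tv in evaluative:
        assert tv.source is not None
        relevant = [rv for rv in reports if rv.sample_id == tv.sample_id
                    and variants_equivalent(rv, tv.source)]
        for participant in design.participants:
            valid = _valid_replicates(design, statuses, participant, tv.sample_id)
            by_rep: dict[int, float] = {}
            for rv in relevant:
                if rv.participant == participant and rv.replicate in valid:
                    by_rep.setdefault(rv.replicate, rv.af)
            records.append(
                DetectionRecord(
                    participant=participant,
                    sample_id=tv.sample_id,
                    key=tv.key,
                    replicates_reported=len(by_rep),
                    replicates_valid=len(valid),
                    assessable=not mask.is_masked(participant, tv.sample_id, tv.key),
                    reported_afs=tuple(by_rep[r] for r in sorted(by_rep)),
                    truth=tv,
                )
            )
    return records


def success_rate(records: Sequence[DetectionRecord]) -> SuccessSummary:
    """Per-participant and global success rates over assessable records."""
    per: dict[str, ParticipantScore] = {}
    participants = sorted({r.participant for r in records})
    for p in participants:
        own = [r for r in records if r.participant == p and r.assessable]
        per[p] = ParticipantScore(
            participant=p,
            correct=sum(1 for r in own if r.detected),
            total=len(own),
        )
    total = sum(s.total for s in per.values())
    if total == 0:
        raise ValueError("no assessable observations: success rate undefined")
    return SuccessSummary(
        per_participant=per,
        global_correct=sum(s.correct for s in per.values()),
        global_total=total,
    )


def repeatability_issues(records: Sequence[DetectionRecord]) -> list[DetectionRecord]:
    """Assessable records reported in some but not all valid replicates."""
    return [
        r for r in records
        if r.assessable and 1 <= r.replicates_reported < r.replicates_valid
    ]


def classify_false_negative(
    record: DetectionRecord,
    annotations: Optional[Annotations] = None,
    near_factor: float = 1.5,
) -> FalseNegative:
    """Assign a cause to one missed evaluative variant (decision cascade)."""
    if record.replicates_reported != 0:
        raise ValueError("record is not a false negative")
    ann = annotations or Annotations()
    ident = (record.participant, record.sample_id, record.key.label)
    evidence = ann.evidence_in_reads.get(ident)
    if not record.assessable:
        return FalseNegative(record, FnCause.CASSETTE_INCOMPATIBILITY, evidence)
    if ident in ann.operator_error:
        return FalseNegative(record, FnCause.OPERATOR_ERROR, evidence)
    policy = ann.policies.get(record.participant)
    expected = record.truth.expected_af if record.truth else None
    if policy is not None and expected is not None:
        if expected < policy.lod_af:
            return FalseNegative(record, FnCause.BELOW_LOD, evidence)
        if expected <= near_factor * policy.lod_af:
            return FalseNegative(record, FnCause.NEAR_LOD, evidence)
    if ident in ann.vus_policy:
        return FalseNegative(record, FnCause.VUS_POLICY, evidence)
    return FalseNegative(record, FnCause.UNDETERMINED, evidence)


def false_negatives(
    records: Sequence[DetectionRecord],
    annotations: Optional[Annotations] = None,
    include_masked: bool = False,
    near_factor: float = 1.5,
) -> list[FalseNegative]:
    """Classified misses; masked observations only when explicitly audited."""
    out = []
    for r in records:
        if r.replicates_reported:
            continue
        if not r.assessable and not include_masked:
            continue
        out.append(classify_false_negative(r, annotations, near_factor))
    return out


def z_citation_tally(
    all_stats: Sequence[VariantStatistics],
) -> tuple[int, int, float]:
    """(cited, allocated, percentage) summed over variants."""
    cited = sum(s.cited for s in all_stats)
    allocated = sum(s.allocated for s in all_stats)
    pct = round_half_up(100.0 * cited / allocated) if allocated else 0.0
    return cited, allocated, pct


@dataclass
class BenchmarkResult:
    """Everything the reports need, computed once."""

    design: BenchmarkDesign
    truth: list[TruthVariant]
    mask: AssessabilityMask
    records: list[DetectionRecord]
    statistics: list[VariantStatistics]
    informative_stats: list[VariantStatistics]
    success: SuccessSummary
    repeatability: list[DetectionRecord]
    fn_pre_masking: list[FalseNegative]
    fn_post_masking: list[FalseNegative]
    mode: AllocationMode

    @property
    def evaluative(self) -> list[TruthVariant]:
        return [t for t in self.truth if t.classification is Classification.EVALUATIVE]

    @property
    def informative(self) -> list[TruthVariant]:
        return [t for t in self.truth if t.classification is Classification.INFORMATIVE]

    @property
    def z_tally(self) -> tuple[int, int, float]:
        return z_citation_tally(self.statistics)

    @property
    def fn_distinct_pairs(self) -> int:
        """Distinct (sample, variant) pairs among pre-masking misses."""
        return len({(fn.record.sample_id, fn.record.key.label)
                    for fn in self.fn_pre_masking})


def peer_groups_from_panels(design: BenchmarkDesign) -> list[PeerGroup]:
    """Participants sharing a gene panel form a peer group."""
    by_panel: dict[str, list[str]] = {}
    for participant in design.participants:
        panel = design.panels.get(participant)
        if panel is not None:
            by_panel.setdefault(panel.panel_id, []).append(participant)
    return [PeerGroup(panel_id=pid, members=tuple(sorted(m)))
            for pid, m in sorted(by_panel.items())]


def evaluate_benchmark(
    design: BenchmarkDesign,
    reports: Sequence[ReportedVariant],
    statuses: Sequence[ReplicateStatus] = (),
    annotations: Optional[Annotations] = None,
    mode: AllocationMode = AllocationMode.GLOBAL,
    near_factor: float = 1.5,
) -> BenchmarkResult:
    """Run the whole assessment for one benchmark round."""
    truth = classify_truth(design, list(reports), list(statuses))
    mask = mask_incompatible(design)
    records = detection_matrix(reports, truth, design, statuses, mask)
    groups = peer_groups_from_panels(design) if mode is AllocationMode.PEER_GROUP else []

    def _stats_for(tv: TruthVariant, mrafs: dict[str, float]) -> VariantStatistics:
        return allocate_z(
            tv.key,
            tv.sample_id,
            mrafs,
            mode=mode,
            groups=groups,
            peer_group_min=design.peer_group_min,
            z_acceptance=design.z_acceptance,
        )

    statistics: list[VariantStatistics] = []
    for tv in truth:
        if tv.classification is not Classification.EVALUATIVE:
            continue
        mrafs = {
            r.participant: r.mraf
            for r in records
            if r.key == tv.key and r.sample_id == tv.sample_id and r.detected
        }
        statistics.append(_stats_for(tv, {p: m for p, m in mrafs.items() if m is not None}))

    # Informative variants get the same descriptive statistics but are never
    # scored; their citation flags are not tallied.
    informative_stats: list[VariantStatistics] = []
    for tv in truth:
        if tv.classification is not Classification.INFORMATIVE:
            continue
        assert tv.source is not None
        by_lab: dict[str, list[float]] = {}
        for rv in reports:
            if rv.sample_id != tv.sample_id or not variants_equivalent(rv, tv.source):
                continue
            if rv.replicate in _valid_replicates(design, statuses, rv.participant, rv.sample_id):
                by_lab.setdefault(rv.participant, []).append(rv.af)
        mrafs = {p: mraf(afs) for p, afs in by_lab.items()}
        informative_stats.append(_stats_for(tv, {p: m for p, m in mrafs.items() if m is not None}))

    return BenchmarkResult(
        design=design,
        truth=truth,
        mask=mask,
        records=records,
        statistics=statistics,
        informative_stats=informative_stats,
        success=success_rate(records),
        repeatability=repeatability_issues(records),
        fn_pre_masking=false_negatives(records, annotations, include_masked=True,
                                       near_factor=near_factor),
        fn_post_masking=false_negatives(records, annotations, include_masked=False,
                                        near_factor=near_factor),
        mode=mode,
    )
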