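"""Detection matrix, success rates, repeatability and the FN cause cascade."""

import warnings
from collections import Counter

import pytest

from eqapt.evaluation import (
    Annotations,
    DetectionRecord,
    FnCause,
    classify_false_negative,
    detection_matrix,
    evaluate_benchmark,
    repeatability_issues,
    round_half_up,
    success_rate,
    z_citation_tally,
)
from eqapt.nomenclature import VariantKey
from eqapt.schemas import (
    BenchmarkDesign,
    GenomicInterval,
    LabPolicy,
    OrderedVariant,
    ReplicateStatus,
    ReportedVariant,
    SampleSpec,
    Validation,
)
from eqapt.truth import classify_truth

KEY = VariantKey(gene="BRAF", canonical_p="p.(Val600Glu)")


def _design(n_labs=3):
    return BenchmarkDesign(
        benchmark_id="T",
        samples=[SampleSpec(sample_id="S1")],
        participants=[f"P{i}" for i in range(n_labs)],
        ordered_variants=[
            OrderedVariant(sample_id="S1", gene="BRAF", p_hgvs="p.(Val600Glu)",
                           chrom="chr7", pos=1000, expected_af=13.0,
                           validation=Validation.DDPCR)
        ],
        roi=[GenomicInterval(chrom="chr7", start=900, end=1100)],
    )


def _report(lab, rep, af=13.0):
    return ReportedVariant(participant=lab, sample_id="S1", replicate=rep,
                           gene="BRAF", chrom="chr7", pos=1000,
                           p_hgvs_raw="p.(Val600Glu)", af=af)


def test_detection_matrix_counts_and_validity():
    design = _design()
    reports = [_report("P0", r) for r in (1, 2, 3)] + [_report("P1", 2)]
    statuses = [ReplicateStatus(participant="P2", sample_id="S1", replicate=3,
                                valid=False, reason="QC")]
    truth = classify_truth(design, reports, statuses)
    records = detection_matrix(reports, truth, design, statuses)
    by_lab = {r.participant: r for r in records}
    assert len(records) == 3
    assert by_lab["P0"].replicates_reported == 3
    assert by_lab["P1"].replicates_reported == 1
    assert by_lab["P2"].replicates_valid == 2  # invalidated replicate removed
    assert by_lab["P2"].replicates_reported == 0


def test_detection_matrix_empty_reports():
    design = _design()
    # classify on non-empty reports so the variant stays evaluative
    truth = classify_truth(design, [_report(f"P{i}", 1) for i in range(3)])
    records = detection_matrix([], truth, design)
    assert all(r.replicates_reported == 0 for r in records)


def test_success_rate_at_least_one_replicate():
    design = _design()
    reports = [_report("P0", 1), _report("P1", 2), _report("P1", 3)]
    truth = classify_truth(design, reports)
    summary = success_rate(detection_matrix(reports, truth, design))
    assert summary.global_correct == 2 and summary.global_total == 3
    assert summary.per_participant["P2"].correct == 0


def test_success_rate_undefined_without_observations():
    with pytest.raises(ValueError):
        success_rate([])


@pytest.mark.parametrize(
    "reported, valid, is_issue",
    [(2, 3, True), (1, 3, True), (3, 3, False), (2, 2, False), (0, 3, False)],
)
def test_repeatability_rule(reported, valid, is_issue):
    rec = DetectionRecord(participant="P", sample_id="S1", key=KEY,
                          replicates_reported=reported, replicates_valid=valid,
                          assessable=True)
    assert (repeatability_issues([rec]) == [rec]) is is_issue


def _fn_record(assessable=True, expected_af=20.0):
    from eqapt.truth import Classification, TruthVariant

    tv = TruthVariant(key=KEY, sample_id="S1",
                      classification=Classification.EVALUATIVE,
                      reporting_count=10, participant_total=12, validated=True,
                      in_roi=True, ordered=True, expected_af=expected_af)
    return DetectionRecord(participant="P1", sample_id="S1", key=KEY,
                           replicates_reported=0, replicates_valid=3,
                           assessable=assessable, truth=tv)


def test_fn_cascade_masked_beats_everything():
    fn = classify_false_negative(_fn_record(assessable=False))
    assert fn.cause is FnCause.CASSETTE_INCOMPATIBILITY


def test_fn_cascade_lod_rules():
    ann = Annotations(policies={"P1": LabPolicy(participant="P1", lod_af=5.0)})
    assert classify_false_negative(_fn_record(expected_af=3.73), ann).cause \
        is FnCause.BELOW_LOD
    assert classify_false_negative(_fn_record(expected_af=5.12), ann).cause \
        is FnCause.NEAR_LOD
    assert classify_false_negative(_fn_record(expected_af=20.0), ann).cause \
        is FnCause.UNDETERMINED


def test_fn_cascade_curated_flags():
    ident = ("P1", "S1", KEY.label)
    ann = Annotations(policies={"P1": LabPolicy(participant="P1", lod_af=5.0)},
                      operator_error={ident},
                      evidence_in_reads={ident: True})
    fn = classify_false_negative(_fn_record(expected_af=3.0), ann)
    assert fn.cause is FnCause.OPERATOR_ERROR  # flag precedes LOD rules
    assert fn.evidence_in_reads is True
    ann2 = Annotations(vus_policy={ident})
    assert classify_false_negative(_fn_record(), ann2).cause is FnCause.VUS_POLICY


def test_fn_missing_policy_skips_lod():
    assert classify_false_negative(_fn_record(expected_af=3.0)).cause \
        is FnCause.UNDETERMINED


def test_fn_requires_a_miss():
    rec = DetectionRecord(participant="P", sample_id="S1", key=KEY,
                          replicates_reported=1, replicates_valid=3,
                          assessable=True)
    with pytest.raises(ValueError):
        classify_false_negative(rec)


def test_z_citation_tally_zero():
    assert z_citation_tally([]) == (0, 0, 0.0)


def test_round_half_up_display():
    assert round_half_up(16.665) == 16.67
    assert round_half_up(96.605) == 96.61
    assert round_half_up(91.666666, 2) == 91.67


def test_per_participant_rates_aggregate_to_global(benchmark_results):
    for _, result in benchmark_results.values():
        s = result.success
        assert s.global_correct == sum(p.correct for p in s.per_participant.values())
        assert s.global_total == sum(p.total for p in s.per_participant.values())


def test_masked_records_out_of_denominators_and_fn_lists(benchmark_results):
    for _, result in benchmark_results.values():
        n_masked = len(result.mask)
        n_eval = len(result.evaluative)
        n_labs = len(result.design.participants)
        assert result.success.global_total == n_labs * n_eval - n_masked
        assert all(fn.record.assessable for fn in result.fn_post_masking)
        pre = len(result.fn_pre_masking)
        assert pre - n_masked == len(result.fn_post_masking)


def test_removing_a_participant_recomputes_denominators():
    design = _design(n_labs=4)
    reports = [_report(f"P{i}", r) for i in range(4) for r in (1, 2, 3)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = evaluate_benchmark(design, reports)
        smaller = design.model_copy(update={"participants": ["P0", "P1", "P2"]})
        part = evaluate_benchmark(
            smaller, [r for r in reports if r.participant != "P3"])
    assert full.success.global_total == 4
    assert part.success.global_total == 3
    assert "P3" not in part.success.per_participant


def test_fixture_repeatability_narratives(benchmark_results):
    _, r1 = benchmark_results["2017/1"]
    assert r1.repeatability == []
    _, r2 = benchmark_results["2017/2"]
    issues = Counter(rec.participant for rec in r2.repeatability)
    assert issues == {"M01": 3, "M02": 3}  # the QC-failed triplicate is not an issue
    _, r3 = benchmark_results["2018/1"]
    assert Counter(rec.participant for rec in r3.repeatability) == {"N01": 2}


def test_fixture_fn_cause_taxonomy(benchmark_results):
    causes = Counter()
    for _, result in benchmark_results.values():
        causes.update(fn.cause.value for fn in result.fn_pre_masking)
    assert causes == {
        "operator_error": 1, "below_lod": 3, "near_lod": 2, "vus_policy": 1,
        "cassette_incompatibility": 6, "undetermined": 10,
    }
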