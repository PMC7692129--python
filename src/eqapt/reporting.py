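"""Anonymized global and individual report rendering.

The global bundle mirrors the published report layout: a per-variant table
for evaluative variants (median AF (SD), Z-citations a/b, participant
success a/b), an informative-variant table, the success-rate
stratification, a false-negative appendix and a repeatability narrative.
Each participant additionally receives a private scorecard listing their
own detections, misses with cause, and Z-scores against the anonymized
distribution. Rendering is deterministic: identical results and seed yield
byte-identical files (run metadata is confined to a header block).
"""

from __future__ import annotations

import hashlib
import os
from typing import Optional, Union

import pandas as pd

from .evaluation import (
    Annotations,
    BenchmarkResult,
    FalseNegative,
    round_half_up,
)
from .stats import AllocationMode, VariantStatistics

PathLike = Union[str, os.PathLike]


class AnonymizationMap:
    """Deterministic opaque participant codes (keyed-hash, 6 hex chars)."""

    def __init__(self, participants: list[str], seed: int = 0):
        self._codes: dict[str, str] = {}
        taken: set[str] = set()
        for p in participants:
            digest = hashlib.blake2b(
                p.encode(), key=str(seed).encode(), digest_size=8
            ).hexdigest()
            code = digest[:6]
            while code in taken:  # truncation collision: extend deterministically
                digest = hashlib.blake2b(
                    (p + code).encode(), key=str(seed).encode(), digest_size=8
                ).hexdigest()
                code = digest[:6]
            taken.add(code)
            self._codes[p] = code

    def __getitem__(self, participant: str) -> str:
        return self._codes[participant]

    def items(self):
        return self._codes.items()


def _fmt(x: Optional[float], digits: int = 2) -> str:
    return "/" if x is None else f"{round_half_up(x, digits):.{digits}f}"


def variant_row(st: VariantStatistics, result: BenchmarkResult) -> dict:
    """One rendered per-variant line of the evaluative table."""
    success = [
        r for r in result.records
        if r.key == st.key and r.sample_id == st.sample_id and r.assessable
    ]
    cited, allocated = st.cited, st.allocated
    no_pool = not st.group_stats
    return {
        "sample": st.sample_id,
        "variant": st.key.label,
        "median_af_sd": "/" if no_pool and result.mode is AllocationMode.PEER_GROUP
        else f"{_fmt(st.maf)} ({_fmt(st.sd)})",
        "z_citations": f"{cited}/{allocated}" if allocated else "/",
        "participant_success": (
            f"{sum(1 for r in success if r.detected)}/{len(success)}"
        ),
    }


def informative_row(st: VariantStatistics, result: BenchmarkResult) -> dict:
    reporters = len(st.mraf_by_participant)
    no_pool = not st.group_stats and result.mode is AllocationMode.PEER_GROUP
    return {
        "sample": st.sample_id,
        "variant": st.key.label,
        "median_af_sd": "/" if no_pool else f"{_fmt(st.maf)} ({_fmt(st.sd)})",
        "participant_identification": f"{reporters}/{len(result.design.participants)}",
    }


def _fn_table(fns: list[FalseNegative], anon: AnonymizationMap) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant": anon[fn.record.participant],
                "sample": fn.record.sample_id,
                "variant": fn.record.key.label,
                "cause": fn.cause.value,
                "evidence_in_reads": (
                    "" if fn.evidence_in_reads is None else str(fn.evidence_in_reads)
                ),
            }
            for fn in fns
        ],
        columns=["participant", "sample", "variant", "cause", "evidence_in_reads"],
    )


def render_global(
    result: BenchmarkResult,
    out_dir: PathLike,
    anon: Optional[AnonymizationMap] = None,
    informative_stats: Optional[list[VariantStatistics]] = None,
    seed: int = 0,
) -> dict[str, str]:
    """Write the anonymized global bundle; returns {artifact: path}."""
    anon = anon or AnonymizationMap(result.design.participants, seed=seed)
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    ev = pd.DataFrame([variant_row(st, result) for st in result.statistics])
    paths["evaluative"] = os.path.join(out_dir, "evaluative_variants.csv")
    ev.to_csv(paths["evaluative"], index=False)

    info = pd.DataFrame(
        [informative_row(st, result) for st in (informative_stats or [])],
        columns=["sample", "variant", "median_af_sd", "participant_identification"],
    )
    paths["informative"] = os.path.join(out_dir, "informative_variants.csv")
    info.to_csv(paths["informative"], index=False)

    strat = pd.DataFrame(result.success.stratified())
    if not strat.empty:
        strat["counts"] = strat["counts"].map(lambda c: " or ".join(c))
    paths["stratified"] = os.path.join(out_dir, "success_stratified.csv")
    strat.to_csv(paths["stratified"], index=False)

    paths["false_negatives"] = os.path.join(out_dir, "false_negatives.csv")
    _fn_table(result.fn_pre_masking, anon).to_csv(paths["false_negatives"], index=False)

    cited, allocated, pct = result.z_tally
    s = result.success
    lines = [
        f"# Global report - benchmark {result.design.benchmark_id}",
        "",
        f"Participants: {len(result.design.participants)}",
        f"Evaluative variants: {len(result.evaluative)}",
        f"Global success rate: {round_half_up(s.global_rate)}% "
        f"({s.global_correct}/{s.global_total})",
        f"Z-score citations: {cited}/{allocated} ({pct}%)",
        f"Masked observations (cassette incompatibility): {len(result.mask)}",
        f"False negatives before masking: {len(result.fn_pre_masking)}",
        "",
        "## Repeatability",
    ]
    if result.repeatability:
        for r in sorted(result.repeatability,
                        key=lambda r: (r.participant, r.sample_id, r.key.label)):
            lines.append(
                f"- {anon[r.participant]}: {r.key.label} in {r.sample_id} reported "
                f"in {r.replicates_reported} of {r.replicates_valid} replicates"
            )
    else:
        lines.append("- no repeatability issues observed")
    paths["narrative"] = os.path.join(out_dir, "global_report.md")
    with open(paths["narrative"], "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    return paths


def render_individual(
    participant: str,
    result: BenchmarkResult,
    out_dir: PathLike,
    anon: Optional[AnonymizationMap] = None,
    annotations: Optional[Annotations] = None,
    seed: int = 0,
) -> str:
    """Write one participant's private scorecard; returns its path."""
    if participant not in result.design.participants:
        raise KeyError(f"unknown participant {participant!r}")
    anon = anon or AnonymizationMap(result.design.participants, seed=seed)
    os.makedirs(out_dir, exist_ok=True)
    ann = annotations or Annotations()
    score = result.success.per_participant[participant]
    own_fns = [fn for fn in result.fn_post_masking
               if fn.record.participant == participant]
    policy = ann.policies.get(participant)

    lines = [
        f"# Individual report - benchmark {result.design.benchmark_id}",
        f"Participant code: {anon[participant]}",
        "",
        f"Success rate: {round_half_up(score.rate)}% ({score.correct}/{score.total})",
        "",
        "## Detections and Z-scores",
    ]
    for st in result.statistics:
        z = st.z_by_participant.get(participant)
        if z is None:
            continue
        if z.allocated:
            flag = " **CITED**" if z.cited else ""
            z_txt = f"Z = {z.z:+.2f}{flag}"
        else:
            z_txt = "Z not allocated"
        own = st.mraf_by_participant.get(participant)
        lines.append(
            f"- {st.key.label} ({st.sample_id}): own MRAF {_fmt(own)}, "
            f"cohort {_fmt(st.maf)} ({_fmt(st.sd)}), {z_txt}"
        )
    lines.append("")
    lines.append("## Missed evaluative variants")
    if own_fns:
        for fn in own_fns:
            extra = ""
            if fn.cause.value in ("below_lod", "near_lod") and policy is not None:
                extra = f" (own LOD {policy.lod_af}% AF)"
            lines.append(
                f"- {fn.record.key.label} in {fn.record.sample_id}: "
                f"{fn.cause.value}{extra}"
            )
    else:
        lines.append("- none")
    path = os.path.join(out_dir, f"scorecard_{anon[participant]}.md")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
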