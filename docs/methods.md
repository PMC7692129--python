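# Methods

`eqapt` implements the evaluation procedure of a national external quality
assessment (EQA / proficiency-testing) scheme for NGS-based somatic variant
reporting in (hemato-)oncology: laboratories sequence blinded DNA samples in
triplicate, submit per-replicate variant lists, and are scored against a
consensus-plus-evidence truth set. This note documents the model, the
tunable parameters, the numerical choices, and what the synthetic cohort
does and does not establish.

## Truth-set determination

Each benchmark round ships a catalogue of certified variants per sample
(vendor-ordered, ddPCR-validated, plus extras later confirmed by WES on the
production cell lines). A catalogue variant is classified per round as:

- **evaluative** — validated by evidence the round accepts (a per-round
  policy: the hematology round accepted ddPCR only), located inside the
  regions of interest (ROI), and reported by at least a consensus fraction
  of enrolled participants (default 2/3; the threshold is
  `ceil(fraction * N)`, so 8 of 12 and 11 of 16 qualify). Only evaluative
  variants are scored.
- **informative** — in-ROI and reported by at least one participant, but
  failing the validation bar or the consensus bar. Listed, never scored.
- **not assessed** — reported by nobody, or outside the ROI.

A participant "reports" a variant when any of its valid replicates contains
an equivalent variant (see nomenclature below). The consensus denominator
is all enrolled participants, not only those whose panel covers the region.

## Nomenclature matching

Matching is protein-level. The parser tolerates the dialect space observed
across laboratories: optional `p.`/bare `p`, optional parentheses, one- or
three-letter amino-acid codes, `*`/`Ter`, `del`/`dup`/`ins`/`delins`/`fs`
forms, and `-` in place of `_` as a range separator. Canonicalization emits
three-letter codes in `p.(...)` with `*` for stop and `_` ranges; a
single-residue delins with a single inserted residue is rewritten as the
equivalent substitution (so `p.V600delinsR` and `p.(Val600Arg)` collapse).
Frameshifts carry their `fs*N` offset in the canonical string; two
frameshifts with the same start but different (or one absent) offsets are
conservatively non-equivalent. When a protein string cannot be parsed the
report falls back to genomic-coordinate identity; protein and coordinate
identities never cross-rescue each other. DNA-level (`c.`) normalization
and 3'-shifting against a reference genome are out of scope (no reference
is bundled, and the assessment itself is protein-level).

## Detection scoring and masking

For every (participant × sample × evaluative variant) the pipeline builds a
detection record: how many valid replicates contained the variant, out of
how many valid replicates. A variant found in at least one valid replicate
is correctly identified; found in none, it is a false negative. Replicates
explicitly invalidated (a sequencing that failed the laboratory's routine
QC) leave all denominators; a replicate merely absent counts as "nothing
reported" and can create a repeatability issue
(`1 <= reported < valid`).

Artificially engineered variants were built with a ~2 kb insertion
cassette. When an amplicon-panel primer pair flanks the cassette, the
amplicon is 2 kb longer than designed and fails, so the variant is
undetectable for that laboratory as an artifact of the benchmark material.
An observation is therefore **masked** when some panel amplicon contains
the variant position and strictly spans both cassette boundaries; partial
overlap still amplifies and does not mask. Probe-based (hybrid-capture)
panels are never masked. Masked observations leave every success-rate
denominator and are excluded from the false-negative list (a pre-masking
audit list retains them with cause `cassette_incompatibility`).

False negatives are assigned a cause by a fixed cascade: masked →
`cassette_incompatibility`; curated transcription-error flag →
`operator_error`; expected AF below the laboratory's declared LOD →
`below_lod`; expected AF within `near_factor` (default 1.5, configurable —
the source procedure gives no cutoff) times the LOD → `near_lod`; curated
VUS-policy flag → `vus_policy`; otherwise `undetermined`. Curated flags
stand in for the manual BAM/IGV review of the original procedure. False
positives are not scored; non-truth reports are listed descriptively only.

## Allele-frequency statistics

All frequencies are percentages on the 0–100 scale. Per evaluative variant:

- **MRAF** — a participant's median AF over its reported replicates.
- **Grubbs trimming** — iterative two-sided Grubbs at α = 0.05, removing
  the most extreme MRAF while `G = max|x−x̄|/s` exceeds
  `((n−1)/√n)·√(t²/(n−2+t²))` with `t` the upper `α/(2n)` t-quantile on
  `n−2` df, and at least three values remain.
- **MAF** — median of the retained MRAFs ("median of medians per
  triplicate", i.e. per participant, not a pooled replicate median).
- **SD** — n−1 sample standard deviation of the retained MRAFs, computed
  after trimming (the source names the test but fixes neither the α, the
  sidedness, nor the trimming/SD order; these are package choices).
- **Z** — `(MRAF − MAF)/SD` per reporter; a **citation** is issued when
  |Z| > 3.0. Laboratories removed as outliers still receive a Z against
  the trimmed consensus — they are precisely whom the citation flags.
  With SD = 0, a reporter on the consensus gets Z = 0 and anything else is
  flagged degenerate and left unallocated rather than infinite.
- **Allocation** — in global mode every reporter of a variant with ≥ 2
  reporters is allocated a Z. In peer-group mode (used when panels differ
  enough that AFs are only comparable within a panel), consensus and Z are
  computed within each peer group (participants sharing a panel), and no Z
  is allocated in groups with fewer than 6 reporting members.
- **Shapiro–Wilk** p-values are attached per variant for reporting only
  and never gate scoring.

Display rounding is decimal half-up to two decimals; internal computation
is never rounded.

## Synthetic cohort

`simulate.generate_design` draws a benchmark (genes from a fixed oncology
panel pool, expected AFs uniform in 5–50%, optional cassette-carrying
variants, ROI covering every variant plus decoys, one amplicon panel per
laboratory). `default_profiles` draws laboratory behavior from the observed
cohort ranges: LOD 1–10% AF and 100–1000 reads, inter-laboratory AF spread
0.4–3 percentage points (the upper range of the observed per-variant SDs,
0.13–2.95), one of seven HGVS dialects. `generate_submissions` then drops a
variant per replicate by cassette incompatibility, LOD censoring
(truncated-Gaussian AF noise below the LOD), whole-variant misses, or
whole-replicate QC failure (recorded as an invalid replicate), and writes
every intended outcome to a planted ledger. Identical (design, profiles,
seed) yield byte-identical submissions.

What a green synthetic test establishes: the pipeline recovers planted
outcomes (masking, censoring, deviating laboratories) under the stated
noise model. What it does not: real submissions carry free-text
interpretation variability, coordinate errors, FFPE artifacts and tumor
heterogeneity, none of which the generator models.

### Power of the Z-citation check

A deviating laboratory mean-shifted by `k` inter-laboratory SDs is cited
only if Grubbs trimming removes it (otherwise it inflates the pool SD and
its own Z shrinks). The Grubbs statistic of a lone outlier is bounded by
`(n−1)/√n`, so at typical cohort sizes shifts just above the |Z| = 3
acceptance bound are unreliably flagged: at n = 12, a 4.5-SD shift is cited
in well under half of rounds. The recovery test therefore plants a clearly
deviating laboratory — 6 SD in a 16-laboratory cohort, the size of the
solid-tumor round — where citation succeeds in ≥ 95% of rounds.

## Reconstructed rounds

`fixtures.table3_fixture` rebuilds the three published rounds from their
printed marginals: per-variant MAF/SD, Z-citations over allocated
reporters, per-variant success counts, masking totals, the
false-negative cause tally and the success-rate stratification. Laboratory
identities are not recoverable from the anonymized report, so assignment is
deterministic and count-preserving: masked observations and misses go to
the lexicographically last laboratories consistent with the stratification,
citations to the first reporting laboratories. Retained reporters sit on a
symmetric evenly-spaced AF grid rescaled to the printed SD around the
printed MAF; cited laboratories sit on an alternating above/below ladder of
extremes (fractions 0.9/0.9/0.5 of the head-room to the AF bounds) that
sequential Grubbs trimming provably peels one at a time — several extremes
on one side would mask each other. Evaluating these fixtures through the
full pipeline reproduces the printed aggregates exactly; the tests in
`tests/test_acceptance.py` assert every one of them.

## Known limitations

- ROI membership requires genomic coordinates; protein-only reports
  cannot be ROI-checked and are treated as outside the ROI with a warning.
- The published tally of "18 different variants" behind 23 false negatives
  does not match any grouping recoverable from the printed tables (the
  reconstruction yields 17 distinct (sample, variant) miss pairs); the
  pipeline reports both the observation count and the distinct-pair count.
- Stratified success-rate rows print exact half-up two-decimal rates
  (16.67%, not a loosely rounded 17%).
- Interpretation text is passed through, never scored.
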