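# eqapt

Proficiency-testing (external quality assessment, EQA) evaluation for
clinical NGS variant reporting in (hemato-)oncology.

National EQA schemes send blinded DNA samples to diagnostic laboratories,
collect their per-replicate variant reports, and score them against a
reference. `eqapt` implements that evaluation end to end for schemes built
on consensus truth sets:

- **Truth sets** — a variant is *evaluative* (scored) when it is validated
  by orthogonal evidence (ddPCR and/or WES), lies in the regions of
  interest, and was reported by ≥ 2/3 of participants; in-ROI variants
  failing a bar are *informative* (listed only).
- **Nomenclature** — protein-level HGVS reports arrive in many dialects
  (`p.(Val600Arg)`, `p(Val600Arg)`, `p.V600R`, `p.Val600delinsArg`, ...);
  a tolerant parser collapses them onto canonical keys before matching.
- **Scoring** — a variant found in ≥ 1 of 3 replicates counts as
  identified; misses are classified (operator error, below/near LOD, VUS
  policy, cassette/panel incompatibility, undetermined). Observations made
  undetectable by a 2 kb insertion cassette spanning a panel's amplicon are
  masked out of all denominators.
- **AF statistics** — per variant, each reporter's median AF over
  replicates (MRAF) is compared to the cohort consensus: median-of-medians
  MAF and SD after iterative two-sided Grubbs outlier trimming, Z =
  (MRAF − MAF)/SD, with a citation when |Z| > 3.0. Peer-group mode
  restricts the comparison to laboratories sharing a panel (no Z in groups
  under 6 reporters).
- **Reports** — anonymized global tables (per-variant statistics,
  stratified success rates, false-negative appendix) and per-laboratory
  scorecards; byte-deterministic for a given seed.
- **Synthetic cohorts** — a generator plants laboratories with known LODs,
  AF noise, dialects, panel incompatibilities and replicate failures, with
  a ledger of intended outcomes for pipeline validation.

## Worked example

Reconstruct the solid-tumor benchmark round (16 laboratories, 4 samples,
16 evaluative variants) and evaluate it:

```python
from eqapt.fixtures import table3_fixture
from eqapt.evaluation import evaluate_benchmark

bundle = table3_fixture("2017/1")
result = evaluate_benchmark(bundle.design, bundle.reports, bundle.statuses,
                            annotations=bundle.annotations, mode=bundle.mode)
s = result.success
cited, allocated, pct = result.z_tally
print(f"success {s.global_correct}/{s.global_total} ({s.global_rate:.2f}%)")
print(f"Z-citations {cited}/{allocated} ({pct}%)")
print(f"masked {len(result.mask)}, false negatives {len(result.fn_pre_masking)}")
```

prints

```
success 247/253 (97.63%)
Z-citations 19/247 (7.69%)
masked 3, false negatives 9
```

i.e. of 16 × 16 = 256 observations, 3 were masked as cassette/panel
incompatibilities (leaving 253 in the denominator), 247 evaluative variants
were found in at least one replicate, and 19 of the 247 allocated Z-scores
exceeded |3|. The same call on `"2017/2"` and `"2018/1"` yields
171/177 (96.61%) and 67/72 (93.06%).

The same pipeline runs from files via the CLI:

```sh
eqa simulate --labs 12 --samples 3 --seed 7 --out round/
eqa evaluate --design round/design.yaml --submissions round/submissions.tsv \
             --statuses round/statuses.tsv --out round/report/
eqa report   --design round/design.yaml --submissions round/submissions.tsv \
             --out round/cards/
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full evaluation over the three reconstructed benchmark rounds
and one freshly simulated cohort, printing the recomputed success rates,
Z-citation proportions, masking and false-negative totals.

## Layout

| module | contents |
| --- | --- |
| `eqapt.schemas` / `eqapt.io` | domain types; design YAML, submission TSV, BED readers/writers |
| `eqapt.nomenclature` | protein-HGVS parsing, canonicalization, variant keys |
| `eqapt.truth` | consensus classification, ROI checks, cassette masking |
| `eqapt.stats` | MRAF/MAF/SD, Grubbs trimming, Z-scores, peer groups |
| `eqapt.evaluation` | detection matrix, success rates, FN taxonomy, orchestration |
| `eqapt.reporting` | anonymized global bundle and individual scorecards |
| `eqapt.simulate` / `eqapt.fixtures` | synthetic cohorts; reconstructed published rounds |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
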