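# tndecay

Analysis toolkit for the **birth and decay of IS-flanked composite
transposons**, built around the paradigm case of the mobile colistin
resistance gene *mcr-1*: a ~2,609-bp cargo (carrying *mcr-1* and a 765-bp
*pap2* ORF) that became mobilizable when two copies of an IS30-family
insertion sequence (ISApl1, 1,070 bp, 27-bp IRR, 2-bp TSD) inserted around
it in direct orientation — and that is progressively stabilized as those IS
copies are lost again by imprecise excision.

It is aimed at people studying resistance-gene mobilization who want to ask,
for a FASTA locus: *which architecture is this, is the flanking direct
repeat a real target-site duplication, where exactly was the IS excised, and
could this structure still transpose?*

## What it computes

- **Structure classification** into the four observed architectures —
  intact composite (IS–cargo–IS), single upstream IS, single downstream IS,
  IS-free — with remnant characterization (e.g. the variants retaining the
  last 42 or 90 bp of the downstream IS including its complete IRR) and a
  structural mobility call (MOBILE / POTENTIALLY_MOBILE / IMMOBILE).
- **TSD detection and validation.** The longest direct repeat of length
  k ≤ 15 flanking the structure, with its chance probability
  `(Σ_b f_b²)^k` under the record's base composition, and — when a matched
  empty site is available — VALIDATED / REFUTED / UNVALIDATED status from
  the pre-insertion junction (one repeat copy expected; two or zero refute).
- **Excision inference.** Against a parental reference: the removed
  interval, the deletion length `d = |parent| − |decayed|`, and the deletion
  joint — the microhomology J present at both removal boundaries in the
  parent and retained once at the junction — with breakpoints normalized to
  the leftmost of the `|J|+1` equivalent placements. Hypothetical parents
  can be reconstructed from an empty site plus a canonical transposon
  sequence.
- **Cohort statistics** (deletion-length mean/sd/range, joint-length
  histogram, class counts) and pairwise **identity metrics** (percent
  identity, indel events counted as gap openings, BLOSUM62 positives).
- A **simulator** that generates all of the above with ground truth —
  composites with ancestral AT/CG inside-end dinucleotides, nested
  insertions with 5/4/9-bp duplications and a 0-bp rolling-circle case,
  decay series with 1,064–1,074-bp deletions and 1–4-bp joints, matched
  empty sites — so the whole pipeline is testable without any downloads.

## Worked example

Simulate one exemplar of each architecture and run the full pipeline:

```python
import tndecay as td

cfg = td.CohortConfig(n_intact=1, n_single_up=1, n_single_down=1, n_no_is=1)
cohort = td.simulate_cohort(cfg, seed=7)
paths = cohort.write("demo")

run = td.run_pipeline(td.PipelineConfig(seed=7), paths["cohort"],
                      paths["empty_sites"], paths["parents"], outdir="demo/out")
for row in run.report_rows():
    print(row["record_id"], row["class"], row["mobility"],
          row["tsd_status"], row["deletion_lens"], row["joint_lens"], sep="\t")
```

prints

```
sim0000_intact       INTACT_COMPOSITE   MOBILE    VALIDATED  -          -
sim0000_single_up    SINGLE_UPSTREAM    IMMOBILE  ABSENT     1066       3
sim0000_single_down  SINGLE_DOWNSTREAM  IMMOBILE  ABSENT     1064       2
sim0000_no_is        NO_IS              IMMOBILE  ABSENT     1068;1073  4;1
```

Reading it: the intact composite's 2-bp flanking repeat is confirmed as a
genuine duplication against its empty site (for this record the TSV also
shows `tsd_seq TT`, `chance_prob 0.0626` — a dinucleotide repeat flanks a
random boundary ~1/16 of the time, which is exactly why validation
matters). The decayed records each carry deletions of about the 1,070-bp IS
length with short (1–4 bp) joints, recovered exactly from the
parent/child alignment; the IS-free record shows both successive excisions.
Their TSD column is ABSENT because a fully excised side leaves a ragged
junction with no structure boundary to attribute a repeat to. `demo/out/`
contains the full TSV report, per-event table, GFF3 annotations, cohort
statistics and a run log with a config hash (identical config + inputs ⇒
byte-identical outputs).

The same stages are available as shell commands:
`tndecay simulate|annotate|classify|tsd|excise|compare|run`.

## Layout

| path | contents |
| --- | --- |
| `src/tndecay/catalog.py` | IS-element and cargo specifications; synthetic default catalog |
| `src/tndecay/synthetic.py` | backbone/insertion/composite/excision simulator with truth |
| `src/tndecay/annotate.py` | seeded local alignment feature mapping |
| `src/tndecay/classify.py` | four-class architecture calls, remnants, mobility |
| `src/tndecay/tsd.py` | TSD detection, chance model, empty-site validation |
| `src/tndecay/excision.py` | gap extraction, joint inference, parent reconstruction, stats |
| `src/tndecay/identity.py` | global-alignment identity / indel / positives metrics |
| `src/tndecay/pipeline.py`, `cli.py` | orchestration, filtering, reports, CLI |
| `docs/methods.md` | model, assumptions, parameter defaults, limitations |

Limitations and design rationale are documented in `docs/methods.md` —
in particular, the simulator plants the sequence *outcome* of abortive
copy-out transposition rather than its strand chemistry, the synthetic
catalog reproduces published element dimensions but not real sequence
content, and large plasmid rearrangements that can delete TSDs after
insertion are out of scope.
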