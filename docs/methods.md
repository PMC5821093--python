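# Methods

## The model

The package models the life cycle of a composite transposon: a cargo region
(a ~2,609-bp segment carrying the *mcr-1* colistin-resistance gene and a
765-bp *pap2* ORF that ends at the cargo 3′ end) that becomes mobilizable
when two copies of an IS30-family insertion sequence (the ISApl1-like
default: 1,070 bp, 27-bp terminal inverted repeats, 2-bp target-site
duplication) insert in direct orientation on either side of it, and that is
subsequently stabilized when those IS copies are lost again by imprecise
excision.

Three sequence signatures carry all the evidence, and each has a dedicated
analyzer:

1. **Target-site duplications (TSDs).** A DDE-type IS duplicates a short
   target motif on insertion, so the composite is flanked by a direct
   repeat, and the ancestral insertion events leave conserved inside-end
   dinucleotides (AT upstream of the cargo, CG downstream). Because a 2-bp
   flanking repeat arises by chance with probability ~1/16, detection is
   length-agnostic (scan k = max_len … 1 for the longest repeat flanking the
   structure bounds) and every call carries a chance probability
   `p^k`, where `p = Σ_b f_b²` is the per-column match probability under an
   i.i.d. base model fitted to the record. A call is only VALIDATED when a
   matched empty site (the same locus without the insertion) shows exactly
   one copy of the repeat at the junction; two copies or none REFUTE it
   (the repeat pre-existed, or the junction disagrees).

2. **Deletion joints.** Imprecise excision removes a contiguous region about
   the length of the IS between two copies of a short microhomology (1–4 bp
   typically; up to 7 and 10 bp in the variants that retain the last 42 or
   90 bp of the downstream IS, including its complete IRR). One copy of the
   joint survives at the junction. A joint of length j makes j+1 deletion
   placements equivalent; breakpoints are reported at the leftmost
   equivalent placement and the equivalence-class size is recorded, so
   repeated analyses are deterministic.

3. **Remnants and mobility.** Structures are classified by which complete
   flanking IS copies survive (`INTACT_COMPOSITE`, `SINGLE_UPSTREAM`,
   `SINGLE_DOWNSTREAM`, `NO_IS`). Partial downstream hits are remnants; a
   remnant that retains the complete IRR at ≥95% identity upgrades a
   single-upstream structure from IMMOBILE to POTENTIALLY_MOBILE. Mobility
   labels are structural assessments only, not transposition-rate
   predictions.

## The simulator

`synthetic` generates the exact structural grammar the analyzers assume,
plus machine-readable truth, so every stage can be scored without any
external data. The excision model is phenomenological: it plants the
documented sequence outcome of abortive copy-out transposition
(microhomology-mediated removal of an approximately IS-length region), not
the strand chemistry of the figure-eight intermediate.

Study conditions (generator defaults):

| parameter | default | rationale |
| --- | --- | --- |
| backbone length | 5,000 bp | leaves >1,000 bp of flank on each side of the cargo, the curation threshold |
| backbone GC | 0.50 | neutral i.i.d. host sequence |
| insertion site | uniform in [1100, L−1100] | keeps flanks above the curation threshold after decay |
| deletion length | uniform 1,064–1,074 bp | the observed range for typical single-ended variants; mean ≈ the 1,070-bp IS length |
| joint length | uniform 1–4 bp | the observed range for typical variants |
| IRR-retaining variants | remnant 42 bp → deletion 1,030 bp, joint 7 bp; remnant 90 bp → deletion 979 bp, joint 10 bp | the published breakpoint geometry of these structures |
| TSD lengths | 2 (composite-former), 5/4/9 (nested elements), 0 (rolling circle) | the printed duplication signatures |
| empty-site fraction | 1.0 | every simulated locus has a matched pre-insertion backbone |
| mutation rate | 0.0 | clean plant-and-recover by default; robustness tests raise it to 1% |

Two deliberate simulator behaviours matter for interpretation:

* **Clean-site selection.** Insertion positions are rejection-sampled so the
  planted duplication is not extended by a serendipitous flanking repeat
  (an event with probability ≈ 4^−(t+1) per site). This makes
  plant-and-recover exact; it does not change the insertion-site
  distribution in any way that matters at these scales.
* **Joint engineering.** A random backbone almost never contains the
  requested microhomology at the requested breakpoints, so the generator
  writes the joint into the upstream flank and pins its maximality with one
  base on each side of the pair. Every touched position is logged in the
  truth record. The engineered parent is the truth parent; analyses are
  scored against it. Consequently the annotated remnant of an IRR-retaining
  variant may exceed the planted remnant by up to the joint length — the
  boundary is genuinely ambiguous, since the retained joint copy aligns
  equally well to either side — and tests accept the interval
  [remnant, remnant + joint].

What the generator does **not** emulate: real IS/cargo sequence content
(catalog entries are random stand-ins with the published dimensions; users
can supply real FASTA catalogs), insertion-site sequence preferences,
large plasmid rearrangements and inversions that can delete TSDs after
insertion, selection, and circular topology (backbones are linear).
Passing tests therefore demonstrate correctness of the inference machinery
on the assumed structural grammar, not performance on rearranged or
repetitive natural plasmids.

## Numerical and algorithmic choices

* **Feature mapping** is seeded local alignment: exact 12-mer seeds
  clustered by diagonal (±60), each cluster window refined with affine-gap
  Smith–Waterman (match +2, mismatch −3, gap open −5, gap extend −2 —
  megablast-like). Hits need ≥90% identity over ≥30 bp; a hit covering
  ≥95% of its reference is a complete copy, shorter hits are remnants. The
  30-bp floor keeps chance hits (a 12-mer seed extended to ≥30 bp at ≥90%
  identity between unrelated random sequences) out of the hit list while
  still recovering the 42-bp remnant; features shorter than ~20 bp with
  mutations can be missed, which is why sub-IRR IS stubs are not annotated.
  Overlapping hits are resolved greedily by score, leftmost on ties.
* **Decayed-vs-parent alignment** uses bit-parallel edit distance (edlib),
  then contiguizes each deletion cluster exactly against the two sequences
  (longest common prefix/suffix inside a ±60-bp window) and normalizes to
  the leftmost placement. On clean data the collapse identity
  `parent[:u] + parent[u+d:] == decayed` holds exactly; when it cannot be
  established the gap is flagged `inexact` and the joint placement
  `inexact` rather than guessed.
* **Joint search** extends the microhomology run up to 30 bp from the gap
  boundary (observed joints are ≤10 bp; the window is generous but
  bounded).
* **Identity metrics** use semi-global alignment (free end gaps), identity
  = matches / aligned columns after end-gap trimming, and indel events =
  maximal internal gap runs, so three isolated single-base deletions count
  as 3 events. "Positive identity" is positive-scoring columns / aligned
  columns with BLOSUM62 (Biopython's bundled copy); with a
  positive-diagonal matrix this is bounded below by identity. Protein mode
  exists for translated ORFs; whether the published positive-identity
  figure was computed on nucleotides with a protein matrix or on
  translations is ambiguous in the source, so only the protein route is
  offered.
* **TSD policy in the pipeline.** Detection runs only when both outer
  structure boundaries are annotated (complete IS or ≥30-bp remnant on each
  side). After a complete excision the junction is ragged — the structure
  has no defined right edge — and any flanking repeat found there would be
  exactly the serendipity the chance model warns about, so such records
  report ABSENT. Truth records carry a geometric `tsd_recoverable` flag
  (intact, or remnant ≥ the annotation floor) computed from the planted
  geometry, not by running the detector.
* **Statistics.** Deletion-length standard deviation uses the sample
  convention (n−1), recorded in the output metadata. The source reports
  both 1,070 ± 2.2 and 1,069.8 ± 2.4 for the same 19 real events —
  a rounding/convention discrepancy that is documented, not resolved.
  `deletion_len` is defined unambiguously as parent length minus decayed
  length, sidestepping the question of whether the retained joint copy is
  counted.
* **Coordinates** are 0-based half-open everywhere in memory; GFF3 emission
  converts to 1-based inclusive.
* **Determinism.** All randomness flows from a single seed through spawned
  per-record substreams, so adding records to a cohort config does not
  reshuffle existing ones, and identical (config, seed) gives byte-identical
  FASTA/JSON/TSV outputs (asserted in tests).

## Open design points, resolved

* The IRR is described as 27 bp in one place and 26 bp in another in the
  source literature; the catalog default is 27 with a per-element override.
* The nested element appears under two names (ISKpn26/ISKpn6) in adjacent
  sentences of the source; names are opaque labels here.
* IS30-family inter-IR spacers of 1–3 nt have been reported; whether spacer
  length modulates excision probability is unknown, so it is not modeled
  (the joint-length distribution is configured directly instead).
* Reconstruction of a hypothetical parent needs the TSD length at the
  insertion junction. For intact or remnant-bounded structures it is
  detected; for ragged single-ended records it cannot be inferred from the
  decayed sequence alone and is supplied from the element catalog
  (`tsd_len=` argument), mirroring how known transposon sequences were used
  to build hypothetical parents in practice.

## Problem sizes

Default analyses run on single loci of ~5–10 kb and cohorts of tens of
records; the bundled end-to-end check uses a 50-record cohort, chosen as a
desk-scale stand-in for the curated public cohort whose headline counts
(273 sequences across 38 unique insertion sites) depend on database
retrieval and are out of scope here.
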