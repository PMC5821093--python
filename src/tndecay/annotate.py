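"""Locate IS copies, IS remnants, and the cargo region in a query sequence.

Feature mapping is seeded local alignment: exact k-mer seeds between the
query and a catalog reference are clustered by diagonal, and each cluster
window is refined with an affine-gap Smith-Waterman (Biopython's
PairwiseAligner, megablast-like scoring: match +2, mismatch -3, gap open -5,
gap extend -2).  Both strands are searched; reverse-strand hits are reported
with strand "-" on forward-strand query coordinates.  Overlapping hits are
resolved greedily by score with leftmost tie-break, so output is
deterministic.

A hit spanning at least ``completeness_threshold`` (default 95%) of its
reference is a complete feature copy; shorter hits are remnants with their
retained length reported — the downstream-IS right ends (e.g. the last
42 bp including the entire IRR) that survive imprecise excision are found
this way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner

from .catalog import CargoSpec, ISElementSpec, revcomp

__all__ = [
    "AlignParams",
    "FeatureHit",
    "StructureAnnotation",
    "locate_feature",
    "annotate_locus",
    "find_ie_dinucleotides",
]


@dataclass(frozen=True)
class AlignParams:
    """Scoring and filtering parameters for feature mapping."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_identity: float = 0.9
    min_len: int = 30
    completeness_threshold: float = 0.95
    seed_k: int = 12
    window_pad: int = 60
    max_overlap: int = 10


DEFAULT_PARAMS = AlignParams()


@dataclass
class FeatureHit:
    """One local alignment of a catalog feature to the query.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    query; ``ref_span`` is the covered interval of the reference feature
    (forward reference coordinates).  ``complete`` is True when the hit
    covers at least the completeness threshold of the reference; otherwise
    ``remnant_len`` records the retained length.
    """

    name: str
    start: int
    end: int
    strand: str
    pct_identity: float
    complete: bool
    remnant_len: int
    score: float
    ref_span: tuple[int, int]
    ref_len: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StructureAnnotation:
    """All feature hits for one record, in one coordinate frame."""

    record_id: str
    record_len: int
    cargo_hit: FeatureHit | None
    cargo_hits: list = field(default_factory=list)
    is_hits: list = field(default_factory=list)
    ie_dinucs: tuple[str, str] | None = None
    warnings: list = field(default_factory=list)


def _make_aligner(params: AlignParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _seed_clusters(query: str, ref: str, k: int, pad: int):
    """Exact k-mer seeds grouped by diagonal into candidate query windows."""
    index: dict[str, list[int]] = {}
    for q in range(len(query) - k + 1):
        index.setdefault(query[q : q + k], []).append(q)
    seeds = []  # (diag, qpos, rpos)
    for r in range(len(ref) - k + 1):
        for q in index.get(ref[r : r + k], ()):
            seeds.append((q - r, q, r))
    if not seeds:
        return []
    seeds.sort()
    clusters = []
    cur = [seeds[0]]
    for s in seeds[1:]:
        if s[0] - cur[-1][0] <= pad:
            cur.append(s)
        else:
            clusters.append(cur)
            cur = [s]
    clusters.append(cur)
    windows = []
    for cl in clusters:
        qmin = min(q - r for _, q, r in cl)
        qmax = max(q + (len(ref) - r) for _, q, r in cl)
        windows.append((max(0, qmin - pad), min(len(query), qmax + pad)))
    # merge overlapping windows (two diag clusters of one feature copy)
    windows.sort()
    merged = [list(windows[0])]
    for a, b in windows[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(w) for w in merged]


def _align_window(
    query: str, wstart: int, wend: int, ref: str, strand: str,
    name: str, params: AlignParams, aligner: PairwiseAligner,
) -> FeatureHit | None:
    window = query[wstart:wend]
    alignments = aligner.align(window, ref)
    try:
        if alignments.score <= 0:
            return None
        aln = alignments[0]
    except (IndexError, OverflowError):
        return None
    qblocks, rblocks = aln.aligned
    qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
    rs, re = int(rblocks[0][0]), int(rblocks[-1][1])
    matches = 0
    columns = 0
    prev_q = prev_r = None
    for (qa, qb), (ra, rb) in zip(qblocks, rblocks):
        if prev_q is not None:
            columns += (qa - prev_q) + (ra - prev_r)  # internal gap columns
        block_q = window[qa:qb]
        block_r = ref[ra:rb]
        matches += sum(x == y for x, y in zip(block_q, block_r))
        columns += qb - qa
        prev_q, prev_r = qb, rb
    identity = matches / columns if columns else 0.0
    hit_len = qe - qs
    if min(hit_len, re - rs) < params.min_len or identity < params.min_identity:
        return None
    coverage = (re - rs) / len(ref)
    complete = coverage >= params.completeness_threshold
    if strand == "-":
        # map reference span back to forward reference coordinates
        rs, re = len(ref) - re, len(ref) - rs
    return FeatureHit(
        name=name,
        start=wstart + qs,
        end=wstart + qe,
        strand=strand,
        pct_identity=identity,
        complete=complete,
        remnant_len=0 if complete else hit_len,
        score=float(aln.score),
        ref_span=(rs, re),
        ref_len=len(ref),
    )


def _resolve_overlaps(hits: list[FeatureHit], max_overlap: int) -> list[FeatureHit]:
    """Greedy by score (leftmost on ties); hits may overlap by <= max_overlap."""
    kept: list[FeatureHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.start, h.name, h.strand)):
        ok = True
        for other in kept:
            overlap = min(hit.end, other.end) - max(hit.start, other.start)
            if overlap > max_overlap:
                ok = False
                break
        if ok:
            kept.append(hit)
    kept.sort(key=lambda h: (h.start, h.end))
    return kept


def locate_feature(
    query: str,
    reference: str,
    min_identity: float | None = None,
    min_len: int | None = None,
    params: AlignParams = DEFAULT_PARAMS,
    feature_name: str = "feature",
) -> list[FeatureHit]:
    """All maximal non-overlapping local alignments of ``reference`` in
    ``query`` with identity >= min_identity and length >= min_len.

    Both strands are searched.  Raises ValueError on empty input or
    ``min_len < 15`` (shorter features are indistinguishable from chance
    matches at these scoring parameters).
    """
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    if min_identity is not None or min_len is not None:
        params = AlignParams(
            **{
                **params.__dict__,
                **({"min_identity": min_identity} if min_identity is not None else {}),
                **({"min_len": min_len} if min_len is not None else {}),
            }
        )
    if params.min_len < 15:
        raise ValueError("min_len must be >= 15")
    aligner = _make_aligner(params)
    k = min(params.seed_k, params.min_len, len(reference))
    hits: list[FeatureHit] = []
    for strand, ref in (("+", reference), ("-", revcomp(reference))):
        for wstart, wend in _seed_clusters(query, ref, k, params.window_pad):
            hit = _align_window(query, wstart, wend, ref, strand,
                                feature_name, params, aligner)
            if hit is not None:
                hits.append(hit)
    return _resolve_overlaps(hits, params.max_overlap)


def annotate_locus(
    record: str,
    catalog: dict[str, ISElementSpec] | list[ISElementSpec],
    cargo: CargoSpec,
    params: AlignParams = DEFAULT_PARAMS,
    record_id: str = "query",
) -> StructureAnnotation:
    """Map the cargo and every catalog IS element onto one record.

    Cargo and IS features share one forward-strand coordinate frame; a
    nested insertion inside the cargo splits the cargo into two partial
    hits, both reported.  A record with no cargo hit is returned with
    ``cargo_hit`` absent and a warning flag.
    """
    if isinstance(catalog, dict):
        elements = list(catalog.values())
    else:
        elements = list(catalog)
    cargo_hits = locate_feature(record, cargo.seq, params=params,
                                feature_name="cargo")
    is_hits: list[FeatureHit] = []
    for element in elements:
        is_hits.extend(
            locate_feature(record, element.seq, params=params,
                           feature_name=element.name)
        )
    is_hits = _resolve_overlaps(is_hits, params.max_overlap)
    warnings = []
    cargo_hit = max(cargo_hits, key=lambda h: h.score, default=None)
    if cargo_hit is None:
        warnings.append("no_cargo_hit")
    ann = StructureAnnotation(
        record_id=record_id,
        record_len=len(record),
        cargo_hit=cargo_hit,
        cargo_hits=cargo_hits,
        is_hits=is_hits,
        warnings=warnings,
    )
    if cargo_hit is not None and cargo_hit.complete:
        ann.ie_dinucs = find_ie_dinucleotides(ann, record)
        if ann.ie_dinucs is None:
            warnings.append("cargo_at_sequence_edge")
    return ann


def find_ie_dinucleotides(
    annotation: StructureAnnotation, record: str
) -> tuple[str, str] | None:
    """The 2 nt immediately 5' and 3' of the cargo interval.

    For an intact composite these are the ancestral inside-end target-site
    dinucleotides (AT upstream, CG downstream).  Returns None when the cargo
    abuts a sequence edge.
    """
    if annotation.cargo_hit is None:
        raise ValueError("cargo hit required to read inside-end dinucleotides")
    s, e = annotation.cargo_hit.start, annotation.cargo_hit.end
    if s < 2 or e + 2 > len(record):
        return None
    return record[s - 2 : s], record[e : e + 2]
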