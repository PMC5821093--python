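"""Assign annotated loci to the four cargo-context architectures.

The four classes, defined by which complete flanking IS copies survive
around the cargo:

* ``INTACT_COMPOSITE`` — two direct-orientation IS copies (the mobilizable
  composite transposon);
* ``SINGLE_UPSTREAM`` — only the upstream copy remains (downstream copy
  excised; a right-end remnant may persist);
* ``SINGLE_DOWNSTREAM`` — only the downstream copy remains (rare);
* ``NO_IS`` — both copies lost.

Upstream/downstream are defined relative to cargo gene orientation:
records whose cargo maps to the reverse strand are flipped internally.

Mobility is a structural assessment only: an intact composite is MOBILE; a
single-upstream variant whose downstream remnant retains the complete IRR
(the transposase-recognition right end) is POTENTIALLY_MOBILE; everything
else is IMMOBILE.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

from .annotate import (AlignParams, DEFAULT_PARAMS, FeatureHit,
                       StructureAnnotation, locate_feature)
from .catalog import ISElementSpec

__all__ = ["StructureCall", "classify_structure", "assess_mobility",
           "CLASSES", "MOBILITIES"]

CLASS_INTACT = "INTACT_COMPOSITE"
CLASS_SINGLE_UP = "SINGLE_UPSTREAM"
CLASS_SINGLE_DOWN = "SINGLE_DOWNSTREAM"
CLASS_NO_IS = "NO_IS"
CLASSES = (CLASS_INTACT, CLASS_SINGLE_UP, CLASS_SINGLE_DOWN, CLASS_NO_IS)

MOBILE = "MOBILE"
POTENTIALLY_MOBILE = "POTENTIALLY_MOBILE"
IMMOBILE = "IMMOBILE"
MOBILITIES = (MOBILE, POTENTIALLY_MOBILE, IMMOBILE)


class ClassificationError(ValueError):
    """Raised when a locus cannot be classified (no cargo hit)."""


@dataclass(frozen=True)
class StructureCall:
    """Classification of one locus with remnant and mobility annotations."""

    record_id: str
    structure_class: str
    downstream_remnant_len: int = 0
    irr_intact: bool = False
    irr_hit_len: int = 0
    mobility: str = IMMOBILE
    nested_insertions: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()


def _flip_hit(hit: FeatureHit, record_len: int) -> FeatureHit:
    return FeatureHit(
        name=hit.name,
        start=record_len - hit.end,
        end=record_len - hit.start,
        strand="+" if hit.strand == "-" else "-",
        pct_identity=hit.pct_identity,
        complete=hit.complete,
        remnant_len=hit.remnant_len,
        score=hit.score,
        ref_span=hit.ref_span,
        ref_len=hit.ref_len,
    )


def _irr_in_remnant(
    record: str,
    hit: FeatureHit,
    element: ISElementSpec,
    irr_identity: float,
    params: AlignParams,
) -> int:
    """Length of the complete IRR found inside a remnant hit (0 if absent)."""
    region = record[hit.start : hit.end]
    if len(region) < 15:
        return 0
    irr_params = AlignParams(
        **{**params.__dict__, "min_identity": irr_identity, "min_len": 15}
    )
    try:
        irr_hits = locate_feature(region, element.irr_seq, params=irr_params,
                                  feature_name="IRR")
    except ValueError:
        return 0
    for h in irr_hits:
        if h.complete and h.strand == "+":
            return h.length
    return 0


def classify_structure(
    annotation: StructureAnnotation,
    catalog: dict[str, ISElementSpec],
    record: str | None = None,
    primary_element: str = "ISApl1-like",
    irr_identity: float = 0.95,
    params: AlignParams = DEFAULT_PARAMS,
    adjacency: int = 50,
) -> StructureCall:
    """Classify one annotated locus.

    ``record`` (the sequence) is needed only to verify the IRR inside a
    downstream remnant; without it ``irr_intact`` falls back to the remnant
    hit's reference span.  Raises :class:`ClassificationError` when the
    annotation has no cargo hit.
    """
    if annotation.cargo_hit is None or not annotation.cargo_hits:
        raise ClassificationError(
            f"{annotation.record_id}: no cargo hit; cannot classify")
    element = catalog[primary_element]
    warnings = list(annotation.warnings)

    cargo_strand = annotation.cargo_hit.strand
    is_hits = list(annotation.is_hits)
    cargo_hits = list(annotation.cargo_hits)
    record_len = annotation.record_len
    flipped = record
    if cargo_strand == "-":
        # work in cargo orientation: mirror all coordinates
        is_hits = [_flip_hit(h, record_len) for h in is_hits]
        cargo_hits = [_flip_hit(h, record_len) for h in cargo_hits]
        if record is not None:
            from .catalog import revcomp

            flipped = revcomp(record)

    span_s = min(h.start for h in cargo_hits)
    span_e = max(h.end for h in cargo_hits)

    upstream = [h for h in is_hits if h.end <= span_s + adjacency // 5]
    downstream = [h for h in is_hits if h.start >= span_e - adjacency // 5]
    nested = [
        h.name
        for h in is_hits
        if h.complete and h.start > span_s and h.end < span_e
    ]

    def primary_complete(hits):
        return [h for h in hits if h.name == primary_element and h.complete]

    def nearest(hits, key):
        return sorted(hits, key=key)

    up_complete = [
        h for h in primary_complete(upstream) if h.end >= span_s - adjacency
    ]
    down_complete = [
        h for h in primary_complete(downstream) if h.start <= span_e + adjacency
    ]

    for h in up_complete + down_complete:
        if h.strand != "+":
            warnings.append("nonstandard_orientation")

    has_up = bool(up_complete)
    has_down = bool(down_complete)
    if has_up and has_down:
        cls = CLASS_INTACT
    elif has_up:
        cls = CLASS_SINGLE_UP
    elif has_down:
        cls = CLASS_SINGLE_DOWN
    else:
        cls = CLASS_NO_IS

    # downstream remnant: partial primary-element hit just 3' of the cargo
    remnant_len = 0
    irr_intact = False
    irr_hit_len = 0
    remnants = [
        h for h in downstream
        if h.name == primary_element and not h.complete
        and h.start <= span_e + adjacency
    ]
    if remnants:
        rem = nearest(remnants, lambda h: h.start)[0]
        remnant_len = rem.remnant_len
        if flipped is not None:
            irr_hit_len = _irr_in_remnant(flipped, rem, element,
                                          irr_identity, params)
            irr_intact = irr_hit_len >= element.irr_len
        else:
            # reference-span fallback: remnant must cover the full IRR
            irr_intact = (
                rem.ref_span[1] >= rem.ref_len
                and rem.ref_span[1] - rem.ref_span[0] >= element.irr_len
                and rem.pct_identity >= irr_identity
            )
            irr_hit_len = element.irr_len if irr_intact else 0

    call = StructureCall(
        record_id=annotation.record_id,
        structure_class=cls,
        downstream_remnant_len=remnant_len,
        irr_intact=irr_intact,
        irr_hit_len=irr_hit_len,
        nested_insertions=tuple(sorted(set(nested))),
        warnings=tuple(warnings),
    )
    return dc_replace(call, mobility=assess_mobility(call))


def assess_mobility(call: StructureCall) -> str:
    """Structural mobility assessment; a pure function of the call fields.

    Intact composites are MOBILE; single-upstream variants whose downstream
    remnant retains the complete IRR are POTENTIALLY_MOBILE; every other
    structure is IMMOBILE.
    """
    if call.structure_class == CLASS_INTACT:
        return MOBILE
    if call.structure_class == CLASS_SINGLE_UP and call.irr_intact:
        return POTENTIALLY_MOBILE
    return IMMOBILE
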