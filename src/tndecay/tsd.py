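"""Target-site duplication inference and empty-site validation.

A TSD is the short direct repeat of target sequence left on both sides of
an element after insertion.  Because the composite-forming element
duplicates only 2 bp, a flanking dinucleotide repeat is weak evidence on
its own — it flanks a random boundary with probability ~1/16 — so detection
here is length-agnostic (the longest flanking repeat k <= max_len is
reported together with its chance probability under an i.i.d. base model
fitted to the record), and a call is only upgraded to VALIDATED when a
matched empty site (the same locus without the insertion) shows exactly one
copy of the repeat at the pre-insertion junction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib

__all__ = ["TSDCall", "detect_tsd", "validate_with_empty_site"]

STATUS_VALIDATED = "VALIDATED"
STATUS_UNVALIDATED = "UNVALIDATED"
STATUS_REFUTED = "REFUTED"
STATUS_ABSENT = "ABSENT"


@dataclass(frozen=True)
class TSDCall:
    """An inferred flanking direct repeat around a structure.

    ``left_interval``/``right_interval`` are the 0-based half-open
    coordinates of the two repeat copies, immediately flanking the structure
    bounds.  ``chance_prob`` is the probability that a repeat of length >= k
    flanks a random boundary under the record's base composition.
    """

    record_id: str
    tsd_seq: str
    tsd_len: int
    left_interval: tuple[int, int]
    right_interval: tuple[int, int]
    status: str
    chance_prob: float
    warnings: tuple[str, ...] = ()


def _base_match_prob(record: str) -> float:
    """P(two i.i.d. bases drawn from the record's composition are equal)."""
    n = len(record)
    if n == 0:
        return 0.25
    return sum((record.count(b) / n) ** 2 for b in "ACGT")


def detect_tsd(
    record: str,
    bounds: tuple[int, int],
    max_len: int = 15,
    record_id: str = "query",
) -> TSDCall:
    """Longest direct repeat immediately flanking ``bounds``.

    Scans k = max_len ... 1 and returns the longest k such that the k nt
    immediately left of the structure equal the k nt immediately right of
    it; k = 0 yields status ABSENT.  The length is inferred, never assumed
    from the element's catalog entry.
    """
    s, e = bounds
    if not 0 <= s <= e <= len(record):
        raise ValueError(f"bounds {bounds} outside record")
    if max_len > 15:
        raise ValueError("max_len must be <= 15")
    warnings: tuple[str, ...] = ()
    if s == 0 or e == len(record):
        warnings = ("structure_at_sequence_edge",)
    p = _base_match_prob(record)
    limit = min(max_len, s, len(record) - e)
    for k in range(limit, 0, -1):
        if record[s - k : s] == record[e : e + k]:
            return TSDCall(
                record_id=record_id,
                tsd_seq=record[s - k : s],
                tsd_len=k,
                left_interval=(s - k, s),
                right_interval=(e, e + k),
                status=STATUS_UNVALIDATED,
                chance_prob=p ** k,
                warnings=warnings,
            )
    return TSDCall(
        record_id=record_id,
        tsd_seq="",
        tsd_len=0,
        left_interval=(s, s),
        right_interval=(e, e),
        status=STATUS_ABSENT,
        chance_prob=1.0,
        warnings=warnings,
    )


def _locate_segment(segment: str, target: str, min_identity: float):
    """Best infix location of ``segment`` in ``target`` (leftmost on ties)."""
    res = edlib.align(segment, target, mode="HW", task="locations")
    if res["editDistance"] < 0:
        return None
    if 1.0 - res["editDistance"] / len(segment) < min_identity:
        return None
    start, end = res["locations"][0]
    return start, end + 1  # half-open


def validate_with_empty_site(
    call: TSDCall,
    record: str,
    empty_site: str,
    min_identity: float = 0.95,
    flank_window: int = 200,
) -> TSDCall:
    """Check a TSD call against the matched pre-insertion (empty-site) locus.

    The two structure flanks are mapped onto the empty site (last/first
    ``flank_window`` nt of each, >= ``min_identity``).  The call becomes
    VALIDATED when the flanks are contiguous in the empty site with exactly
    one copy of the repeat at the junction; REFUTED when the junction shows
    two copies (the repeat pre-existed: serendipitous, not a duplication) or
    none; UNVALIDATED when the flanks do not map.
    """
    if call.status == STATUS_ABSENT:
        raise ValueError("cannot validate an ABSENT TSD call")
    left_flank = record[: call.left_interval[0]]
    right_flank = record[call.right_interval[1] :]
    lseg = left_flank[-flank_window:]
    rseg = right_flank[:flank_window]
    if not lseg or not rseg or len(empty_site) < len(lseg) + len(rseg):
        return replace(call, status=STATUS_UNVALIDATED,
                       warnings=call.warnings + ("empty_site_too_short",))
    lloc = _locate_segment(lseg, empty_site, min_identity)
    rloc = _locate_segment(rseg, empty_site, min_identity)
    if lloc is None or rloc is None or lloc[1] > rloc[0]:
        return replace(call, status=STATUS_UNVALIDATED,
                       warnings=call.warnings + ("flanks_do_not_map",))
    junction = empty_site[lloc[1] : rloc[0]]
    if junction == call.tsd_seq:
        return replace(call, status=STATUS_VALIDATED)
    if junction == "" or junction == call.tsd_seq * 2:
        return replace(call, status=STATUS_REFUTED)
    return replace(call, status=STATUS_UNVALIDATED,
                   warnings=call.warnings + ("ambiguous_junction",))
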