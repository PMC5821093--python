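"""Infer excision breakpoints, deletion joints, and deletion lengths.

Given a decayed structure and its parental reference (real, from truth, or
reconstructed from an empty site), the analyzers here recover the sequence
signature of imprecise IS excision:

* :func:`align_to_parent` aligns the decayed sequence to the parent and
  extracts the large gap(s) — the removed region(s);
* :func:`find_deletion_joint` characterizes one gap: the microhomology
  (deletion joint) whose two parental copies were resolved to a single copy
  at the junction, with breakpoints normalized to the leftmost equivalent
  placement (a joint of length j allows j+1 equivalent placements);
* :func:`reconstruct_parent` builds the hypothetical parental insertion from
  an empty site plus a canonical transposon sequence, duplicating the
  inferred TSD;
* :func:`cohort_deletion_stats` summarizes deletion and joint lengths over a
  cohort.

The pairwise alignment itself is bit-parallel edit distance (edlib); gap
clusters are then contiguized exactly against the two sequences, so on
clean data the reconstruction identity ``parent with the removed interval
collapsed == decayed`` holds exactly and is asserted downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

__all__ = [
    "DeletionEvent",
    "CohortStats",
    "GapCandidate",
    "align_to_parent",
    "find_deletion_joint",
    "reconstruct_parent",
    "cohort_deletion_stats",
    "ReconstructionError",
]

PLACEMENT_UNIQUE = "unique"
PLACEMENT_AMBIGUOUS = "ambiguous_leftmost"
PLACEMENT_INEXACT = "inexact"

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class ReconstructionError(ValueError):
    """Raised when a decayed sequence cannot be mapped onto an empty site."""


@dataclass(frozen=True)
class GapCandidate:
    """One candidate removed region, in parent coordinates.

    ``exact`` is True when collapsing the gap reproduces the decayed
    sequence without mismatch in the surrounding windows.
    """

    start: int
    end: int
    child_pos: int
    exact: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DeletionEvent:
    """An inferred (or planted) excision, in parent coordinates."""

    record_id: str
    parent_id: str
    removed_interval: tuple[int, int]
    deletion_len: int
    joint_seq: str
    joint_len: int
    retained_up: str
    retained_down: str
    placement: str
    equivalence_class_size: int = 1

    def collapse(self, parent: str) -> str:
        """Parent with the removed interval collapsed (one joint copy kept)."""
        s, e = self.removed_interval
        return parent[:s] + parent[e:]


def _cigar_ops(cigar: str):
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _leftmost(parent: str, start: int, end: int) -> tuple[int, int]:
    """Slide a deletion window to its leftmost equivalent placement."""
    while start > 0 and parent[start - 1] == parent[end - 1]:
        start -= 1
        end -= 1
    return start, end


def align_to_parent(
    decayed: str,
    parent: str,
    min_gap: int = 20,
    cluster_sep: int = 10,
    window: int = 60,
) -> tuple[list[GapCandidate], list[str]]:
    """Gaps in a global alignment of ``decayed`` against ``parent``.

    Returns ``(gaps, warnings)``; each gap is a parent-coordinate interval
    normalized to the leftmost equivalent placement.  Runs of deleted parent
    bases separated by fewer than ``cluster_sep`` aligned columns are merged
    into one cluster and contiguized exactly.  A single dominant gap is the
    expected outcome for single-excision records; more than one large gap
    adds a ``multi_event`` warning (sequential excisions).
    """
    if not decayed or not parent:
        raise ValueError("sequences must be non-empty")
    if len(parent) < len(decayed):
        raise ValueError("parent must not be shorter than the decayed sequence")
    if parent == decayed:
        return [], []

    res = edlib.align(decayed, parent, mode="NW", task="path")
    ops = _cigar_ops(res["cigar"])

    # collect D runs (parent consumed, decayed not) with coordinates
    runs = []  # (parent_start, parent_end, child_pos)
    ppos = cpos = 0
    for n, op in ops:
        if op == "D":
            runs.append([ppos, ppos + n, cpos])
            ppos += n
        elif op == "I":
            cpos += n
        else:  # =, X, M consume both
            ppos += n
            cpos += n

    # cluster runs separated by few aligned columns
    clusters: list[list] = []
    for run in runs:
        if clusters and run[0] - clusters[-1][-1][1] <= cluster_sep:
            clusters[-1].append(run)
        else:
            clusters.append([run])

    gaps: list[GapCandidate] = []
    warnings: list[str] = []
    for cl in clusters:
        pa, pb = cl[0][0], cl[-1][1]
        ca, cb = cl[0][2], cl[-1][2]
        # exact contiguization in a window around the cluster
        A = max(0, pa - window)
        B = min(len(parent), pb + window)
        P = parent[A:B]
        ca0 = max(0, ca - (pa - A))
        C = decayed[ca0 : cb + (B - pb)]
        D_local = len(P) - len(C)
        lcp = 0
        while lcp < len(C) and lcp < len(P) and C[lcp] == P[lcp]:
            lcp += 1
        lcs = 0
        while (lcs < len(C) and lcs < len(P)
               and C[len(C) - 1 - lcs] == P[len(P) - 1 - lcs]):
            lcs += 1
        if lcp + lcs >= len(C) and D_local > 0:
            x0 = max(0, len(C) - lcs)
            start, end = A + x0, A + x0 + D_local
            start, end = _leftmost(parent, start, end)
            gaps.append(GapCandidate(start=start, end=end,
                                     child_pos=ca - (pa - start), exact=True))
        else:
            start, end = _leftmost(parent, pa, pb)
            gaps.append(GapCandidate(start=start, end=end,
                                     child_pos=max(0, ca - (pa - start)),
                                     exact=False))
            warnings.append("inexact_gap")

    gaps = [g for g in gaps if g.length >= min_gap]
    if len(gaps) > 1:
        warnings.append("multi_event")
    return gaps, warnings


def find_deletion_joint(
    parent: str,
    decayed: str,
    gap: GapCandidate | tuple[int, int],
    record_id: str = "query",
    parent_id: str = "parent",
    max_joint: int = 30,
    flank_report: int = 20,
) -> DeletionEvent:
    """Characterize the deletion joint of one gap.

    The joint is the maximal microhomology shared by the two removal
    boundaries in the parent — present twice in the parent, retained once at
    the junction of the decayed sequence.  Breakpoints are reported at the
    leftmost equivalent placement; a joint of length j makes j+1 placements
    equivalent, recorded in ``equivalence_class_size``.
    """
    if isinstance(gap, GapCandidate):
        start0, end0 = gap.start, gap.end
        exact = gap.exact
        child_pos = gap.child_pos
    else:
        start0, end0 = gap
        exact = True
        child_pos = start0
    start, end = _leftmost(parent, start0, end0)
    child_pos -= start0 - start
    d = end - start

    m = 0
    while (m < max_joint and start + m < len(parent) and end + m < len(parent)
           and parent[start + m] == parent[end + m]):
        m += 1
    joint_seq = parent[end : end + m]

    if not exact:
        placement = PLACEMENT_INEXACT
    elif m == 0:
        placement = PLACEMENT_UNIQUE
    else:
        placement = PLACEMENT_AMBIGUOUS

    junction = max(0, child_pos)  # child coordinate of the junction
    retained_up = decayed[max(0, junction - flank_report) : junction]
    retained_down = decayed[junction : junction + flank_report]
    return DeletionEvent(
        record_id=record_id,
        parent_id=parent_id,
        removed_interval=(start, end),
        deletion_len=d,
        joint_seq=joint_seq,
        joint_len=m,
        retained_up=retained_up,
        retained_down=retained_down,
        placement=placement,
        equivalence_class_size=m + 1,
    )


def reconstruct_parent(
    decayed: str,
    empty_site: str,
    canonical_transposon: str,
    bounds: tuple[int, int],
    tsd_len: int | None = None,
    max_tsd_len: int = 15,
    min_identity: float = 0.95,
    flank_window: int = 200,
) -> tuple[str, dict]:
    """Hypothetical parental insertion implied by an empty site.

    ``bounds`` is the structure interval in the decayed sequence (from
    annotation).  The TSD is inferred at the structure boundary (or taken
    from ``tsd_len`` when the right junction is ragged and the element's
    characteristic length is known), the left flank is mapped onto the
    empty site to fix the insertion position, and the canonical transposon
    is placed there with the TSD duplicated.

    Returns ``(parent_seq, meta)`` with ``meta['hypothetical'] = True``,
    the inferred insertion position and TSD.  Raises
    :class:`ReconstructionError` when the decayed flanks do not map onto the
    empty site.
    """
    from .tsd import detect_tsd

    if tsd_len is None:
        call = detect_tsd(decayed, bounds, max_len=max_tsd_len)
        t = call.tsd_len
    else:
        t = int(tsd_len)
    pos = bounds[0] - t
    left_flank = decayed[:pos]
    if len(left_flank) < 20:
        raise ReconstructionError("left flank too short to map")
    lseg = left_flank[-flank_window:]
    res = edlib.align(lseg, empty_site, mode="HW", task="locations")
    if (res["editDistance"] < 0
            or 1.0 - res["editDistance"] / len(lseg) < min_identity):
        raise ReconstructionError("decayed sequence does not map to empty site")
    # anchor: the left flank must end at `pos` in empty-site coordinates too
    end_in_empty = res["locations"][0][1] + 1
    if abs(end_in_empty - pos) > flank_window:
        raise ReconstructionError("left flank maps away from the junction")
    pos_empty = end_in_empty
    tsd = empty_site[pos_empty : pos_empty + t]
    meta = {
        "hypothetical": True,
        "insertion_pos": pos_empty,
        "tsd_seq": tsd,
        "tsd_len": t,
        "warnings": [] if t > 0 else ["no_tsd_evidence"],
    }
    parent = (empty_site[: pos_empty + t] + canonical_transposon
              + empty_site[pos_empty:])
    return parent, meta


@dataclass(frozen=True)
class CohortStats:
    """Descriptive statistics of deletion and joint lengths over a cohort."""

    n: int
    mean_deletion: float | None
    sd_deletion: float | None
    min_deletion: int | None
    max_deletion: int | None
    joint_len_histogram: dict = field(default_factory=dict)
    class_counts: dict = field(default_factory=dict)
    sd_convention: str = "sample (n-1)"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_deletion": self.mean_deletion,
            "sd_deletion": self.sd_deletion,
            "min_deletion": self.min_deletion,
            "max_deletion": self.max_deletion,
            "joint_len_histogram": dict(self.joint_len_histogram),
            "class_counts": dict(self.class_counts),
            "sd_convention": self.sd_convention,
        }


def cohort_deletion_stats(events, calls=()) -> CohortStats:
    """Summaries of inferred deletion events and structure calls.

    The standard deviation is the sample convention (n-1 denominator),
    recorded in the output metadata.
    """
    lengths = np.array([e.deletion_len for e in events], dtype=float)
    hist: dict[int, int] = {}
    for e in events:
        hist[e.joint_len] = hist.get(e.joint_len, 0) + 1
    class_counts: dict[str, int] = {}
    for c in calls:
        cls = getattr(c, "structure_class", c)
        class_counts[cls] = class_counts.get(cls, 0) + 1
    if len(lengths) == 0:
        return CohortStats(n=0, mean_deletion=None, sd_deletion=None,
                           min_deletion=None, max_deletion=None,
                           joint_len_histogram=hist, class_counts=class_counts)
    sd = float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0
    return CohortStats(
        n=int(len(lengths)),
        mean_deletion=float(np.mean(lengths)),
        sd_deletion=sd,
        min_deletion=int(lengths.min()),
        max_deletion=int(lengths.max()),
        joint_len_histogram=hist,
        class_counts=class_counts,
    )
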