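"""Simulator for the birth and decay of an IS-flanked composite transposon.

The generator reproduces, with machine-readable ground truth, the structural
grammar the analysis stages assume:

* a random host backbone (chromosome or linearized plasmid);
* insertion of an IS element with target-site duplication (TSD) —
  ``backbone[pos:pos+t]`` is duplicated on both sides of the element, or no
  duplication for rolling-circle elements;
* formation of an intact composite transposon: two direct-orientation IS
  copies around the cargo, with the ancestral AT/CG dinucleotides on the
  inside ends and a fresh outer TSD from the new target site;
* imprecise excision of either IS copy: a contiguous region about the length
  of the IS is removed between two copies of a short (1-10 bp) deletion
  joint, one copy of which survives at the junction — the sequence signature
  of abortive copy-out transposition.  The simulator is phenomenological: it
  plants the documented sequence outcome, not the strand chemistry.

When a requested joint does not occur naturally, the generator *engineers*
the microhomology (writes the joint into the upstream flank and pins its
maximality with one base on each side) and logs every touched position in
the truth record, so requested cohorts are always produced and the analysis
can still be scored exactly.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .catalog import CargoSpec, ISElementSpec, default_cargo, default_catalog

__all__ = [
    "TruthRecord",
    "SimRecord",
    "Cohort",
    "CohortConfig",
    "make_backbone",
    "plant_target_site",
    "choose_clean_site",
    "insert_with_tsd",
    "form_composite",
    "excise_is",
    "irr_retaining_variant",
    "simulate_cohort",
    "mutate_sequence",
    "REMNANT_GEOMETRIES",
]

TRUTH_SCHEMA_VERSION = "1.0"

#: IRR-retaining single-ended geometries: remnant length -> (deletion_len, joint_len)
REMNANT_GEOMETRIES = {42: (1030, 7), 90: (979, 10)}

_BASES = np.array(list("ACGT"))

CLASS_INTACT = "INTACT_COMPOSITE"
CLASS_SINGLE_UP = "SINGLE_UPSTREAM"
CLASS_SINGLE_DOWN = "SINGLE_DOWNSTREAM"
CLASS_NO_IS = "NO_IS"


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class TruthRecord:
    """Ground truth for one simulated locus.

    ``coords`` maps structural part names (``tsd_left``, ``up_is``, ``ie_up``,
    ``cargo``, ``ie_down``, ``down_is``, ``tsd_right``, ``down_remnant`` ...)
    to current 0-based half-open intervals in the record sequence; it is kept
    consistent through every planted event.
    """

    record_id: str
    backbone_len: int
    events: list = field(default_factory=list)
    class_label: str = CLASS_INTACT
    empty_site_id: str | None = None
    coords: dict = field(default_factory=dict)
    element_name: str = "ISApl1-like"
    tsd_recoverable: bool = True
    engineered_positions: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coords"] = {k: list(v) for k, v in self.coords.items()}
        return d


@dataclass
class SimRecord:
    """A simulated sequence plus its truth and (when decayed) its parent."""

    record_id: str
    seq: str
    truth: TruthRecord
    parent_seq: str | None = None
    empty_site_seq: str | None = None


# ---------------------------------------------------------------------------
# primitive operations


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_backbone(length: int, gc_fraction: float = 0.5, seed=None) -> str:
    """Random host backbone of exactly ``length`` nt with the given GC content.

    Bases are i.i.d. with P(G) = P(C) = gc_fraction/2.  Deterministic for a
    given seed.
    """
    if length < 100:
        raise ValueError("backbone length must be >= 100")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = _as_rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(_BASES[idx])


def plant_target_site(backbone: str, pos: int, site_seq: str) -> str:
    """Overwrite ``backbone[pos:pos+len(site_seq)]`` with a target-site motif.

    Used to plant the printed duplication sequences (e.g. GTAAA, CTAG,
    AAAAAATTG) before calling :func:`insert_with_tsd` at the same position.
    """
    if not 0 <= pos <= len(backbone) - len(site_seq):
        raise ValueError("target site out of range")
    return backbone[:pos] + site_seq + backbone[pos + len(site_seq):]


def _site_is_clean(backbone: str, pos: int, tsd_len: int, max_len: int = 15) -> bool:
    """True if an insertion at ``pos`` yields a flanking repeat of exactly
    ``tsd_len`` — i.e. no serendipitous longer repeat straddles the junctions.

    The junction repeat at length k compares ``backbone[pos+t-k:pos+t]``
    (left of the element) with ``backbone[pos:pos+k]`` (right of it),
    independent of the element sequence.
    """
    t = tsd_len
    for k in range(t + 1, max_len + 1):
        if pos + t - k < 0 or pos + k > len(backbone):
            break
        if backbone[pos + t - k : pos + t] == backbone[pos : pos + k]:
            return False
    return True


def choose_clean_site(
    backbone: str,
    rng,
    tsd_len: int,
    lo: int,
    hi: int,
    max_tries: int = 200,
) -> int:
    """Uniformly sample an insertion offset in [lo, hi) whose flanks will not
    extend the planted TSD by chance (rejection sampling; the reject set is a
    measure-~0 sliver of homopolymeric sites)."""
    rng = _as_rng(rng)
    for _ in range(max_tries):
        pos = int(rng.integers(lo, hi))
        if _site_is_clean(backbone, pos, tsd_len):
            return pos
    raise RuntimeError("could not find a clean insertion site")


def insert_with_tsd(
    backbone: str,
    element: ISElementSpec,
    pos: int,
    tsd_override: int | None = None,
) -> tuple[str, str]:
    """Insert an element at ``pos``, duplicating the target site.

    Returns ``(product, tsd_seq)``.  The ``t = tsd_len`` nucleotides starting
    at ``pos`` end up as a direct repeat on both sides of the element::

        backbone[:pos] + TSD + element + TSD + backbone[pos+t:]

    A 0-bp TSD (rolling-circle mechanism) inserts with no duplication and the
    product is exactly ``len(backbone) + element.length`` nt.
    """
    t = element.tsd_len if tsd_override is None else int(tsd_override)
    if t < 0:
        raise ValueError("tsd length must be >= 0")
    if not 0 <= pos <= len(backbone) - t:
        raise ValueError(f"insertion position {pos} out of range")
    tsd = backbone[pos : pos + t]
    product = backbone[: pos + t] + element.seq + backbone[pos:]
    return product, tsd


def mutate_sequence(seq: str, rate: float, rng) -> tuple[str, int]:
    """Apply i.i.d. point substitutions at the given per-base rate."""
    if rate <= 0:
        return seq, 0
    rng = _as_rng(rng)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        old = arr[i].decode()
        choices = [b for b in "ACGT" if b != old]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode(), len(hits)


# ---------------------------------------------------------------------------
# composite formation


def form_composite(
    backbone: str,
    cargo: CargoSpec,
    element: ISElementSpec,
    site: int,
    seed=None,
    record_id: str = "composite",
) -> tuple[str, TruthRecord]:
    """Build an intact composite transposon insertion at ``site``.

    Product layout (left to right): outer TSD copy, upstream IS, ancestral
    upstream dinucleotide (AT), cargo, ancestral downstream dinucleotide (CG),
    downstream IS, outer TSD copy.  Both IS copies are in direct orientation.
    """
    up_d, down_d = cargo.ancestral_flank
    unit = element.seq + up_d + cargo.seq + down_d + element.seq
    t = element.tsd_len
    if not 0 <= site <= len(backbone) - t:
        raise ValueError(f"insertion site {site} out of range")
    product = backbone[: site + t] + unit + backbone[site:]
    tsd = backbone[site : site + t]

    L, C = element.length, cargo.length
    s0 = site + t  # unit start in product
    coords = {
        "tsd_left": (site, site + t),
        "unit": (s0, s0 + len(unit)),
        "up_is": (s0, s0 + L),
        "ie_up": (s0 + L, s0 + L + 2),
        "cargo": (s0 + L + 2, s0 + L + 2 + C),
        "ie_down": (s0 + L + 2 + C, s0 + L + 4 + C),
        "down_is": (s0 + L + 4 + C, s0 + 2 * L + 4 + C),
        "tsd_right": (s0 + len(unit), s0 + len(unit) + t),
    }
    truth = TruthRecord(
        record_id=record_id,
        backbone_len=len(backbone),
        class_label=CLASS_INTACT,
        coords=coords,
        element_name=element.name,
    )
    truth.events.append(
        {
            "kind": "insertion",
            "element": element.name,
            "composite": True,
            "pos": site,
            "tsd_seq": tsd,
            "tsd_len": t,
            "ie_dinucs": [up_d, down_d],
        }
    )
    return product, truth


# ---------------------------------------------------------------------------
# imprecise excision


def _shift_coords(coords: dict, u: int, e0: int) -> dict:
    """Update feature intervals after removal of parent[u:e0]."""
    d = e0 - u
    out = {}
    for name, (s, e) in coords.items():
        if e <= u:  # entirely upstream of the removal
            out[name] = (s, e)
        elif s >= e0:  # entirely downstream: shift left
            out[name] = (s - d, e - d)
        else:  # overlaps the removed window: keep what survives
            left_len = max(0, u - s)
            right_len = max(0, e - e0)
            if left_len or right_len:
                start = s if left_len else u
                out[name] = (start, start + left_len + right_len)
            # fully removed features are dropped
    return out


def excise_is(
    parent: str,
    truth: TruthRecord,
    side: str,
    joint_len: int = 2,
    deletion_len: int | None = None,
    remnant_len: int = 0,
    seed=None,
) -> tuple[str, str, TruthRecord]:
    """Imprecisely excise the IS copy on one side of the composite.

    Removes a contiguous region of exactly ``deletion_len`` nt ending
    ``remnant_len`` nt before the IS right end, so the last ``remnant_len``
    nt of the IS (including its IRR whenever ``remnant_len >= irr_len``)
    survive.  A ``joint_len``-nt joint is present at both removal boundaries
    of the (possibly engineered) parent and retained exactly once at the
    junction of the product.

    Returns ``(child, parent_used, child_truth)`` where ``parent_used`` is
    the parent actually excised — identical to ``parent`` except for the
    logged microhomology-engineering positions.

    Raises ``KeyError``-derived state errors when the requested side carries
    no IS copy.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be 'upstream' or 'downstream'")
    key = "up_is" if side == "upstream" else "down_is"
    if key not in truth.coords:
        raise LookupError(f"no IS copy on the {side} side of {truth.record_id}")
    rng = _as_rng(seed)
    is_s, is_e = truth.coords[key]
    L = is_e - is_s
    if deletion_len is None:
        deletion_len = L
    j = int(joint_len)
    d = int(deletion_len)
    r = int(remnant_len)
    if not 0 <= r < L:
        raise ValueError("remnant_len must be in [0, element length)")
    if j < 0 or j > 10:
        raise ValueError("joint_len must be in 0..10")

    e0 = is_e - r
    u = e0 - d
    if u - j - 1 < 0:
        raise ValueError("deletion_len too large for this locus")

    p = list(parent)
    engineered: list[int] = []
    joint = "".join(p[e0 - j : e0])
    # engineer the upstream copy of the joint where it differs
    for i in range(j):
        if p[u - j + i] != joint[i]:
            p[u - j + i] = joint[i]
            engineered.append(u - j + i)
    # pin maximality: one mismatch immediately left of the joint pair ...
    if p[u - j - 1] == p[e0 - j - 1]:
        p[u - j - 1] = str(rng.choice([b for b in "ACGT" if b != p[e0 - j - 1]]))
        engineered.append(u - j - 1)
    # ... and one immediately right (inside the removed window: no child effect)
    if e0 < len(p) and p[u] == p[e0]:
        p[u] = str(rng.choice([b for b in "ACGT" if b != p[e0]]))
        engineered.append(u)

    parent_used = "".join(p)
    child = parent_used[:u] + parent_used[e0:]

    child_truth = copy.deepcopy(truth)
    child_truth.coords = _shift_coords(truth.coords, u, e0)
    child_truth.coords.pop(key, None)
    if r > 0:
        child_truth.coords[f"{'up' if side == 'upstream' else 'down'}_remnant"] = (u, u + r)
    child_truth.engineered_positions.extend(engineered)
    child_truth.events.append(
        {
            "kind": "excision",
            "side": side,
            "removed_interval": [u, e0],
            "deletion_len": d,
            "joint_seq": joint,
            "joint_len": j,
            "remnant_len": r,
            "engineered_positions": engineered,
        }
    )
    has_up = "up_is" in child_truth.coords
    has_down = "down_is" in child_truth.coords
    child_truth.class_label = (
        CLASS_INTACT if has_up and has_down
        else CLASS_SINGLE_UP if has_up
        else CLASS_SINGLE_DOWN if has_down
        else CLASS_NO_IS
    )
    # the outer junction stays annotatable only when a sizeable remnant or a
    # complete IS bounds it; otherwise the junction is ragged and a flanking
    # TSD cannot be attributed to the structure boundary
    if side == "downstream":
        child_truth.tsd_recoverable = truth.tsd_recoverable and r >= 20
    else:
        child_truth.tsd_recoverable = False
    return child, parent_used, child_truth


def irr_retaining_variant(
    seed=None,
    remnant_len: int = 42,
    backbone_len: int = 5000,
    catalog: dict | None = None,
    cargo: CargoSpec | None = None,
) -> SimRecord:
    """Single-ended variant retaining the last 42 (or 90) bp of the downstream
    IS, including its entire IRR.

    Encodes the published breakpoint geometry for these IRR-retaining
    structures: a 1,030-bp deletion with a 7-bp joint for the 42-bp remnant,
    and a 979-bp deletion with a 10-bp joint for the 90-bp remnant; in both
    the joint region reaches into the flank just upstream of the IS left end.
    """
    if remnant_len not in REMNANT_GEOMETRIES:
        raise ValueError(f"remnant_len must be one of {sorted(REMNANT_GEOMETRIES)}")
    deletion_len, joint_len = REMNANT_GEOMETRIES[remnant_len]
    catalog = catalog or default_catalog()
    cargo = cargo or default_cargo()
    element = catalog["ISApl1-like"]
    rng = _as_rng(seed)
    backbone = make_backbone(backbone_len, 0.5, rng)
    site = choose_clean_site(backbone, rng, element.tsd_len, 1100, backbone_len - 1100)
    parent, truth = form_composite(backbone, cargo, element, site,
                                   record_id=f"irr_retaining_r{remnant_len}")
    child, parent_used, child_truth = excise_is(
        parent, truth, "downstream",
        joint_len=joint_len, deletion_len=deletion_len, remnant_len=remnant_len,
        seed=rng,
    )
    return SimRecord(
        record_id=child_truth.record_id,
        seq=child,
        truth=child_truth,
        parent_seq=parent_used,
        empty_site_seq=backbone,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Class counts default to the four-architecture desk-scale mix; deletion
    lengths are drawn uniformly from the published 1,064-1,074 bp range and
    joints uniformly from the published 1-4 bp range.
    """

    n_intact: int = 5
    n_single_up: int = 5
    n_single_down: int = 1
    n_no_is: int = 5
    n_single_up_remnant: int = 0  # IRR-retaining 42-bp-remnant variants
    backbone_len: int = 5000
    gc_fraction: float = 0.5
    deletion_len_range: tuple[int, int] = (1064, 1074)
    joint_len_range: tuple[int, int] = (1, 4)
    empty_site_fraction: float = 1.0
    mutation_rate: float = 0.0
    nested_per_intact: int = 0  # nested insertions planted in intact records
    element_name: str = "ISApl1-like"

    def total(self) -> int:
        return (self.n_intact + self.n_single_up + self.n_single_down
                + self.n_no_is + self.n_single_up_remnant)


@dataclass
class Cohort:
    """Simulated records, matched empty sites, truth parents, and truth log."""

    records: list
    config: CohortConfig
    seed: int

    @property
    def empty_sites(self) -> dict[str, str]:
        return {
            f"{r.record_id}_empty": r.empty_site_seq
            for r in self.records
            if r.empty_site_seq is not None
        }

    @property
    def parents(self) -> dict[str, str]:
        return {r.record_id: r.parent_seq for r in self.records if r.parent_seq}

    def truth_json(self) -> dict:
        return {
            "schema_version": TRUTH_SCHEMA_VERSION,
            "seed": self.seed,
            "records": [r.truth.to_dict() for r in self.records],
        }

    def write(self, outdir) -> dict[str, Path]:
        from .io import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cohort": outdir / "cohort.fasta",
            "empty_sites": outdir / "empty_sites.fasta",
            "parents": outdir / "parents.fasta",
            "truth": outdir / "truth.json",
        }
        write_fasta([(r.record_id, r.seq) for r in self.records], paths["cohort"])
        write_fasta(sorted(self.empty_sites.items()), paths["empty_sites"])
        write_fasta(
            [(f"{rid}|parent", seq) for rid, seq in sorted(self.parents.items())],
            paths["parents"],
        )
        paths["truth"].write_text(json.dumps(self.truth_json(), indent=1))
        return paths


_NESTED_DEFAULT = ("Tn3-like", "ISKpn6-like", "IS1294-like")


def _nest_into_cargo(record: SimRecord, element: ISElementSpec, offset: int,
                     catalog_cargo: CargoSpec) -> None:
    """Plant a nested insertion inside a noncoding cargo interval (in place)."""
    cs, _ce = record.truth.coords["cargo"]
    nc_s, nc_e = catalog_cargo.noncoding_intervals[-1]
    pos = cs + nc_s + offset
    if pos + element.tsd_len > cs + nc_e:
        raise ValueError("nested insertion outside the noncoding interval")
    seq, tsd = insert_with_tsd(record.seq, element, pos)
    record.seq = seq
    shift = element.length + element.tsd_len
    new_coords = {}
    for name, (s, e) in record.truth.coords.items():
        if s >= pos + element.tsd_len:
            new_coords[name] = (s + shift, e + shift)
        elif e <= pos:
            new_coords[name] = (s, e)
        else:
            new_coords[name] = (s, e + shift)  # host feature grows around it
    new_coords[f"nested_{element.name}"] = (
        pos + element.tsd_len, pos + element.tsd_len + element.length
    )
    record.truth.coords = new_coords
    record.truth.events.append(
        {
            "kind": "insertion",
            "element": element.name,
            "composite": False,
            "pos": pos,
            "tsd_seq": tsd,
            "tsd_len": element.tsd_len,
            "nested": True,
        }
    )


def simulate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    catalog: dict | None = None,
    cargo: CargoSpec | None = None,
) -> Cohort:
    """Generate a cohort of loci across the four structure classes.

    Deterministic for a given (config, seed): every record draws from its own
    spawned substream, so adding classes does not reshuffle existing records.
    """
    config = config or CohortConfig()
    if config.total() <= 0:
        raise ValueError("cohort must contain at least one record")
    catalog = catalog or default_catalog()
    cargo = cargo or default_cargo()
    element = catalog[config.element_name]

    plan: list[tuple[str, str]] = []
    for label, n in (
        ("intact", config.n_intact),
        ("single_up", config.n_single_up),
        ("single_down", config.n_single_down),
        ("no_is", config.n_no_is),
        ("single_up_remnant", config.n_single_up_remnant),
    ):
        plan.extend((label, f"sim{i:04d}_{label}") for i in range(n))

    streams = np.random.SeedSequence(seed).spawn(len(plan))
    records: list[SimRecord] = []
    dl_lo, dl_hi = config.deletion_len_range
    jl_lo, jl_hi = config.joint_len_range

    for (label, rid), stream in zip(plan, streams):
        rng = np.random.default_rng(stream)
        backbone = make_backbone(config.backbone_len, config.gc_fraction, rng)
        site = choose_clean_site(
            backbone, rng, element.tsd_len, 1100,
            max(1101, config.backbone_len - 1100),
        )
        parent, truth = form_composite(backbone, cargo, element, site, record_id=rid)

        def draw_geom():
            return (int(rng.integers(jl_lo, jl_hi + 1)),
                    int(rng.integers(dl_lo, dl_hi + 1)))

        parent_seq: str | None = None
        if label == "intact":
            child, child_truth = parent, truth
            for k in range(config.nested_per_intact):
                nested = catalog[_NESTED_DEFAULT[k % len(_NESTED_DEFAULT)]]
                rec_tmp = SimRecord(rid, child, child_truth)
                _nest_into_cargo(rec_tmp, nested, 10 + 30 * k, cargo)
                child, child_truth = rec_tmp.seq, rec_tmp.truth
        elif label == "single_up":
            j, d = draw_geom()
            child, parent_seq, child_truth = excise_is(
                parent, truth, "downstream", joint_len=j, deletion_len=d, seed=rng)
        elif label == "single_up_remnant":
            d, j = REMNANT_GEOMETRIES[42]
            child, parent_seq, child_truth = excise_is(
                parent, truth, "downstream", joint_len=j, deletion_len=d,
                remnant_len=42, seed=rng)
        elif label == "single_down":
            j, d = draw_geom()
            child, parent_seq, child_truth = excise_is(
                parent, truth, "upstream", joint_len=j, deletion_len=d, seed=rng)
        else:  # no_is: two successive excisions, downstream first
            j, d = draw_geom()
            mid, parent_seq, mid_truth = excise_is(
                parent, truth, "downstream", joint_len=j, deletion_len=d, seed=rng)
            j2, d2 = draw_geom()
            child, parent_seq2, child_truth = excise_is(
                mid, mid_truth, "upstream", joint_len=j2, deletion_len=d2, seed=rng)
            # re-apply the second event's engineering to the composite parent:
            # those positions lie upstream of the first removal window, so the
            # coordinates coincide in parent and intermediate frames
            p = list(parent_seq)
            for pos in child_truth.events[-1]["engineered_positions"]:
                p[pos] = parent_seq2[pos]
            parent_seq = "".join(p)

        if config.mutation_rate > 0:
            child, _n = mutate_sequence(child, config.mutation_rate, rng)

        child_truth.class_label = _expected_class(child_truth)
        rec = SimRecord(record_id=rid, seq=child, truth=child_truth,
                        parent_seq=parent_seq)
        if rng.random() < config.empty_site_fraction:
            rec.empty_site_seq = backbone
            child_truth.empty_site_id = f"{rid}_empty"
        records.append(rec)

    return Cohort(records=records, config=config, seed=seed)


def _expected_class(truth: TruthRecord) -> str:
    has_up = "up_is" in truth.coords
    has_down = "down_is" in truth.coords
    if has_up and has_down:
        return CLASS_INTACT
    if has_up:
        return CLASS_SINGLE_UP
    if has_down:
        return CLASS_SINGLE_DOWN
    return CLASS_NO_IS
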