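"""Pipeline orchestration: annotate -> classify -> TSD -> excision -> stats.

The pipeline consumes FASTA queries (plus optional matched empty sites and
parental references), applies the flanking-sequence filter used for cohort
curation (records need more than ``flank_min`` nt of sequence on both sides
of the cargo), and emits a per-record TSV report, per-event TSV/JSON,
cohort statistics JSON, GFF3 feature annotations, and a log carrying a
configuration hash.  Per-record failures are quarantined and the run
continues; identical config + inputs give byte-identical outputs.

TSD calls are only attempted when both outer structure boundaries are
annotatable (a complete IS copy or a sizeable remnant); the ragged junction
left by a complete excision does not define a boundary to which a flanking
repeat could be attributed, and such records report ABSENT.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .annotate import AlignParams, StructureAnnotation, annotate_locus, locate_feature
from .catalog import CargoSpec, ISElementSpec, default_cargo, default_catalog
from .classify import ClassificationError, StructureCall, classify_structure
from .excision import (DeletionEvent, align_to_parent, cohort_deletion_stats,
                       find_deletion_joint)
from .io import gff3_line, read_fasta, write_gff3, write_json
from .tsd import STATUS_ABSENT, TSDCall, detect_tsd, validate_with_empty_site

__all__ = ["PipelineConfig", "RecordResult", "RunResult", "filter_cohort",
           "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and references for one pipeline run."""

    catalog: dict[str, ISElementSpec] = field(default_factory=default_catalog)
    cargo: CargoSpec = field(default_factory=default_cargo)
    flank_min: int = 1000
    align_params: AlignParams = field(default_factory=AlignParams)
    primary_element: str = "ISApl1-like"
    irr_identity: float = 0.95
    max_tsd_len: int = 15
    min_gap: int = 20
    seed: int = 0
    apply_flank_filter: bool = False

    def config_hash(self) -> str:
        payload = {
            "flank_min": self.flank_min,
            "align_params": self.align_params.__dict__,
            "primary_element": self.primary_element,
            "irr_identity": self.irr_identity,
            "max_tsd_len": self.max_tsd_len,
            "min_gap": self.min_gap,
            "seed": self.seed,
            "apply_flank_filter": self.apply_flank_filter,
            "catalog": {k: v.seq for k, v in sorted(self.catalog.items())},
            "cargo": self.cargo.seq,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RecordResult:
    record_id: str
    annotation: StructureAnnotation | None = None
    call: StructureCall | None = None
    tsd: TSDCall | None = None
    events: list = field(default_factory=list)
    error: str | None = None


@dataclass
class RunResult:
    records: list
    quarantined: list
    dropped: list
    stats: dict
    config_hash: str

    def report_rows(self) -> list[dict]:
        rows = []
        for r in self.records:
            if r.error:
                continue
            rows.append(
                {
                    "record_id": r.record_id,
                    "class": r.call.structure_class,
                    "remnant_len": r.call.downstream_remnant_len,
                    "irr_intact": r.call.irr_intact,
                    "mobility": r.call.mobility,
                    "nested": ",".join(r.call.nested_insertions) or "-",
                    "tsd_seq": r.tsd.tsd_seq if r.tsd else "-",
                    "tsd_len": r.tsd.tsd_len if r.tsd else 0,
                    "tsd_status": r.tsd.status if r.tsd else STATUS_ABSENT,
                    "chance_prob": (f"{r.tsd.chance_prob:.4g}" if r.tsd else "1"),
                    "n_events": len(r.events),
                    "deletion_lens": ";".join(
                        str(e.deletion_len) for e in r.events) or "-",
                    "joint_lens": ";".join(
                        str(e.joint_len) for e in r.events) or "-",
                }
            )
        return rows


def filter_cohort(
    records: list[tuple[str, str]],
    cargo: CargoSpec,
    flank_min: int = 1000,
    params: AlignParams | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Keep records with more than ``flank_min`` nt on each side of the cargo.

    Returns ``(kept, dropped_with_reasons)``; a record with no cargo hit is
    dropped with reason ``no_cargo``.  The bound is strict (a 1,000-nt flank
    at flank_min = 1,000 is dropped).
    """
    params = params or AlignParams()
    kept, dropped = [], []
    for rid, seq in records:
        try:
            hits = locate_feature(seq, cargo.seq, params=params,
                                  feature_name="cargo")
        except ValueError:
            dropped.append((rid, "no_cargo"))
            continue
        if not hits:
            dropped.append((rid, "no_cargo"))
            continue
        span_s = min(h.start for h in hits)
        span_e = max(h.end for h in hits)
        left, right = span_s, len(seq) - span_e
        if left <= flank_min:
            dropped.append((rid, "left_flank"))
        elif right <= flank_min:
            dropped.append((rid, "right_flank"))
        else:
            kept.append((rid, seq))
    return kept, dropped


def _structure_bounds(ann: StructureAnnotation, primary: str) -> tuple[int, int] | None:
    """Outer bounds of the structure, when both boundaries are annotatable.

    The left boundary is a complete primary IS (or the cargo when no
    upstream IS survives — then no TSD can flank the structure and None is
    returned); the right boundary is a complete primary IS or a remnant hit.
    """
    cargo_hits = ann.cargo_hits
    if not cargo_hits:
        return None
    span_s = min(h.start for h in cargo_hits)
    span_e = max(h.end for h in cargo_hits)
    left = [h for h in ann.is_hits
            if h.name == primary and h.complete and h.end <= span_s + 10]
    right = [h for h in ann.is_hits
             if h.name == primary and h.start >= span_e - 10]
    if not left or not right:
        return None
    return min(h.start for h in left), max(h.end for h in right)


def run_pipeline(
    config: PipelineConfig,
    queries: list[tuple[str, str]] | str | Path,
    empty_sites: dict[str, str] | str | Path | None = None,
    parents: dict[str, tuple[str, str]] | str | Path | None = None,
    outdir: str | Path | None = None,
) -> RunResult:
    """Run the full analysis over a cohort.

    ``queries`` is a FASTA path or (id, seq) pairs.  ``empty_sites`` maps
    ``<record_id>_empty`` ids to pre-insertion sequences; ``parents`` maps
    record ids to ``(parent_id, parent_seq)`` (FASTA ids ``<id>|parent``).
    """
    if isinstance(queries, (str, Path)):
        queries = read_fasta(queries)
    if isinstance(empty_sites, (str, Path)):
        empty_sites = dict(read_fasta(empty_sites))
    empty_sites = empty_sites or {}
    if isinstance(parents, (str, Path)):
        parents = {
            rid.split("|")[0]: (rid, seq) for rid, seq in read_fasta(parents)
        }
    parents = parents or {}

    dropped: list[tuple[str, str]] = []
    if config.apply_flank_filter:
        queries, dropped = filter_cohort(
            queries, config.cargo, config.flank_min, config.align_params)

    results: list[RecordResult] = []
    quarantined: list[tuple[str, str]] = []
    for rid, seq in queries:
        res = RecordResult(record_id=rid)
        try:
            ann = annotate_locus(seq, config.catalog, config.cargo,
                                 params=config.align_params, record_id=rid)
            res.annotation = ann
            res.call = classify_structure(
                ann, config.catalog, record=seq,
                primary_element=config.primary_element,
                irr_identity=config.irr_identity,
                params=config.align_params,
            )
            bounds = _structure_bounds(ann, config.primary_element)
            if bounds is not None:
                call = detect_tsd(seq, bounds, max_len=config.max_tsd_len,
                                  record_id=rid)
                empty = empty_sites.get(f"{rid}_empty")
                if empty is not None and call.status != STATUS_ABSENT:
                    call = validate_with_empty_site(call, seq, empty)
                res.tsd = call
            if rid in parents:
                parent_id, parent_seq = parents[rid]
                gaps, _warn = align_to_parent(seq, parent_seq,
                                              min_gap=config.min_gap)
                for gap in gaps:
                    res.events.append(
                        find_deletion_joint(parent_seq, seq, gap,
                                            record_id=rid, parent_id=parent_id)
                    )
        except (ClassificationError, ValueError, LookupError) as exc:
            res.error = f"{type(exc).__name__}: {exc}"
            quarantined.append((rid, res.error))
        results.append(res)

    all_events = [e for r in results for e in r.events]
    all_calls = [r.call for r in results if r.call is not None]
    stats = cohort_deletion_stats(all_events, all_calls).to_dict()
    run = RunResult(
        records=results,
        quarantined=quarantined,
        dropped=dropped,
        stats=stats,
        config_hash=config.config_hash(),
    )
    if outdir is not None:
        _write_outputs(run, Path(outdir))
    return run


def _write_outputs(run: RunResult, outdir: Path) -> None:
    import csv

    outdir.mkdir(parents=True, exist_ok=True)
    rows = run.report_rows()
    with open(outdir / "report.tsv", "w", newline="") as fh:
        fieldnames = list(rows[0]) if rows else ["record_id"]
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)
    with open(outdir / "events.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["record_id", "parent_id", "removed_start",
                         "removed_end", "deletion_len", "joint_seq",
                         "joint_len", "placement", "retained_up",
                         "retained_down"])
        for r in run.records:
            for e in r.events:
                writer.writerow([
                    e.record_id, e.parent_id, *e.removed_interval,
                    e.deletion_len, e.joint_seq, e.joint_len, e.placement,
                    e.retained_up, e.retained_down,
                ])
    gff_lines = []
    for r in run.records:
        if r.annotation is None:
            continue
        hits = list(r.annotation.cargo_hits) + list(r.annotation.is_hits)
        for h in sorted(hits, key=lambda h: (h.start, h.end)):
            gff_lines.append(
                gff3_line(
                    r.record_id,
                    "mobile_genetic_element" if h.name != "cargo" else "region",
                    h.start, h.end, h.strand, h.score,
                    ID=f"{r.record_id}:{h.name}:{h.start}",
                    identity=f"{h.pct_identity:.4f}",
                    complete=str(h.complete).lower(),
                    remnant_len=h.remnant_len,
                )
            )
    write_gff3(gff_lines, outdir / "annotations.gff3")
    write_json(run.stats, outdir / "cohort_stats.json")
    write_json(
        {
            "config_hash": run.config_hash,
            "n_records": len(run.records),
            "n_quarantined": len(run.quarantined),
            "quarantined": run.quarantined,
            "dropped": run.dropped,
        },
        outdir / "run_log.json",
    )
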