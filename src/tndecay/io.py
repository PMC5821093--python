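"""FASTA / GFF3 / TSV / JSON input-output helpers.

Sequences travel as plain ``(id, sequence)`` pairs; FASTA is read and
written with Biopython (60-column wrapping).  Coordinates are 0-based
half-open everywhere in memory and converted to 1-based inclusive only on
GFF3 emission.
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "gff3_line", "write_gff3", "write_json"]


def read_fasta(path) -> list[tuple[str, str]]:
    """All records of a FASTA file as (id, uppercase sequence) pairs."""
    return [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records, path, descriptions=None) -> None:
    """Write (id, seq) pairs as 60-column-wrapped FASTA."""
    descriptions = descriptions or {}
    seqrecords = [
        SeqRecord(Seq(seq), id=rid, description=descriptions.get(rid, ""))
        for rid, seq in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def gff3_line(
    seqid: str,
    feature_type: str,
    start: int,
    end: int,
    strand: str = "+",
    score=".",
    source: str = "tndecay",
    **attributes,
) -> str:
    """One GFF3 feature line; start/end are 0-based half-open and converted."""
    attr = ";".join(f"{k}={v}" for k, v in attributes.items()) or "."
    score_s = f"{score:.3g}" if isinstance(score, float) else str(score)
    return "\t".join(
        [seqid, source, feature_type, str(start + 1), str(end), score_s,
         strand, ".", attr]
    )


def write_gff3(lines, path) -> None:
    Path(path).write_text("##gff-version 3\n" + "\n".join(lines) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
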