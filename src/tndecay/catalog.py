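"""Reference catalog of IS elements and the mcr-1/pap2 cargo region.

An :class:`ISElementSpec` describes one insertion sequence: its full
reference sequence, the terminal inverted repeats (IRL at the left end, IRR
at the right end) that the transposase recognizes, the length of the target
site duplication (TSD) it generates on insertion, and its transposition
mechanism class.  DDE-type IS30-family elements transpose copy-out/paste-in
and duplicate a short target motif (2 bp for the ISApl1-like default);
rolling-circle elements (IS1294-like) integrate without any duplication.

The default catalog is a set of synthetic stand-ins with the published
dimensions of the real elements (ISApl1: 1,070 bp with a 27-bp IRR; cargo:
2,609 bp ending in a 765-bp pap2 ORF).  Real FASTA catalogs can be supplied
instead; nothing downstream depends on the synthetic sequences themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ISElementSpec",
    "CargoSpec",
    "revcomp",
    "default_catalog",
    "default_cargo",
    "DEFAULT_IS_LENGTH",
    "DEFAULT_IRR_LENGTH",
    "DEFAULT_CARGO_LENGTH",
    "PAP2_LENGTH",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: dimensions of the ISApl1-like default element and the mcr-1 cargo region
DEFAULT_IS_LENGTH = 1070
DEFAULT_IRR_LENGTH = 27
DEFAULT_CARGO_LENGTH = 2609
PAP2_LENGTH = 765

# fixed internal seed so the synthetic catalog is identical across sessions
_CATALOG_SEED = 241_070

_BASES = np.array(list("ACGT"))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ISElementSpec:
    """One catalog entry for an insertion sequence.

    Parameters
    ----------
    name : str
        Opaque label ("ISApl1-like", ...).  Names from the literature are
        treated as labels only; no family logic hangs off them.
    seq : str
        Full element sequence, IRL first, IRR last.
    irl_len, irr_len : int
        Lengths of the terminal inverted repeats (prefix / suffix of ``seq``).
    tsd_len : int
        Characteristic target site duplication length; 0 for rolling-circle
        elements, which integrate without duplicating the target.
    mechanism : {"ddE_copy_out", "rolling_circle"}
    target_bias : {"at_rich", "none"}
        Insertion-site preference (informational).
    """

    name: str
    seq: str
    irl_len: int = 27
    irr_len: int = DEFAULT_IRR_LENGTH
    tsd_len: int = 2
    mechanism: str = "ddE_copy_out"
    target_bias: str = "none"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("element sequence must be non-empty")
        if self.irl_len + self.irr_len > len(self.seq):
            raise ValueError("terminal repeats longer than the element")
        if (self.tsd_len == 0) != (self.mechanism == "rolling_circle"):
            raise ValueError("tsd_len == 0 iff mechanism == 'rolling_circle'")
        if self.mechanism not in ("ddE_copy_out", "rolling_circle"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def irl_seq(self) -> str:
        return self.seq[: self.irl_len]

    @property
    def irr_seq(self) -> str:
        return self.seq[-self.irr_len :]


@dataclass(frozen=True)
class CargoSpec:
    """The mobilized cargo region: mcr-1 plus the pap2 ORF.

    The pap2 interval is 765 bp and ends at the cargo 3' end; the cargo is
    flanked in its ancestral chromosome by the AT (upstream) and CG
    (downstream) dinucleotides that become the inside-end fingerprints of
    every intact composite transposon built from it.
    """

    seq: str
    mcr1_interval: tuple[int, int] = (100, 1726)
    pap2_interval: tuple[int, int] = (DEFAULT_CARGO_LENGTH - PAP2_LENGTH, DEFAULT_CARGO_LENGTH)
    noncoding_intervals: tuple[tuple[int, int], ...] = ((0, 100), (1726, 1844))
    ancestral_flank: tuple[str, str] = ("AT", "CG")

    def __post_init__(self) -> None:
        n = len(self.seq)
        ps, pe = self.pap2_interval
        if pe - ps != PAP2_LENGTH:
            raise ValueError(f"pap2 interval must be {PAP2_LENGTH} bp")
        for s, e in (self.mcr1_interval, self.pap2_interval, *self.noncoding_intervals):
            if not (0 <= s <= e <= n):
                raise ValueError(f"interval ({s}, {e}) outside cargo [0, {n})")
        for dinuc in self.ancestral_flank:
            if len(dinuc) != 2:
                raise ValueError("ancestral flank dinucleotides must be 2 nt")

    @property
    def length(self) -> int:
        return len(self.seq)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _make_element(
    rng: np.random.Generator,
    name: str,
    length: int,
    *,
    irl_len: int = 27,
    irr_len: int = 27,
    tsd_len: int = 2,
    mechanism: str = "ddE_copy_out",
    target_bias: str = "none",
) -> ISElementSpec:
    # IRR approximately the reverse complement of IRL, as in real IS ends
    irl = _random_dna(rng, irl_len)
    irr = list(revcomp(irl))[-irr_len:] if irr_len <= irl_len else list(
        _random_dna(rng, irr_len - irl_len) + revcomp(irl)
    )
    # two mismatches: terminal IRs are near- but not perfect inverted repeats
    for pos in rng.choice(len(irr) - 2, size=2, replace=False):
        irr[pos + 1] = str(rng.choice([b for b in "ACGT" if b != irr[pos + 1]]))
    core = _random_dna(rng, length - irl_len - irr_len)
    return ISElementSpec(
        name=name,
        seq=irl + core + "".join(irr),
        irl_len=irl_len,
        irr_len=irr_len,
        tsd_len=tsd_len,
        mechanism=mechanism,
        target_bias=target_bias,
    )


def default_catalog() -> dict[str, ISElementSpec]:
    """Synthetic stand-in catalog with the published element dimensions.

    Returns a name-keyed dict; the ISApl1-like element (1,070 bp, 27-bp IRR,
    2-bp TSD) is the primary composite-forming element, the others are the
    nested-insertion elements with their printed TSD lengths: Tn3-like 5 bp,
    ISKpn6-like 4 bp, IS1A-like 9 bp, and the 0-bp rolling-circle IS1294-like.
    """
    rng = np.random.default_rng(_CATALOG_SEED)
    elements = [
        _make_element(rng, "ISApl1-like", DEFAULT_IS_LENGTH, tsd_len=2,
                      target_bias="at_rich"),
        _make_element(rng, "Tn3-like", 980, tsd_len=5),
        _make_element(rng, "ISKpn6-like", 820, tsd_len=4),
        _make_element(rng, "IS1A-like", 768, tsd_len=9),
        _make_element(rng, "IS1294-like", 900, tsd_len=0,
                      mechanism="rolling_circle"),
    ]
    return {e.name: e for e in elements}


def default_cargo() -> CargoSpec:
    """Synthetic 2,609-bp cargo with nominal mcr-1/pap2/noncoding intervals."""
    rng = np.random.default_rng(_CATALOG_SEED + 1)
    return CargoSpec(seq=_random_dna(rng, DEFAULT_CARGO_LENGTH))
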