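"""Edge-bait construction from a TE or retrovirus reference sequence.

A bait set holds four probes of length ``L``: the first and last ``L`` bases of
the element (the junction-forming edges of an LTR or provirus) and their
reverse complements, so that chimeric reads from either strand and either
junction can be recognised.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

from .formats import FormatError, read_fasta

__all__ = ["BAIT_KEYS", "BaitSet", "reverse_complement", "make_baits", "baits_from_fasta"]

#: Fixed bait order, also the tie-break order when a read matches several baits.
BAIT_KEYS = ("five_prime_fwd", "five_prime_rc", "three_prime_fwd", "three_prime_rc")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NUCLEOTIDES = frozenset("ACGTN")

DEFAULT_BAIT_LENGTH = 15


def reverse_complement(seq: str) -> str:
    """Reverse complement over A/C/G/T/N (N maps to N); rejects other characters."""
    seq = seq.upper()
    if set(seq) - _NUCLEOTIDES:
        bad = sorted(set(seq) - _NUCLEOTIDES)
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BaitSet:
    """The four edge-derived probes of one TE/virus reference."""

    source_name: str
    bait_length: int
    baits: dict[str, str]

    def __post_init__(self) -> None:
        if tuple(self.baits) != BAIT_KEYS:
            raise ValueError(f"baits must be keyed exactly {BAIT_KEYS}")
        for key, bait in self.baits.items():
            if len(bait) != self.bait_length:
                raise ValueError(f"bait {key} has length {len(bait)} != {self.bait_length}")
        if self.baits["five_prime_rc"] != reverse_complement(self.baits["five_prime_fwd"]):
            raise ValueError("five_prime_rc is not the reverse complement of five_prime_fwd")
        if self.baits["three_prime_rc"] != reverse_complement(self.baits["three_prime_fwd"]):
            raise ValueError("three_prime_rc is not the reverse complement of three_prime_fwd")

    def ordered(self) -> tuple[str, ...]:
        """Bait sequences in the fixed :data:`BAIT_KEYS` order."""
        return tuple(self.baits[k] for k in BAIT_KEYS)


def make_baits(te_sequence: str, bait_length: int = DEFAULT_BAIT_LENGTH, source_name: str = "") -> BaitSet:
    """Build the four edge baits of ``te_sequence``.

    Requires ``len(te_sequence) >= 2 * bait_length`` so the two edges do not
    overlap, and ``bait_length >= 8`` (shorter probes make seeding degenerate).
    Degenerate IUPAC codes are rejected; only A/C/G/T references are handled.
    """
    if bait_length < 8:
        raise ValueError(f"bait_length {bait_length} < 8: seeding becomes degenerate")
    seq = te_sequence.upper()
    if set(seq) - frozenset("ACGT"):
        bad = sorted(set(seq) - frozenset("ACGT"))
        raise ValueError(f"TE reference contains non-ACGT characters {bad}; degenerate codes are not expanded")
    if len(seq) < 2 * bait_length:
        raise ValueError(
            f"TE reference of length {len(seq)} is shorter than 2*bait_length={2 * bait_length}; "
            f"choose a smaller bait length"
        )
    five = seq[:bait_length]
    three = seq[-bait_length:]
    return BaitSet(
        source_name=source_name,
        bait_length=bait_length,
        baits={
            "five_prime_fwd": five,
            "five_prime_rc": reverse_complement(five),
            "three_prime_fwd": three,
            "three_prime_rc": reverse_complement(three),
        },
    )


def baits_from_fasta(path: Union[str, Path], bait_length: int = DEFAULT_BAIT_LENGTH) -> list[BaitSet]:
    """One :class:`BaitSet` per sequence in a TE reference FASTA."""
    sequences = read_fasta(path)
    if not sequences:
        raise FormatError(f"no sequences in TE reference {path}")
    return [make_baits(seq, bait_length, name) for name, seq in sequences.items()]
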