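"""Sequence utilities for self-complementary (palindromic) DNA duplexes.

Short palindromic oligonucleotides are the workhorse of intercalation
sequence-specificity studies: two copies of one strand form a symmetric
duplex, so every dinucleotide step appears in a well-defined equivalence
class under reverse complementation (the familiar ``XY/X'Y'`` slash
notation).  This module provides reverse complementation, palindrome
validation, canonical dinucleotide-step enumeration and the location of
NTAN tetranucleotide binding sites (a central 5'-TA-3' step with variable
flanks), the sequence unit at which TA-specific intercalators read
double-stranded DNA.

Coordinates are 0-based and half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

__all__ = [
    "DuplexSequence",
    "DinucleotideStep",
    "reverse_complement",
    "is_self_complementary",
    "unique_dinucleotide_steps",
    "canonical_step",
    "steps_in_duplex",
    "find_ntan_sites",
]


def _validate_sequence(seq: str) -> str:
    """Uppercase ``seq`` and reject anything outside strict A/C/G/T."""
    if not isinstance(seq, str) or len(seq) == 0:
        raise ValidationError("sequence must be a non-empty string")
    up = seq.upper()
    for i, base in enumerate(up):
        if base not in "ACGT":
            raise ValidationError(
                f"invalid nucleotide {base!r} at position {i} (only A/C/G/T accepted)"
            )
    return up


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of ``seq``.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    Case-insensitive input; output is uppercase.
    """
    return _validate_sequence(seq).translate(_COMPLEMENT)[::-1]


def is_self_complementary(seq: str) -> bool:
    """True iff ``seq`` equals its own reverse complement.

    Only even-length sequences can be palindromic in the Watson-Crick
    sense (a central base would have to pair with itself).
    """
    up = _validate_sequence(seq)
    return up == up.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DuplexSequence:
    """A self-complementary strand and the duplex it forms with its own copy.

    ``pairs[i] == (i, length - 1 - i)`` pairs position ``i`` of strand A
    with position ``length - 1 - i`` of the (identical) strand B; the
    duplex therefore has exactly ``length`` Watson-Crick base pairs, each
    A.T/T.A or G.C/C.G by construction.
    """

    strand: str
    pairs: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        up = _validate_sequence(self.strand)
        if not is_self_complementary(up):
            raise ValidationError(
                f"strand {up!r} is not self-complementary; only palindromic "
                "duplexes are supported"
            )
        object.__setattr__(self, "strand", up)
        object.__setattr__(
            self, "pairs", [(i, len(up) - 1 - i) for i in range(len(up))]
        )

    @property
    def length(self) -> int:
        """Number of base pairs in the duplex (== strand length)."""
        return len(self.strand)

    def base_pair(self, i: int) -> tuple[str, str]:
        """Bases of pair ``i``: (strand A base, strand B partner base)."""
        a, b = self.pairs[i]
        return self.strand[a], self.strand[b]

    def is_terminal(self, i: int) -> bool:
        return i == 0 or i == self.length - 1


@dataclass(frozen=True)
class DinucleotideStep:
    """A dinucleotide step as an equivalence class under reverse complement.

    ``canonical_label`` is the lexicographically smaller of the step and
    its reverse complement; exactly 10 classes exist, of which AT, TA, GC
    and CG are their own reverse complements (singleton classes).
    """

    canonical_label: str

    def __post_init__(self) -> None:
        up = _validate_sequence(self.canonical_label)
        if len(up) != 2:
            raise ValidationError("a dinucleotide step has exactly 2 bases")
        if up != min(up, reverse_complement(up)):
            raise ValidationError(
                f"{up!r} is not canonical (use {min(up, reverse_complement(up))!r})"
            )
        object.__setattr__(self, "canonical_label", up)

    @property
    def equivalence_class(self) -> frozenset[str]:
        return frozenset({self.canonical_label, reverse_complement(self.canonical_label)})


def canonical_step(step: str) -> str:
    """Canonical label (lexicographic min of step and its reverse complement)."""
    up = _validate_sequence(step)
    if len(up) != 2:
        raise ValidationError("a dinucleotide step has exactly 2 bases")
    return min(up, reverse_complement(up))


def unique_dinucleotide_steps() -> set[DinucleotideStep]:
    """The 10 distinct dinucleotide steps of double-stranded DNA.

    The 16 dinucleotides collapse to 10 classes under reverse-complement
    equivalence: 6 doubleton classes (e.g. CT/AG) and 4 singletons
    (AT, TA, GC, CG).
    """
    return {
        DinucleotideStep(canonical_step(a + b))
        for a in "ACGT"
        for b in "ACGT"
    }


def steps_in_duplex(seq: str) -> list[tuple[int, str]]:
    """Canonicalized dinucleotide steps along a palindromic duplex.

    Returns one ``(start, canonical_label)`` entry per adjacent base-pair
    step (``len(seq) - 1`` entries), 0-based start positions.
    """
    up = _validate_sequence(seq)
    if not is_self_complementary(up):
        raise ValidationError(
            f"steps_in_duplex requires a self-complementary sequence, got {up!r}"
        )
    return [(i, canonical_step(up[i : i + 2])) for i in range(len(up) - 1)]


def find_ntan_sites(seq: str) -> list[tuple[int, str]]:
    """All NTAN tetranucleotide windows (N = any base, central 5'-TA-3').

    Returns ``(start, site)`` for every 4-nt window whose middle two bases
    are TA, half-open ``[start, start + 4)``.  The central TA step is the
    intercalation cavity; the flanking Ns set its sequence context.
    """
    up = _validate_sequence(seq)
    return [
        (i, up[i : i + 4])
        for i in range(len(up) - 3)
        if up[i + 1 : i + 3] == "TA"
    ]
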