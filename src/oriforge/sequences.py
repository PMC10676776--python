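"""Validated DNA sequences and phase decomposition.

A sequence of length n is split into three phase subsequences by position
modulo 3 (1-based): phase i collects the bases at positions i, i+3, i+6, ...
This codon-like decomposition lets composition statistics be computed per
reading phase, which is what makes the phase-specific Z-curve parameters
sensitive to periodicity patterns in coding-like DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ALPHABET = "ACGT"
_VALID = frozenset(ALPHABET)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class InvalidSequenceError(ValueError):
    """Raised for empty sequences or characters outside {A, C, G, T}."""


@dataclass(frozen=True)
class DnaSequence:
    """An identified DNA sequence over the strict {A, C, G, T} alphabet.

    Input is uppercased on construction; any other symbol (N, IUPAC
    ambiguity codes, gaps) is rejected because it has no defined Z-curve
    coordinates.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        s = self.seq.upper()
        if not s:
            raise InvalidSequenceError(f"sequence {self.id!r} is empty")
        bad = set(s) - _VALID
        if bad:
            raise InvalidSequenceError(
                f"sequence {self.id!r} contains non-ACGT symbols: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", s)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        """GC fraction (G+C)/length."""
        return gc_content(self.seq)

    def complement(self) -> "DnaSequence":
        """Base-wise complement (A<->T, G<->C), no reversal."""
        return DnaSequence(self.id, self.seq.translate(_COMPLEMENT))


@dataclass(frozen=True)
class PhaseDecomposition:
    """The full sequence s0 and its three phase subsequences s1, s2, s3."""

    s0: str
    s1: str = field(init=False)
    s2: str = field(init=False)
    s3: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "s1", self.s0[0::3])
        object.__setattr__(self, "s2", self.s0[1::3])
        object.__setattr__(self, "s3", self.s0[2::3])

    @property
    def phases(self) -> tuple[str, str, str]:
        return (self.s1, self.s2, self.s3)


def as_str(seq: "DnaSequence | str") -> str:
    return seq.seq if isinstance(seq, DnaSequence) else seq


def phase_decompose(seq: "DnaSequence | str") -> PhaseDecomposition:
    """Split a sequence into its three phase subsequences.

    Phase i (1-based) holds the bases at 1-based positions i, i+3, i+6, ...;
    interleaving the phases back by original index reconstructs the input.
    """
    s = as_str(seq)
    if not s:
        raise InvalidSequenceError("cannot phase-decompose an empty sequence")
    return PhaseDecomposition(s)


def gc_content(seq: "DnaSequence | str") -> float:
    """Fraction of G and C bases; errors on empty input."""
    s = as_str(seq)
    if not s:
        raise InvalidSequenceError("GC content of an empty sequence is undefined")
    return (s.count("G") + s.count("C")) / len(s)
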