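"""Nucleotide sequence primitives shared by the whole package.

Provides validated DNA/RNA sequences, terminal-modification codes for
orderable oligos (5'-amino-C6 linker, 3'-C3 spacer, 5'-phosphate), and the
bracketed "order string" rendering used by oligo vendors, e.g.
``[AmC6]ACCCA`` or ``CTGAAGGAGTAGAAAGTACACACCGCCCGT[SpC3]``.

Sequences are stored uppercase; ambiguity codes (N, R, Y, ...) are rejected
outright because an oligo containing them cannot be ordered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum


class PsiBridgeError(ValueError):
    """Base class for all domain errors raised by this package."""


class AlphabetError(PsiBridgeError):
    """A sequence contains a character outside its declared alphabet."""


class OrderStringError(PsiBridgeError):
    """An order string does not follow the rendering grammar."""


class LengthError(PsiBridgeError):
    """A window, offset or segment does not fit in its sequence."""


class Alphabet(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


_LETTERS = {Alphabet.DNA: frozenset("ACGT"), Alphabet.RNA: frozenset("ACGU")}
_COMPLEMENT = {
    Alphabet.DNA: str.maketrans("ACGT", "TGCA"),
    Alphabet.RNA: str.maketrans("ACGU", "UGCA"),
}


@dataclass(frozen=True)
class NucSequence:
    """A validated nucleotide sequence over a single declared alphabet.

    Input is canonicalised to uppercase. Positions are 1-based, 5'->3'
    throughout the package; :meth:`sub` slices inclusively in those
    coordinates.
    """

    letters: str
    alphabet: Alphabet

    def __post_init__(self) -> None:
        canonical = self.letters.upper()
        object.__setattr__(self, "letters", canonical)
        allowed = _LETTERS[self.alphabet]
        for i, ch in enumerate(canonical, start=1):
            if ch not in allowed:
                raise AlphabetError(
                    f"invalid {self.alphabet.value} character {ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.letters)

    def __str__(self) -> str:
        return self.letters

    def base(self, position: int) -> str:
        """Return the base at a 1-based position."""
        if not 1 <= position <= len(self):
            raise LengthError(
                f"position {position} outside sequence of length {len(self)}"
            )
        return self.letters[position - 1]

    def sub(self, start: int, end: int) -> "NucSequence":
        """Inclusive 1-based subsequence [start, end]."""
        if not (1 <= start <= end <= len(self)):
            raise LengthError(
                f"window [{start}, {end}] outside sequence of length {len(self)}"
            )
        return NucSequence(self.letters[start - 1 : end], self.alphabet)


def dna(letters: str) -> NucSequence:
    return NucSequence(letters, Alphabet.DNA)


def rna(letters: str) -> NucSequence:
    return NucSequence(letters, Alphabet.RNA)


def detect_alphabet(letters: str) -> Alphabet:
    """Infer DNA vs RNA from the letters (presence of U => RNA).

    A sequence mixing U and T is ambiguous and rejected; a sequence with
    neither is treated as DNA.
    """
    upper = letters.upper()
    has_u, has_t = "U" in upper, "T" in upper
    if has_u and has_t:
        raise AlphabetError("sequence mixes U and T; alphabet is ambiguous")
    return Alphabet.RNA if has_u else Alphabet.DNA


def auto(letters: str) -> NucSequence:
    """Build a sequence with the alphabet inferred by :func:`detect_alphabet`."""
    return NucSequence(letters, detect_alphabet(letters))


def reverse_complement(seq: NucSequence) -> NucSequence:
    """Reverse complement within the sequence's own alphabet."""
    if len(seq) == 0:
        raise LengthError("cannot reverse-complement an empty sequence")
    flipped = seq.letters.translate(_COMPLEMENT[seq.alphabet])[::-1]
    return NucSequence(flipped, seq.alphabet)


def to_dna(seq: NucSequence) -> NucSequence:
    """U->T conversion; idempotent on DNA."""
    if seq.alphabet is Alphabet.DNA:
        return seq
    return NucSequence(seq.letters.replace("U", "T"), Alphabet.DNA)


def to_rna(seq: NucSequence) -> NucSequence:
    """T->U conversion; idempotent on RNA."""
    if seq.alphabet is Alphabet.RNA:
        return seq
    return NucSequence(seq.letters.replace("T", "U"), Alphabet.RNA)


class Modification(Enum):
    """Terminal modification codes, with their canonical order-string token.

    * ``AMC6_5PRIME`` — 5' amino-C6 linker; blocks ligation at the 5' end.
    * ``SPC3_3PRIME`` — 3' C3 spacer; blocks extension and ligation at the
      3' end.
    * ``PHOS_5PRIME`` — 5' phosphate; required for an oligo's 5' end to be
      ligatable by T4 DNA ligase.
    """

    AMC6_5PRIME = ("AmC6", 5)
    SPC3_3PRIME = ("SpC3", 3)
    PHOS_5PRIME = ("Phos", 5)

    @property
    def token(self) -> str:
        return self.value[0]

    @property
    def end(self) -> int:
        return self.value[1]


# Vendor catalogues and protocols use several spellings for the same
# chemistry; all are accepted on parse, rendering is always canonical.
_FIVE_PRIME_SYNONYMS = {
    "AmC6": Modification.AMC6_5PRIME,
    "5AmC6": Modification.AMC6_5PRIME,
    "5AmMC6": Modification.AMC6_5PRIME,
    "Phos": Modification.PHOS_5PRIME,
    "5Phos": Modification.PHOS_5PRIME,
}
_THREE_PRIME_SYNONYMS = {
    "SpC3": Modification.SPC3_3PRIME,
    "3SpC3": Modification.SPC3_3PRIME,
}


@dataclass(frozen=True)
class Oligo:
    """A named, orderable oligonucleotide with optional terminal chemistry."""

    name: str
    core: NucSequence
    mods: frozenset = field(default_factory=frozenset)
    phosphorylated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "mods", frozenset(self.mods))
        five = [m for m in self.mods if m.end == 5]
        three = [m for m in self.mods if m.end == 3]
        if len(five) > 1:
            raise PsiBridgeError("an oligo can carry at most one 5' modification")
        if len(three) > 1:
            raise PsiBridgeError("an oligo can carry at most one 3' modification")

    @property
    def phosphorylated_5prime(self) -> bool:
        return self.phosphorylated or Modification.PHOS_5PRIME in self.mods

    @property
    def ligatable_5prime(self) -> bool:
        """An amino-C6 5' end cannot be joined by ligase."""
        return Modification.AMC6_5PRIME not in self.mods

    @property
    def ligatable_3prime(self) -> bool:
        """A C3 spacer blocks both extension and ligation at the 3' end."""
        return Modification.SPC3_3PRIME not in self.mods

    # extension and ligation are blocked by the same 3' chemistry
    extendable_3prime = ligatable_3prime

    def with_phosphorylation(self) -> "Oligo":
        """Return a copy treated with T4 PNK (5'-phosphorylated)."""
        return Oligo(self.name, self.core, self.mods, phosphorylated=True)


def render_order_string(oligo: Oligo) -> str:
    """Render an oligo the way it is typed on an order form."""
    prefix = "".join(f"[{m.token}]" for m in oligo.mods if m.end == 5)
    suffix = "".join(f"[{m.token}]" for m in oligo.mods if m.end == 3)
    return f"{prefix}{oligo.core.letters}{suffix}"


_ORDER_RE = re.compile(
    r"^(?:\[(?P<five>[A-Za-z0-9]+)\])?(?P<core>[A-Za-z]+)(?:\[(?P<three>[A-Za-z0-9]+)\])?$"
)


def parse_order_string(text: str, name: str = "") -> Oligo:
    """Parse an order string back into an :class:`Oligo`.

    Round-trips with :func:`render_order_string` for canonical tokens;
    synonym spellings (5AmMC6, 5AmC6, 3SpC3, 5Phos) are accepted.
    """
    match = _ORDER_RE.match(text.strip())
    if match is None:
        raise OrderStringError(f"cannot parse order string {text!r}")
    mods = set()
    five = match.group("five")
    if five is not None:
        if five not in _FIVE_PRIME_SYNONYMS:
            raise OrderStringError(
                f"unknown 5' modification code [{five}]; accepted: "
                + ", ".join(sorted(_FIVE_PRIME_SYNONYMS))
            )
        mods.add(_FIVE_PRIME_SYNONYMS[five])
    three = match.group("three")
    if three is not None:
        if three not in _THREE_PRIME_SYNONYMS:
            raise OrderStringError(
                f"unknown 3' modification code [{three}]; accepted: "
                + ", ".join(sorted(_THREE_PRIME_SYNONYMS))
            )
        mods.add(_THREE_PRIME_SYNONYMS[three])
    return Oligo(name, auto(match.group("core")), frozenset(mods))
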