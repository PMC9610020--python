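"""Melting-temperature estimation and primer-pair compatibility.

PCR on the splinted junction fails silently when the adaptor-side and
gene-side primers have mismatched melting temperatures, so the designer
exposes both the quick Wallace rule and a two-state nearest-neighbor model,
plus a hairpin/self-dimer scan for the splint itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple, Union

from .seqcore import (
    Alphabet,
    AlphabetError,
    LengthError,
    NucSequence,
    Oligo,
    reverse_complement,
)

SeqLike = Union[NucSequence, Oligo]

# Unified nearest-neighbor duplex parameters (Allawi & SantaLucia 1997,
# Biochemistry 36:10581; the "unified" set of SantaLucia 1998 PNAS 95:1460).
# dH in kcal/mol, dS in cal/(mol K), keyed by the 5'->3' top-strand
# dinucleotide; two-fold degenerate stacks carry identical values.
NN_STACK = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# Duplex initiation per terminal base pair (same source).
NN_INIT_GC = (0.1, -2.8)
NN_INIT_AT = (2.3, 4.1)
NN_SYM_DS = -1.4  # entropy penalty for self-complementary duplexes
GAS_CONSTANT = 1.9872  # cal/(mol K)


@dataclass(frozen=True)
class TmSettings:
    """Conditions and thresholds for Tm estimation.

    ``oligo_concentration`` is total single-strand concentration C_T in
    mol/L (excess over template, so C_T/4 enters the two-state formula);
    ``monovalent_salt`` is [Na+] equivalents in mol/L; ``max_pair_delta``
    is the largest |ΔTm| (°C) a primer pair is allowed before the
    compatibility check fails.
    """

    method: str = "nearest_neighbor"
    oligo_concentration: float = 2.5e-7
    monovalent_salt: float = 0.05
    max_pair_delta: float = 5.0

    def __post_init__(self) -> None:
        if self.method not in ("wallace", "nearest_neighbor"):
            raise ValueError(f"unknown Tm method {self.method!r}")
        if self.oligo_concentration <= 0 or self.monovalent_salt <= 0:
            raise ValueError("concentrations must be positive")
        if self.max_pair_delta < 0:
            raise ValueError("max_pair_delta must be non-negative")


def _as_sequence(x: SeqLike) -> NucSequence:
    # Tm is computed on the core letters only; terminal modifications are
    # modeled structurally (ligatability/extendability), not thermodynamically.
    return x.core if isinstance(x, Oligo) else x


def tm_wallace(seq: SeqLike) -> float:
    """Wallace rule: 2(A+T/U) + 4(G+C), in °C."""
    s = _as_sequence(seq)
    if len(s) < 2:
        raise LengthError("Tm needs at least 2 nt")
    weak = sum(s.letters.count(b) for b in "ATU")
    strong = sum(s.letters.count(b) for b in "GC")
    return 2.0 * weak + 4.0 * strong


def tm_nearest_neighbor(seq: SeqLike, settings: TmSettings | None = None) -> float:
    """Two-state nearest-neighbor Tm in °C for a DNA oligo.

    ΔH/ΔS are accumulated over adjacent dinucleotides with per-terminus
    initiation terms; the entropy is corrected for monovalent salt with
    0.368·(N−1)·ln[Na+] and the duplex melts at
    Tm = ΔH / (ΔS + R·ln(C_T/x)) with x = 4 (x = 1 for a
    self-complementary oligo).
    """
    settings = settings or TmSettings()
    s = _as_sequence(seq)
    if s.alphabet is not Alphabet.DNA:
        raise AlphabetError(
            "nearest-neighbor Tm is parameterised for DNA; convert with to_dna()"
        )
    if len(s) < 2:
        raise LengthError("Tm needs at least 2 nt")
    letters = s.letters
    dh = 0.0  # kcal/mol
    ds = 0.0  # cal/(mol K)
    for i in range(len(letters) - 1):
        h, e = NN_STACK[letters[i : i + 2]]
        dh += h
        ds += e
    for terminal in (letters[0], letters[-1]):
        h, e = NN_INIT_GC if terminal in "GC" else NN_INIT_AT
        dh += h
        ds += e
    selfcomp = letters == reverse_complement(s).letters
    if selfcomp:
        ds += NN_SYM_DS
    ds += 0.368 * (len(letters) - 1) * math.log(settings.monovalent_salt)
    x = 1.0 if selfcomp else 4.0
    ct = settings.oligo_concentration
    return 1000.0 * dh / (ds + GAS_CONSTANT * math.log(ct / x)) - 273.15


def tm(seq: SeqLike, settings: TmSettings | None = None) -> float:
    """Dispatch on ``settings.method``."""
    settings = settings or TmSettings()
    if settings.method == "wallace":
        return tm_wallace(seq)
    return tm_nearest_neighbor(seq, settings)


def tm_compatible(
    p1: SeqLike, p2: SeqLike, settings: TmSettings | None = None
) -> Tuple[float, bool]:
    """|ΔTm| between two primers and whether it is within ``max_pair_delta``."""
    settings = settings or TmSettings()
    delta = abs(tm(p1, settings) - tm(p2, settings))
    return delta, delta <= settings.max_pair_delta


_PAIRS = {"AT", "TA", "GC", "CG", "AU", "UA"}


def _complementary(a: str, b: str) -> bool:
    return a + b in _PAIRS


def self_structure_scan(
    oligo: SeqLike, min_stem: int = 4
) -> List[Tuple[int, int, int]]:
    """Find potential hairpin/self-dimer stems within one oligo.

    Returns maximal (i, j, length) triples, 1-based, where the segment
    starting at i equals the reverse complement of the equal-length,
    non-overlapping segment starting at j (i < j). A maximal stem cannot be
    extended by another complementary pair at either end. An empty list
    means no self-structure warning at this stem length.
    """
    s = _as_sequence(oligo).letters
    n = len(s)
    # Exhaustive enumeration of all matched stems, then keep the maximal
    # ones. Oligos are short (<= ~50 nt), so O(n^3) with an inner scan is
    # fine. A stem (i, j, L) pairs s[i+t] with s[j+L-1-t]; growing it adds
    # an outer pair ((i-1, j, L+1)) or an inner pair ((i, j-1, L+1)).
    matches = set()
    for L in range(min_stem, n // 2 + 1):
        for i in range(0, n - 2 * L + 1):
            for j in range(i + L, n - L + 1):
                if all(
                    _complementary(s[i + t], s[j + L - 1 - t]) for t in range(L)
                ):
                    matches.add((i, j, L))
    maximal = [
        (i + 1, j + 1, L)
        for (i, j, L) in matches
        if (i - 1, j, L + 1) not in matches and (i, j - 1, L + 1) not in matches
    ]
    return sorted(maximal)
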