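"""Deterministic in-silico model of the CMC/RT-stop splint-ligation protocol.

The model is a pure string predictor of product *identity*, not yield:

* CMC leaves an adduct only on pseudouridines (alkaline reversal removes
  the U and G adducts), and that adduct halts reverse transcription so the
  cDNA's 3'-terminal base pairs transcript position psi+1.
* Without CMC (or with no adducted site upstream) the polymerase runs to
  the template 5' end — the true 5' end, a fragmentation breakpoint, or
  through the blocking oligo ligated onto a 5' end.
* T4 DNA ligase joins the adaptor to a cDNA only when the bridging oligo's
  two halves match exactly and the adaptor is 5'-phosphorylated.
* PCR succeeds iff both primers have unique exact sites in amplifiable
  orientation; cycle counts affect yield only and are not modeled.

All hybridisation is exact-match: the protocol's specificity rests on
perfect splint hybridisation, and that is what is simulated.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import List, Optional, Tuple

from . import reference
from .bridge import (
    BridgeDesign,
    DesignParams,
    PsiSite,
    adaptor_primer,
    design_bridging_oligo,
)
from .seqcore import (
    Alphabet,
    LengthError,
    NucSequence,
    Oligo,
    PsiBridgeError,
    dna,
    reverse_complement,
    rna,
    to_dna,
)


class SimulationError(PsiBridgeError):
    """A protocol-simulation precondition is violated."""


class PrimerSiteError(SimulationError):
    """A primer has zero or multiple exact annealing sites."""


class InferenceError(SimulationError):
    """The Ψ position cannot be read off an amplicon unambiguously."""


class StopCause(str, Enum):
    PSI_ADDUCT = "psi_adduct"
    RUNOFF = "runoff"
    FRAGMENT_END = "fragment_end"


@dataclass(frozen=True)
class TranscriptWithPsi:
    """An RNA with its pseudouridylated positions and degradation state.

    ``fragments`` lists 1-based breakpoints, each the 5' end of an internal
    fragment produced by random cleavage during CMC treatment; the region
    before the first breakpoint is the 5'-terminal fragment.
    ``blocking_ligated`` means the blocking oligo was ligated onto every
    accessible RNA 5' end (intact ends and fragment ends alike).
    """

    id: str
    rna: NucSequence
    psis: frozenset = field(default_factory=frozenset)
    blocking_ligated: bool = False
    fragments: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.rna.alphabet is not Alphabet.RNA:
            raise SimulationError("transcript must be RNA")
        object.__setattr__(self, "psis", frozenset(self.psis))
        for p in self.psis:
            if self.rna.base(p) != "U":
                raise SimulationError(
                    f"psi position {p} on {self.id!r} is not a uridine"
                )
        object.__setattr__(self, "fragments", tuple(sorted(self.fragments)))
        for b in self.fragments:
            if not 2 <= b <= len(self.rna):
                raise SimulationError(
                    f"fragment breakpoint {b} outside transcript interior"
                )


@dataclass(frozen=True)
class SimulatedCDNA:
    """A cDNA (5'->3', beginning with the RT primer) and why it ended.

    ``junction_rna_position`` is the transcript coordinate paired by the
    cDNA's 3'-terminal transcript-templated base: psi+1 for a Ψ-adduct
    stop, the template 5' end for run-off. When the blocking oligo was
    read through, the very last bases pair the blocking oligo instead and
    the junction still reports the last transcript position covered.
    """

    dna: NucSequence
    stop_cause: StopCause
    junction_rna_position: int


@dataclass(frozen=True)
class LigationResult:
    product: Optional[NucSequence]
    reason: Optional[str] = None

    @property
    def success(self) -> bool:
        return self.product is not None


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product.

    ``sense`` is the product's sense strand (the strand the forward primer
    matches directly); primer site coordinates are 1-based on ``sense``.
    """

    sense: NucSequence
    forward_site: Tuple[int, int]
    reverse_site: Tuple[int, int]

    @property
    def length(self) -> int:
        return len(self.sense)


def _unique_site(needle: str, haystack: str, what: str) -> Tuple[int, int]:
    sites = []
    start = haystack.find(needle)
    while start != -1:
        sites.append((start + 1, start + len(needle)))
        start = haystack.find(needle, start + 1)
    if len(sites) == 0:
        raise PrimerSiteError(f"{what}: no exact site found")
    if len(sites) > 1:
        raise PrimerSiteError(f"{what}: ambiguous, candidate sites {sites}")
    return sites[0]


def simulate_rt(
    t: TranscriptWithPsi,
    rt_primer: Oligo,
    cmc_treated: bool,
    blocking_oligo: Oligo = reference.BLOCKING_OLIGO,
) -> SimulatedCDNA:
    """First-strand synthesis from a gene-specific primer.

    The primer must be the exact reverse complement of exactly one
    transcript segment. With CMC, extension halts at the 3'-most adducted
    Ψ 5' of the primer segment (within the primer's fragment); otherwise
    it runs to the fragment 5' end, reading through the blocking oligo
    when one is ligated there.
    """
    template = to_dna(t.rna).letters
    seg_start, seg_end = _unique_site(
        reverse_complement(rt_primer.core).letters, template,
        f"RT primer {rt_primer.name!r}",
    )
    frag_start = 1
    for b in t.fragments:
        if b <= seg_start:
            frag_start = b
        if seg_start < b <= seg_end:
            raise SimulationError(
                f"fragment breakpoint {b} interrupts the RT primer site "
                f"[{seg_start}, {seg_end}]"
            )

    psi_star = None
    if cmc_treated:
        upstream = [p for p in t.psis if frag_start <= p < seg_start]
        if upstream:
            psi_star = max(upstream)

    if psi_star is not None:
        covered_start = psi_star + 1
        cdna = reverse_complement(dna(template[covered_start - 1 : seg_end]))
        return SimulatedCDNA(cdna, StopCause.PSI_ADDUCT, covered_start)

    cdna_letters = reverse_complement(
        dna(template[frag_start - 1 : seg_end])
    ).letters
    if t.blocking_ligated:
        if not blocking_oligo.ligatable_3prime:
            raise SimulationError(
                "blocking oligo carries a 3' spacer and cannot be ligated to RNA"
            )
        cdna_letters += reverse_complement(to_dna(blocking_oligo.core)).letters
        cause = StopCause.RUNOFF
    else:
        cause = StopCause.RUNOFF if frag_start == 1 else StopCause.FRAGMENT_END
    return SimulatedCDNA(dna(cdna_letters), cause, frag_start)


def simulate_splint_ligation(
    cdna: SimulatedCDNA,
    adaptor: Oligo,
    bridge: BridgeDesign,
    k: Optional[int] = None,
    m: Optional[int] = None,
) -> LigationResult:
    """Attempt the splinted adaptor ligation onto a cDNA 3' end.

    Succeeds only when (1) the splint's RNA-side half pairs the cDNA's
    3'-terminal m nt, (2) its adaptor-side half pairs the adaptor's
    5'-terminal k nt, and (3) the adaptor is 5'-phosphorylated. Failures
    are returned as reasons, not raised.
    """
    k = k if k is not None else len(bridge.adaptor_side)
    m = m if m is not None else len(bridge.rna_side)
    if len(bridge.adaptor_side) != k or len(bridge.rna_side) != m:
        raise LengthError(
            f"bridge halves are {len(bridge.adaptor_side)}+{len(bridge.rna_side)} "
            f"nt, expected k+m={k}+{m}"
        )
    expected_terminus = reverse_complement(bridge.rna_side).letters
    if len(cdna.dna) < m or cdna.dna.letters[-m:] != expected_terminus:
        return LigationResult(None, "cDNA-side mismatch")
    if (
        bridge.adaptor_side.letters
        != reverse_complement(adaptor.core.sub(1, k)).letters
    ):
        return LigationResult(None, "adaptor-side mismatch")
    if not adaptor.phosphorylated_5prime:
        return LigationResult(None, "adaptor not 5'-phosphorylated")
    if not adaptor.ligatable_5prime:
        return LigationResult(None, "adaptor 5' end is blocked")
    return LigationResult(dna(cdna.dna.letters + adaptor.core.letters))


def simulate_pcr(
    template: NucSequence, forward: Oligo, reverse: Oligo
) -> Optional[Amplicon]:
    """Predict the product of exponential PCR on a single template strand.

    ``template`` is the antisense strand (a ligated cDNA+adaptor, or the
    reverse complement of a previous amplicon's sense strand for a nested
    pass); the sense strand is its reverse complement. Returns ``None``
    when a primer has no site or the sites are not in amplifiable order;
    raises :class:`PrimerSiteError` when a primer has multiple sites.
    """
    sense = reverse_complement(template).letters
    try:
        f_start, f_end = _unique_site(
            forward.core.letters, sense, f"forward primer {forward.name!r}"
        )
    except PrimerSiteError as err:
        if "no exact site" in str(err):
            return None
        raise
    try:
        r_start, r_end = _unique_site(
            reverse_complement(reverse.core).letters, sense,
            f"reverse primer {reverse.name!r}",
        )
    except PrimerSiteError as err:
        if "no exact site" in str(err):
            return None
        raise
    if f_start > r_start or f_end > r_end:
        return None  # primers point away from each other
    product = dna(sense[f_start - 1 : r_end])
    flen = f_end - f_start + 1
    rlen = r_end - r_start + 1
    return Amplicon(
        product,
        (1, flen),
        (len(product) - rlen + 1, len(product)),
    )


def infer_psi(
    amplicon: Amplicon, adaptor: Oligo, transcript: NucSequence
) -> int:
    """Read the Ψ position off an amplicon, as Sanger sequencing would.

    The amplicon's sense strand is an adaptor-derived prefix (a suffix of
    revcomp(adaptor)) followed by transcript sequence; the first transcript
    coordinate j after the junction pairs the cDNA's 3'-terminal base, so
    the pseudouridine is at j−1.
    """
    sense = amplicon.sense.letters
    adaptor_rc = reverse_complement(adaptor.core).letters
    prefix_len = 0
    for p in range(min(len(sense), len(adaptor_rc)), 0, -1):
        if adaptor_rc.endswith(sense[:p]):
            prefix_len = p
            break
    if prefix_len == 0:
        raise InferenceError("unmappable: amplicon has no adaptor-derived prefix")
    mapped = sense[prefix_len:]
    if not mapped:
        raise InferenceError("unmappable: no transcript-derived sequence found")
    haystack = to_dna(transcript).letters
    sites = []
    start = haystack.find(mapped)
    while start != -1:
        sites.append(start + 1)
        start = haystack.find(mapped, start + 1)
    if len(sites) == 0:
        raise InferenceError(
            "unmappable: transcript-derived segment not found on transcript"
        )
    if len(sites) > 1:
        raise InferenceError(
            f"ambiguous: transcript segment maps at positions {sites}"
        )
    return sites[0] - 1


@dataclass(frozen=True)
class SyntheticFixture:
    """A generated transcript plus primers compatible with its layout.

    ``nested_primer`` is an inner gene-side primer when the layout leaves
    room for one between the 3'-most Ψ and the RT-primer segment,
    otherwise ``None`` (the round-trip then runs a semi-nested pass with
    the RT primer as the inner reverse primer).
    """

    transcript: TranscriptWithPsi
    rt_primer: Oligo
    nested_primer: Optional[Oligo]
    rt_segment: Tuple[int, int]


_NESTED_LEN = 18
_NESTED_GAP = 2  # nt between inner-primer segment end and RT segment end


def generate_synthetic_transcript(
    length: int = 200,
    gc_fraction: float = 0.5,
    n_psi: int = 1,
    seed: int = 0,
    m: int = 10,
    min_psi_separation: int = 5,
    require_unique_contexts: bool = True,
) -> SyntheticFixture:
    """Generate a random transcript with planted Ψ sites and an RT primer.

    Deterministic for a given seed. Ψ sites are planted on uridines,
    pairwise separated by at least ``min_psi_separation`` nt and at least
    m+1 nt 5' of the RT-primer segment; each site's (psi+1..psi+m) context
    is unique on the transcript, as is the RT-primer segment (the
    generator retries deterministically until both hold). The RT primer is
    the 18-22 nt reverse complement of the 3'-terminal segment.
    """
    if length < 40:
        raise SimulationError("transcript length must be >= 40")
    if n_psi < 1:
        raise SimulationError("n_psi must be >= 1")
    if not 0.0 < gc_fraction < 1.0:
        raise SimulationError("gc_fraction must be in (0, 1)")

    last_error = "constraints not satisfied"
    for attempt in range(64):
        rng = random.Random((seed * 1_000_003 + attempt * 7919) % (2**31 - 1))
        letters = "".join(
            rng.choices("GCAU", weights=[gc_fraction / 2, gc_fraction / 2,
                                         (1 - gc_fraction) / 2,
                                         (1 - gc_fraction) / 2], k=length)
        )
        transcript = rna(letters)
        template = to_dna(transcript).letters

        rt_len = rng.randint(18, min(22, length // 2))
        rt_start, rt_end = length - rt_len + 1, length
        rt_segment = template[rt_start - 1 :]
        if template.count(rt_segment) != 1:
            last_error = "RT-primer segment not unique"
            continue
        rt_primer = Oligo(
            "rt_primer", reverse_complement(dna(rt_segment))
        )

        # eligible U positions: inside the body, clear of the RT window
        hi = rt_start - m - 1
        eligible = [
            p for p in range(2, hi + 1) if letters[p - 1] == "U"
        ]
        rng.shuffle(eligible)
        psis: List[int] = []
        # prefer sites leaving room for an inner nested gene primer
        nested_cut = rt_start - _NESTED_GAP - _NESTED_LEN
        for pool in (
            [p for p in eligible if p < nested_cut],
            [p for p in eligible if p >= nested_cut],
        ):
            for p in pool:
                if len(psis) == n_psi:
                    break
                if all(abs(p - q) >= min_psi_separation for q in psis):
                    psis.append(p)
        if len(psis) < n_psi:
            last_error = (
                f"only {len(psis)} of {n_psi} psi sites placeable; try a "
                "longer transcript or lower gc_fraction"
            )
            continue

        if require_unique_contexts:
            contexts = [template[p : p + m] for p in psis]
            if any(template.count(c) != 1 for c in contexts):
                last_error = "psi context not unique on transcript"
                continue

        t = TranscriptWithPsi(f"synthetic_seed{seed}", transcript, frozenset(psis))

        nested_primer = None
        if max(psis) < nested_cut:
            inner_end = rt_start - 1 - _NESTED_GAP
            inner_start = inner_end - _NESTED_LEN + 1
            inner_segment = template[inner_start - 1 : inner_end]
            if template.count(inner_segment) == 1:
                nested_primer = Oligo(
                    "nested_gene_primer",
                    reverse_complement(dna(inner_segment)),
                )
        return SyntheticFixture(t, rt_primer, nested_primer, (rt_start, rt_end))

    raise SimulationError(
        f"could not generate a valid fixture after 64 attempts: {last_error}"
    )


@dataclass(frozen=True)
class RoundtripParams:
    """Study conditions for the end-to-end recovery run."""

    length: int = 200
    gc_fraction: float = 0.5
    n_psi: int = 1
    design: DesignParams = DesignParams()
    adaptor: Oligo = reference.ADAPTOR


@dataclass(frozen=True)
class RoundtripFailure:
    transcript_id: str
    psi: int
    stage: str
    message: str


@dataclass(frozen=True)
class RoundtripReport:
    n: int
    n_recovered: int
    n_minus_cmc_amplicons: int
    failures: Tuple[RoundtripFailure, ...]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "n_recovered": self.n_recovered,
            "n_minus_cmc_amplicons": self.n_minus_cmc_amplicons,
            "failures": [
                {"transcript": f.transcript_id, "psi": f.psi,
                 "stage": f.stage, "message": f.message}
                for f in self.failures
            ],
        }


def roundtrip(
    seed: int,
    n_transcripts: int = 100,
    params: RoundtripParams = RoundtripParams(),
) -> RoundtripReport:
    """Design → +CMC RT → splint ligation → outer + nested PCR → inference.

    For every planted Ψ on every seeded synthetic transcript, a bridging
    oligo is designed and pushed through the full simulated protocol; the
    site counts as recovered only when the inferred position equals the
    planted one. The −CMC arm of each transcript is run alongside and must
    never yield a junction amplicon. With several Ψ per transcript each
    site is simulated as the molecule subpopulation adducted at that site
    alone (the deterministic RT model always stops at the 3'-most adduct).
    """
    adaptor = params.adaptor.with_phosphorylation()
    outer_fwd = adaptor_primer(adaptor, 1, min(23, len(adaptor.core)))
    nested_fwd = adaptor_primer(
        adaptor, 15, min(26, len(adaptor.core) - 14), name="adaptor_nested_primer"
    )
    k, m = params.design.adaptor_side_len, params.design.rna_side_len

    n = 0
    n_recovered = 0
    n_minus = 0
    failures: List[RoundtripFailure] = []
    for i in range(n_transcripts):
        sub_seed = (seed * 9_576_890_767 + i * 104_729) % (2**31 - 1)
        try:
            fixture = generate_synthetic_transcript(
                params.length, params.gc_fraction, params.n_psi, sub_seed, m=m
            )
        except SimulationError:
            # short RNA-side halves (small m) make unique contexts
            # unattainable; run anyway and let the per-stage checks report
            try:
                fixture = generate_synthetic_transcript(
                    params.length, params.gc_fraction, params.n_psi, sub_seed,
                    m=m, require_unique_contexts=False,
                )
            except SimulationError as err:
                n += params.n_psi
                failures.append(
                    RoundtripFailure(f"synthetic_seed{sub_seed}", 0,
                                     "generate", str(err))
                )
                continue
        t, rt_primer = fixture.transcript, fixture.rt_primer
        inner_rev = fixture.nested_primer or rt_primer
        for psi_pos in sorted(t.psis):
            n += 1
            mono = replace(t, psis=frozenset({psi_pos}))
            psi = PsiSite(t.id, psi_pos)
            try:
                design = design_bridging_oligo(adaptor, t.rna, psi, params.design)
                plus = simulate_rt(mono, rt_primer, cmc_treated=True)
                lig = simulate_splint_ligation(plus, adaptor, design, k, m)
                if not lig.success:
                    failures.append(
                        RoundtripFailure(t.id, psi_pos, "ligation", lig.reason)
                    )
                    continue
                outer = simulate_pcr(lig.product, outer_fwd, rt_primer)
                if outer is None:
                    failures.append(
                        RoundtripFailure(t.id, psi_pos, "pcr", "no outer amplicon")
                    )
                    continue
                nested = simulate_pcr(
                    reverse_complement(outer.sense), nested_fwd, inner_rev
                )
                if nested is None:
                    failures.append(
                        RoundtripFailure(t.id, psi_pos, "nested_pcr",
                                         "no nested amplicon")
                    )
                    continue
                inferred = infer_psi(nested, adaptor, t.rna)
            except PsiBridgeError as err:
                failures.append(
                    RoundtripFailure(t.id, psi_pos, "error", str(err))
                )
                continue
            if inferred == psi_pos:
                n_recovered += 1
            else:
                failures.append(
                    RoundtripFailure(
                        t.id, psi_pos, "inference",
                        f"inferred {inferred}, planted {psi_pos}",
                    )
                )
            # −CMC control arm: full read-through must never ligate
            minus = simulate_rt(mono, rt_primer, cmc_treated=False)
            lig_minus = simulate_splint_ligation(minus, adaptor, design, k, m)
            if lig_minus.success:
                amp = simulate_pcr(lig_minus.product, outer_fwd, rt_primer)
                if amp is not None:
                    n_minus += 1
    return RoundtripReport(n, n_recovered, n_minus, tuple(failures))
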