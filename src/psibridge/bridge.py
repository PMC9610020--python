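"""Design and validation of bridging (splint) oligos.

A CMC-stopped cDNA ends immediately 3' of the pseudouridine (on the
transcript: position psi+1). T4 DNA ligase cannot join single strands, so
the adaptor is splinted onto that cDNA end by a bridging oligo whose 5'
half is the reverse complement of the adaptor's 5'-terminal k nt and whose
3' half is the sense transcript sequence just 3' of the Ψ (m nt, U->T).
The splint carries a 3' C3 spacer so it cannot itself be extended or
ligated.

Coordinates are 1-based, inclusive, 5'->3' on the transcript;
``psi.position`` is the modified U itself and the RNA-side window is
[psi+1, psi+m].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .seqcore import (
    LengthError,
    Modification,
    NucSequence,
    Oligo,
    PsiBridgeError,
    render_order_string,
    reverse_complement,
    to_dna,
)


class DesignError(PsiBridgeError):
    """A bridging-oligo design precondition is violated."""


@dataclass(frozen=True)
class PsiSite:
    """A pseudouridylated position on a transcript (1-based, the U itself)."""

    transcript_id: str
    position: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DesignError(
                f"psi position must be >= 1, got {self.position} "
                f"({self.transcript_id})"
            )


@dataclass(frozen=True)
class DesignParams:
    """Tunable lengths of the two splint halves.

    10 nt per side is usually enough; longer halves buy specificity (and
    the validated 18S design uses 15+15).
    """

    adaptor_side_len: int = 10
    rna_side_len: int = 10
    add_3prime_spacer: bool = True

    def __post_init__(self) -> None:
        if self.adaptor_side_len < 1 or self.rna_side_len < 1:
            raise DesignError("both splint half lengths must be >= 1")


@dataclass(frozen=True)
class BridgeDesign:
    """A designed bridging oligo and its two halves."""

    adaptor_side: NucSequence
    rna_side: NucSequence
    oligo: Oligo
    warnings: Tuple[str, ...] = ()

    @property
    def order_string(self) -> str:
        return render_order_string(self.oligo)


def design_from_context(
    adaptor: Oligo,
    context: NucSequence,
    k: int = 10,
    m: int = 10,
    add_spacer: bool = True,
    name: str = "bridging_oligo",
) -> BridgeDesign:
    """Design a splint from the sequence starting immediately 3' of the Ψ.

    ``context`` is the transcript (RNA or DNA) read 5'->3' from position
    psi+1; only its first ``m`` nt are used. The splint is assembled
    5'->3' as revcomp(adaptor[1..k]) + context[1..m] (U->T), with a 3' C3
    spacer unless ``add_spacer`` is False.
    """
    if k < 1 or m < 1:
        raise DesignError("both splint half lengths must be >= 1")
    if k > len(adaptor.core):
        raise LengthError(
            f"adaptor-side length k={k} exceeds adaptor length {len(adaptor.core)}"
        )
    if len(context) < m:
        raise LengthError(
            f"context ({len(context)} nt) shorter than RNA-side length m={m}"
        )
    adaptor_side = reverse_complement(adaptor.core.sub(1, k))
    rna_side = to_dna(context.sub(1, m))
    mods = frozenset({Modification.SPC3_3PRIME}) if add_spacer else frozenset()
    core = NucSequence(adaptor_side.letters + rna_side.letters, adaptor_side.alphabet)
    return BridgeDesign(adaptor_side, rna_side, Oligo(name, core, mods))


def design_bridging_oligo(
    adaptor: Oligo,
    transcript: NucSequence,
    psi: PsiSite,
    params: DesignParams = DesignParams(),
) -> BridgeDesign:
    """Design a splint for one Ψ site on a transcript.

    Validates that the site indexes a uridine and that the RNA-side window
    [psi+1, psi+m] fits on the transcript, then delegates to
    :func:`design_from_context`. A specificity warning is attached when the
    RNA-side half occurs more than once on the transcript (suggesting a
    larger m).
    """
    m = params.rna_side_len
    if not 1 <= psi.position <= len(transcript):
        raise DesignError(
            f"psi position {psi.position} outside transcript "
            f"{psi.transcript_id!r} of length {len(transcript)}"
        )
    base = transcript.base(psi.position)
    if base not in ("U", "T"):
        raise DesignError(
            f"psi position {psi.position} on {psi.transcript_id!r} is not a "
            f"uridine (found {base})"
        )
    if psi.position + m > len(transcript):
        raise LengthError(
            f"RNA-side window [{psi.position + 1}, {psi.position + m}] exceeds "
            f"transcript end ({len(transcript)})"
        )
    context = transcript.sub(psi.position + 1, len(transcript))
    name = f"{psi.transcript_id}_psi{psi.position}"
    design = design_from_context(
        adaptor, context, params.adaptor_side_len, m, params.add_3prime_spacer, name
    )
    warnings = list(design.warnings)
    hits = check_specificity(design.rna_side, transcript)
    if hits > 1:
        warnings.append(
            f"RNA-side half matches the transcript at {hits} positions; "
            f"consider a larger rna_side_len than {m}"
        )
    return BridgeDesign(design.adaptor_side, design.rna_side, design.oligo,
                        tuple(warnings))


def adaptor_primer(
    adaptor: Oligo, start: int, length: int, name: str = "adaptor_primer"
) -> Oligo:
    """Derive an adaptor-side PCR primer.

    The primer is the substring of reverse_complement(adaptor) at the
    1-based window [start, start+length-1]; start=1 gives the outermost
    (distal) primer, larger offsets give nested primers.
    """
    if start < 1:
        raise LengthError(f"primer start must be >= 1, got {start}")
    end = start + length - 1
    if end > len(adaptor.core):
        raise LengthError(
            f"primer window [{start}, {end}] exceeds adaptor length "
            f"{len(adaptor.core)}"
        )
    rc = reverse_complement(adaptor.core)
    return Oligo(name, rc.sub(start, end))


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    message: str = ""


@dataclass(frozen=True)
class ValidationReport:
    checks: Tuple[CheckResult, ...]
    warnings: Tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)


def validate_bridging_oligo(
    bridge: Oligo,
    adaptor: Oligo,
    transcript: NucSequence,
    psi: PsiSite,
    k: int,
    m: int,
) -> ValidationReport:
    """Check a (possibly hand-made) splint against adaptor and transcript.

    Verifies the adaptor-side half, the RNA-side half, and the presence of
    the 3' spacer (a warning, not a failure — an unblocked 3' end is merely
    extendable/ligatable).
    """
    if len(bridge.core) != k + m:
        raise LengthError(
            f"bridging oligo core is {len(bridge.core)} nt, expected k+m={k + m}"
        )
    checks: List[CheckResult] = []
    warnings: List[str] = []

    expected_adaptor_side = reverse_complement(adaptor.core.sub(1, k))
    got_adaptor_side = bridge.core.sub(1, k)
    if got_adaptor_side.letters == expected_adaptor_side.letters:
        checks.append(CheckResult("adaptor_side", True))
    else:
        pos = _first_mismatch(got_adaptor_side.letters, expected_adaptor_side.letters)
        checks.append(
            CheckResult(
                "adaptor_side",
                False,
                f"adaptor-side half mismatches revcomp(adaptor[1..{k}]) "
                f"first at position {pos}",
            )
        )

    expected_rna_side = to_dna(transcript.sub(psi.position + 1, psi.position + m))
    got_rna_side = bridge.core.sub(k + 1, k + m)
    if got_rna_side.letters == expected_rna_side.letters:
        checks.append(CheckResult("rna_side", True))
    else:
        pos = _first_mismatch(got_rna_side.letters, expected_rna_side.letters)
        checks.append(
            CheckResult(
                "rna_side",
                False,
                f"RNA-side half mismatches transcript[{psi.position + 1}.."
                f"{psi.position + m}] first at position {pos}",
            )
        )

    if Modification.SPC3_3PRIME not in bridge.mods:
        warnings.append(
            "no 3' spacer: the bridging oligo's 3' end is extendable/ligatable"
        )
    return ValidationReport(tuple(checks), tuple(warnings))


def _first_mismatch(a: str, b: str) -> int:
    for i, (x, y) in enumerate(zip(a, b), start=1):
        if x != y:
            return i
    return min(len(a), len(b)) + 1


def check_specificity(segment: NucSequence, transcript: NucSequence) -> int:
    """Count exact overlapping occurrences of ``segment`` on the sense strand.

    Alphabet differences (a DNA splint half vs an RNA transcript) are
    normalised before matching. More than one hit means the splint could
    ligate a cDNA stopped elsewhere.
    """
    if len(segment) == 0:
        raise LengthError("specificity segment must be non-empty")
    if len(segment) > len(transcript):
        raise LengthError("segment longer than transcript")
    needle = to_dna(segment).letters
    haystack = to_dna(transcript).letters
    count = 0
    start = haystack.find(needle)
    while start != -1:
        count += 1
        start = haystack.find(needle, start + 1)
    return count


def _find_antisense_sites(
    primer: Oligo, transcript: NucSequence
) -> List[Tuple[int, int]]:
    """1-based [start, end] transcript segments whose revcomp is the primer."""
    target = to_dna(reverse_complement(primer.core)).letters
    haystack = to_dna(transcript).letters
    sites = []
    start = haystack.find(target)
    while start != -1:
        sites.append((start + 1, start + len(target)))
        start = haystack.find(target, start + 1)
    return sites


@dataclass(frozen=True)
class PrimerPlacement:
    name: str
    sites: Tuple[Tuple[int, int], ...]
    ok: bool
    message: str = ""

    @property
    def segment(self) -> Optional[Tuple[int, int]]:
        return self.sites[0] if len(self.sites) == 1 else None


@dataclass(frozen=True)
class LayoutReport:
    rt: PrimerPlacement
    gene_primers: Tuple[PrimerPlacement, ...]
    nesting_ok: bool
    amplicon_spans: Tuple[Tuple[int, int], ...]

    @property
    def passed(self) -> bool:
        return (
            self.rt.ok
            and all(p.ok for p in self.gene_primers)
            and self.nesting_ok
        )


def validate_primer_layout(
    transcript: NucSequence,
    psi: PsiSite,
    rt_primer: Oligo,
    gene_primers: Sequence[Oligo] = (),
) -> LayoutReport:
    """Check that RT and gene-side PCR primers sit where the method needs them.

    The RT primer must anneal at exactly one place, 3' of the Ψ, so the
    cDNA runs through the junction. Each antisense gene primer (listed
    outer to inner for a nested pair) must match exactly one segment inside
    [psi+1, RT-segment end], and an inner primer's segment must end no
    later than its outer neighbour's. Transcript-side amplicon spans
    [psi+1, segment end] are reported for each valid primer.
    """
    rt_sites = _find_antisense_sites(rt_primer, transcript)
    if len(rt_sites) == 0:
        rt = PrimerPlacement(rt_primer.name, (), False, "RT primer not found")
    elif len(rt_sites) > 1:
        rt = PrimerPlacement(
            rt_primer.name, tuple(rt_sites), False,
            f"RT primer is ambiguous: candidate segments {rt_sites}",
        )
    elif rt_sites[0][0] <= psi.position:
        rt = PrimerPlacement(
            rt_primer.name, tuple(rt_sites), False,
            "RT primer does not cover the Ψ junction (segment starts at "
            f"{rt_sites[0][0]} <= psi {psi.position})",
        )
    else:
        rt = PrimerPlacement(rt_primer.name, tuple(rt_sites), True)

    rt_end = rt.segment[1] if rt.segment else len(transcript)
    placements: List[PrimerPlacement] = []
    spans: List[Tuple[int, int]] = []
    for primer in gene_primers:
        sites = _find_antisense_sites(primer, transcript)
        if len(sites) == 0:
            placements.append(
                PrimerPlacement(primer.name, (), False, "primer not found")
            )
            continue
        if len(sites) > 1:
            placements.append(
                PrimerPlacement(
                    primer.name, tuple(sites), False,
                    f"primer is ambiguous: candidate segments {sites}",
                )
            )
            continue
        start, end = sites[0]
        if start < psi.position + 1 or end > rt_end:
            placements.append(
                PrimerPlacement(
                    primer.name, tuple(sites), False,
                    f"primer segment [{start}, {end}] not inside "
                    f"[{psi.position + 1}, {rt_end}]",
                )
            )
            continue
        placements.append(PrimerPlacement(primer.name, tuple(sites), True))
        spans.append((psi.position + 1, end))

    nesting_ok = True
    valid = [p for p in placements if p.ok and p.segment]
    for outer, inner in zip(valid, valid[1:]):
        if inner.segment[1] > outer.segment[1]:
            nesting_ok = False
    return LayoutReport(rt, tuple(placements), nesting_ok, tuple(spans))


@dataclass(frozen=True)
class BatchFailure:
    row: int
    psi: PsiSite
    message: str


@dataclass(frozen=True)
class BatchRow:
    psi: PsiSite
    design: BridgeDesign


@dataclass(frozen=True)
class BatchResult:
    rows: Tuple[BatchRow, ...]
    failures: Tuple[BatchFailure, ...]

    def summary(self) -> str:
        return (
            f"{len(self.rows)} designed, {len(self.failures)} failed"
            + ("" if not self.failures else ": " + "; ".join(
                f"row {f.row} ({f.psi.transcript_id}:{f.psi.position}): {f.message}"
                for f in self.failures))
        )


def batch_design(
    transcripts: Dict[str, NucSequence],
    psi_sites: Iterable[PsiSite],
    adaptor: Oligo,
    params: DesignParams = DesignParams(),
) -> BatchResult:
    """Design one splint per Ψ-table row, in input order, fail-soft.

    A bad row (unknown transcript, non-U position, window off the 3' end)
    is recorded as a failure and does not stop the remaining rows.
    """
    rows: List[BatchRow] = []
    failures: List[BatchFailure] = []
    for idx, psi in enumerate(psi_sites, start=1):
        transcript = transcripts.get(psi.transcript_id)
        if transcript is None:
            failures.append(
                BatchFailure(idx, psi, f"unknown transcript id {psi.transcript_id!r}")
            )
            continue
        try:
            design = design_bridging_oligo(adaptor, transcript, psi, params)
        except PsiBridgeError as err:
            failures.append(BatchFailure(idx, psi, str(err)))
            continue
        rows.append(BatchRow(psi, design))
    return BatchResult(tuple(rows), tuple(failures))
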