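# Methods

## Design rule

Coordinates are 1-based, inclusive, 5′→3′ on the transcript. `psi` is the
modified uridine itself. A bridging oligo for `psi` is assembled 5′→3′ as

```
revcomp(adaptor[1..k]) + transcript[psi+1 .. psi+m] (U→T) + [SpC3]
```

The adaptor-side half splints the adaptor's 5′-terminal k nt; the
RNA-side half is identical to the sense transcript just 3′ of the Ψ and
therefore reverse-complementary to the 3′-terminal m nt of a cDNA whose
synthesis halted at the Ψ adduct (the cDNA's last base pairs transcript
position psi+1). This fixes the one convention everything else depends
on: design and simulation agree by construction, and the round-trip test
quantifies that agreement.

Defaults are k = m = 10 nt. Ten per side is normally enough for specific
splinting; longer halves buy specificity on repetitive contexts, and the
validated 18S reference design uses 15+15 (reproduced by passing the
lengths explicitly — no auto-selection is attempted, since no principled
rule for choosing between 10 and 15 exists and both work). The 3′ C3
spacer is on by default: a splint with a free 3′-OH can be extended by
the polymerase or ligated, creating artefacts; omitting it is allowed
but flagged as a warning by the validator.

Specificity scanning counts exact, overlapping, sense-strand occurrences
of the RNA-side half on its own transcript; more than one hit raises a
warning suggesting a larger m. The scan is deliberately single-transcript
and sense-only: the ligation substrate is the cDNA of the targeted
transcript, and transcriptome-wide off-target search is out of scope.
All matching in the designer and simulator is exact — the protocol's
specificity rests on perfect splint hybridisation, and modelling partial
annealing would only blur what the exact model can verify exactly.

## Melting temperatures

Primer pairs with mismatched Tm are a leading cause of silent PCR
failure on the adaptor–cDNA junction, so two estimators are exposed
(neither is privileged by the protocol; the nearest-neighbor model is
the package default, the Wallace rule is the quick bench heuristic):

* Wallace rule: Tm = 2(A+T/U) + 4(G+C) °C.
* Two-state nearest-neighbor model: ΔH/ΔS summed over adjacent
  dinucleotides with per-terminus initiation terms from the unified
  parameter set of Allawi & SantaLucia (1997, Biochemistry 36:10581),
  entropic salt correction 0.368·(N−1)·ln[Na⁺], and
  Tm = ΔH / (ΔS + R·ln(C_T/4)) (C_T/1 for self-complementary oligos).
  Defaults: C_T = 250 nM total strand, [Na⁺] = 50 mM. One parameter set,
  hard-coded; no table switching.

A primer pair is called compatible when |ΔTm| ≤ 5 °C. The threshold is
common primer-design practice (no protocol-derived number exists) and is
configurable (`max_pair_delta`). Tm is computed on core letters only;
terminal modifications are modelled structurally (ligatability,
extendability), not thermodynamically. A brute-force hairpin/self-dimer
scan (`self_structure_scan`, minimum stem 4 bp) reports maximal
self-complementary segment pairs; the reference splint is checked against
an independent enumeration oracle in the tests.

## Protocol simulation

The simulator is a deterministic string model of product *identity*:

* **CMC arm.** Only Ψ adducts survive alkaline reversal, so with CMC the
  reverse transcriptase halts at the 3′-most Ψ 5′ of the primer segment
  (within the primer's fragment); the cDNA covers [psi+1, primer-segment
  end]. CMC-U/G adducts are not modelled at all.
* **−CMC arm.** Complete read-through to the template 5′ end; no
  stochastic stops. Degradation is modelled only through explicit
  fragment breakpoints (each the 5′ end of a fragment).
* **Blocking oligo.** When ligated (onto every accessible 5′ end), a
  run-off cDNA continues into the reverse complement of the blocker, so
  a fragment-end cDNA acquires a 3′ tail (e.g. `TGGGT`) that no
  Ψ-designed splint matches — the exact-model version of the blocker's
  purpose, and the property the protection trials measure. Its 5′
  amino-C6 makes its own 5′ end non-ligatable (no concatemers).
* **Splint ligation.** Succeeds iff the splint's RNA-side half pairs the
  cDNA's 3′-terminal m nt, its adaptor-side half pairs the adaptor's
  5′-terminal k nt, and the adaptor is 5′-phosphorylated (commercial
  oligos are not; `Oligo.with_phosphorylation()` models the PNK step).
  Failures return reasons rather than raising.
* **PCR.** A pure string predictor: unique exact primer sites in
  amplifiable orientation define the product; multiple sites are an
  ambiguity error, absent sites mean no product. Cycle numbers affect
  yield, not identity, and are not modelled. The outer pass is assumed
  to use the distal adaptor primer plus the gene-specific RT primer;
  the nested pass uses the nested adaptor primer plus an inner gene
  primer (this outer-pair assignment is an assumption of the simulator,
  stated here because the protocol it models leaves it implicit).
* **Inference.** The amplicon's sense strand is split at the end of its
  adaptor-derived prefix (the longest prefix that is a suffix of
  revcomp(adaptor)); the transcript-derived remainder is exact-searched
  on the transcript and its first coordinate j gives Ψ = j−1. Zero hits
  → "unmappable", several → "ambiguous" with candidates; a wrong
  position is never returned silently.

## Synthetic transcripts

`generate_synthetic_transcript` emulates what the designer needs from a
real target: a transcript of configurable length (default 200 nt) and GC
content (default 0.5, i.i.d. bases), n planted Ψ sites on uridines
(pairwise ≥ 5 nt apart, ≥ m+1 nt 5′ of the RT-primer window), and an
18–22 nt RT primer reverse-complementary to a unique 3′-terminal
segment. Each Ψ context (psi+1..psi+m) is required to be unique on the
transcript (deterministic retries; relaxable via
`require_unique_contexts=False`, which the round-trip uses as a fallback
for deliberately short m). Sites are preferentially placed ≥ 20 nt 5′ of
the RT window so an inner 18-nt gene primer fits for the nested pass;
when a site lands closer, the round-trip degrades to a semi-nested pass
(nested adaptor primer + RT primer). Everything is deterministic given a
seed; per-transcript seeds are derived arithmetically and kept < 2³¹.

What the generator does **not** emulate: real rRNA secondary structure
and base composition, partial CMC conversion, stochastic RT drop-off,
sequencing error, and cellular abundance. Passing round-trips therefore
demonstrate that the *design logic and protocol bookkeeping* are exactly
mutually consistent — adaptor-side/RNA-side orientation, coordinate
conventions, ligation requirements, primer placement — not that the wet
protocol will succeed on a given biological target.

With several Ψ per transcript the deterministic RT always stops at the
3′-most adduct, so the round-trip simulates each site as the molecule
subpopulation adducted at that site alone; this mirrors the real partial
modification of a population without modelling its stoichiometry.

## Problem sizes and numerics

The recovery experiment uses 100 transcripts of 200 nt with one Ψ each
(unique contexts) — large enough that primer/context uniqueness is
generic, small enough that the whole suite runs in seconds. The
blocking-oligo trials inject one breakpoint between the Ψ and the RT
window (clamped 5′ of the primer segment) with the blocker ligated, 100
seeded trials. Nearest-neighbor Tm is checked against an independent
summation oracle to 1e-9 °C and against Biopython's `Tm_NN` (same table,
DNA_NN3) to 0.05 °C — the residual difference is the gas-constant
rounding. Ties and degenerate inputs: empty sequences, ambiguity codes
and mixed U/T are rejected at construction with the offending position;
batch design is fail-soft (bad rows are collected, good rows survive);
ligation failures are values, not exceptions.

## Known limitations

* Exact-match hybridisation only; no mismatch tolerance, dangling ends,
  or Mg²⁺/dNTP corrections in the Tm model.
* No transcriptome-wide off-target scanning and no reverse-strand
  specificity scan (the cDNA substrate is sense-defined).
* The simulator predicts product identity, never yield; the modelled
  protocol is qualitative by design (nested PCR biases abundance).
* Internal modifications and quality scores are out of scope for the
  oligo model.
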