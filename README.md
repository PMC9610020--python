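# psibridge

Bridging (splint) oligo design — with full in-silico validation — for
CMC-based pseudouridine (Ψ) mapping.

## The problem

The standard low-throughput way to confirm a pseudouridine at a known
position is CMC primer extension: CMC
(N-cyclohexyl-N′-(2-morpholinoethyl)carbodiimide) forms adducts on U, G
and Ψ; alkaline treatment strips all but the Ψ adduct, which then stops
reverse transcription so the cDNA ends exactly opposite the nucleotide 3′
of the Ψ. To amplify and sequence that truncated cDNA, a universal DNA
adaptor is ligated to its 3′ end. T4 DNA ligase cannot join single
strands, so the ligation needs a **bridging (splint) oligo** that holds
the two ends together:

```
5'-<adaptor, phosphorylated>-3'      3'-<cDNA ... stops at Ψ+1>-5'
         |||||||||| k nt                  |||||||||| m nt
   3'-<revcomp(adaptor[1..k])><transcript[Ψ+1..Ψ+m], U→T>-[SpC3]-5'
```

Getting this oligo right by hand is error-prone (two reverse
complements, two coordinate conventions, a mandatory 3′ spacer), and an
incorrect splint fails silently — no ligation, no PCR product, no
explanation. `psibridge` designs the splint from the adaptor and the
transcript context, derives the adaptor-side outer and nested PCR
primers, checks melting-temperature compatibility (Wallace rule and
nearest-neighbor model), and then *proves each design in silico*: a
deterministic simulator runs the whole protocol — CMC adduct → RT stop →
splinted adaptor ligation → outer + nested PCR → junction read-out — and
checks that the recovered Ψ position equals the one the oligo was
designed for, and that the −CMC control arm stays silent.

It is written for bench scientists validating candidate Ψ sites (e.g.
snoRNA-guided sites on rRNA) and for anyone building batch order sheets
of splint oligos.

## Worked example

The validated 18S rRNA reference design (SNORA70-guided Ψ at position
1692). The transcript context is the 18S sequence starting immediately 3′
of the Ψ; splint halves of 15 nt each:

```
$ psibridge design \
    --adaptor TTTCTACTCCTTCAGTCCATGTCAGTGTCCTCGTGCTCCAGTCG \
    --context GUACACACCGCCCGU --k 15 --m 15
CTGAAGGAGTAGAAAGTACACACCGCCCGT[SpC3]
```

`CTGAAGGAGTAGAAA` is the reverse complement of the adaptor's first 15 nt,
`GTACACACCGCCCGT` is the context with U→T, and `[SpC3]` is the 3′ C3
spacer that keeps the splint itself from being extended or ligated. The
adaptor-side PCR primers and their Tm compatibility:

```
$ psibridge primers --adaptor TTTCTACTCCTTCAGTCCATGTCAGTGTCCTCGTGCTCCAGTCG
adaptor_primer          CGACTGGAGCACGAGGACACTGA
adaptor_nested_primer   GGACACTGACATGGACTGAAGGAGTA

$ psibridge tm --method wallace CGACTGGAGCACGAGGACACTGA GGACACTGACATGGACTGAAGGAGTA
CGACTGGAGCACGAGGACACTGA 74.00
GGACACTGACATGGACTGAAGGAGTA      78.00
delta   4.00    compatible
```

And the end-to-end in-silico check (seeded synthetic transcripts, one
planted Ψ each):

```
$ psibridge --seed 1 roundtrip --n 100
{
  "n": 100,
  "n_recovered": 100,
  "n_minus_cmc_amplicons": 0,
  "failures": []
}
```

100/100 means every designed splint ligated only its own Ψ-stopped cDNA
and the inferred junction position matched the planted site; 0 means the
−CMC (no adduct) arm never produced a junction amplicon. Other
subcommands: `batch` (FASTA + Ψ-site TSV → order-sheet CSV), `validate`
(check a hand-made splint or a primer layout), `simulate` (one protocol
pass), `make-fixtures` (synthetic FASTA + TSV). The same operations are
available as library functions (`psibridge.design_bridging_oligo`,
`psibridge.roundtrip`, ...).

## Scope

The package designs and verifies oligo *sets*; it does not model yields,
kinetics or sequencing error, and the protocol it simulates is not
quantitative (nested PCR biases abundance). See `docs/methods.md` for
the model, its assumptions and its limits.
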