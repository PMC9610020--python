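"""The validated 18S rRNA reference oligo set.

These are the oligos of the published CMC/RT-stop splint-ligation workflow
targeting the SNORA70-guided Ψ site at position 1692 of human 18S rRNA.
They serve as regression fixtures (the set is internally consistent: the
bridging oligo's halves are derivable from the adaptor and the 18S context)
and as convenient defaults for simulations.
"""

from __future__ import annotations

from .seqcore import Modification, Oligo, dna

#: Adaptor ligated to the cDNA 3' end; provides the universal PCR priming
#: sites. Commercial oligos arrive unphosphorylated — phosphorylate with
#: :meth:`~psibridge.seqcore.Oligo.with_phosphorylation` before ligation.
ADAPTOR = Oligo("adaptor", dna("TTTCTACTCCTTCAGTCCATGTCAGTGTCCTCGTGCTCCAGTCG"))

#: Bridging (splint) oligo for the 18S Ψ1692 site, 15 nt each side, 3' C3
#: spacer so the splint itself can neither be extended nor ligated.
BRIDGING_OLIGO_18S = Oligo(
    "18s_bridging_oligo",
    dna("CTGAAGGAGTAGAAAGTACACACCGCCCGT"),
    frozenset({Modification.SPC3_3PRIME}),
)

#: Blocking oligo ligated to RNA 5' ends so run-off cDNAs from degraded
#: fragments cannot mimic a Ψ RT stop; the 5' amino-C6 prevents concatemers.
BLOCKING_OLIGO = Oligo(
    "blocking_oligo", dna("ACCCA"), frozenset({Modification.AMC6_5PRIME})
)

#: Outer adaptor-side PCR primer (reverse complement of the adaptor,
#: positions 1-23).
ADAPTOR_PRIMER = Oligo("adaptor_primer", dna("CGACTGGAGCACGAGGACACTGA"))

#: Nested adaptor-side primer (reverse complement of the adaptor,
#: positions 15-40).
ADAPTOR_NESTED_PRIMER = Oligo(
    "adaptor_nested_primer", dna("GGACACTGACATGGACTGAAGGAGTA")
)

#: Gene-specific RT primer for 18S rRNA (antisense).
RT_PRIMER_18S = Oligo("18s_rt_primer", dna("ATCCGAGGGCCTCACTAAAC"))

#: Inner gene-side primer for the nested PCR on 18S (antisense).
NESTED_PRIMER_18S = Oligo("18s_nested_primer", dna("ACCATCCAATCGGTAGTAGCG"))

#: 1-based position of the SNORA70-guided pseudouridine on 18S rRNA.
PSI_18S_POSITION = 1692

#: 18S sequence immediately 3' of the Ψ site (what the designer needs).
CONTEXT_18S = "GUACACACCGCCCGU"
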