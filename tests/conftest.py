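import pytest

from psibridge import Oligo, PsiSite, dna, rna
from psibridge import reference


@pytest.fixture
def adaptor() -> Oligo:
    return reference.ADAPTOR


@pytest.fixture
def phosphorylated_adaptor() -> Oligo:
    return reference.ADAPTOR.with_phosphorylation()


@pytest.fixture
def toy_transcript():
    """20-nt RNA with a pseudouridine at position 7; the RT primer
    GGATGCTC anneals on the 3'-terminal segment [13, 20]."""
    return rna("GGGAUUUCCAUGGAGCAUCC")


@pytest.fixture
def toy_psi() -> PsiSite:
    return PsiSite("toy", 7)


@pytest.fixture
def toy_rt_primer() -> Oligo:
    return Oligo("rt", dna("GGATGCTC"))
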