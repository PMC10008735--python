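import pytest

from serumrna.annotate import KmerIndex, annotate_library, collapse_reads
from serumrna.reference import build_default_reference
from serumrna.simulate import default_mixture_config, sample_fragments


@pytest.fixture(scope="session")
def ref():
    return build_default_reference(1)


@pytest.fixture(scope="session")
def mixture():
    return default_mixture_config()


@pytest.fixture(scope="session")
def kindex(ref):
    return KmerIndex(ref)


@pytest.fixture(scope="session")
def truth20k(ref, mixture):
    """20,000 reads from the default healthy-serum mixture, with truth."""
    return sample_fragments(mixture, ref, 20_000, seed=11)


@pytest.fixture(scope="session")
def library20k(ref, truth20k, kindex):
    reads = collapse_reads(truth20k["sequence"])
    return annotate_library(reads, ref, index=kindex)
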