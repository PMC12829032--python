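import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from epihap.amplicon import AmpliconSpec, onecut2_amplicon


@pytest.fixture(scope="session")
def spec():
    return onecut2_amplicon()


@pytest.fixture(scope="session")
def toy_spec():
    # 6 bp amplicon with one CpG and one convertible non-CpG cytosine
    return AmpliconSpec(name="toy", chrom="chrT", start=1, end=6,
                        ref_seq="ACGTCA", cpg_positions=(1,))
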