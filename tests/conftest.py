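import pytest

from slocus import synth


@pytest.fixture(scope="session")
def locus():
    return synth.make_gene_model(seed=0)


@pytest.fixture(scope="session")
def bundle():
    """Full synthetic cohort (37 pins, 37 thrums, 31 homostyles)."""
    return synth.make_cohort_inputs()
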