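import pytest

from cladetrace.synth import (
    DEFAULT_ADAPTER,
    SynthSpec,
    generate_reference_bundle,
    generate_sample,
)
from cladetrace.io import SampleConfig


@pytest.fixture(scope="session")
def bundle():
    """Small clade-exclusive marker world: 4 clades, 6 families each."""
    return generate_reference_bundle(
        n_clades=4, families_per_clade=6, species_per_family=2, seed=11
    )


@pytest.fixture(scope="session")
def catalog(bundle):
    return bundle.clade_catalog()


@pytest.fixture(scope="session")
def rnatype_db(bundle):
    return bundle.rnatype_db()


@pytest.fixture(scope="session")
def adapter():
    return DEFAULT_ADAPTER


@pytest.fixture(scope="session")
def truseq_cfg():
    return SampleConfig(sample_id="s1", adapter=DEFAULT_ADAPTER)


@pytest.fixture(scope="session")
def clean_sample(bundle):
    """2000 error-free reads from the 'rodent' clade with ground truth."""
    spec = SynthSpec(seed=7, n_reads=2000, per_base_error_rate=0.0, clade="rodent")
    return generate_sample(spec, bundle)
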