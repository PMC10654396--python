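import numpy as np
import pytest

from lmexome.core import (
    FunctionalClass,
    Preservation,
    SampleMeta,
    SiteType,
    VariantCall,
    VariantKey,
    fold_substitution,
)
from lmexome.simulate import SimConfig


def make_call(
    chrom="chr1",
    pos=1000,
    ref="C",
    alt="T",
    callers=("mutect2", "muse"),
    alt_reads=20,
    depth=80,
    germline=0,
    fclass=FunctionalClass.EXONIC_NONSILENT,
    context=None,
):
    return VariantCall(
        key=VariantKey(chrom, pos, ref, alt),
        callers=frozenset(callers),
        tumour_alt_reads=alt_reads,
        depth=depth,
        vaf=alt_reads / depth,
        germline_alt_reads=germline,
        functional_class=fclass,
        substitution=fold_substitution(ref, alt),
        context=context,
    )


@pytest.fixture
def sample_meta():
    return SampleMeta(
        sample_id="S1",
        patient="P1",
        site_type=SiteType.CSF,
        preservation=Preservation.CFDNA,
        purity_model=0.6,
        ploidy_model=2.0,
        purity=0.6,
        ploidy=2.0,
    )


@pytest.fixture
def small_sim_config():
    """Two-patient cohort, cheap enough for per-test simulation."""
    return SimConfig(seed=11, n_patients=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
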