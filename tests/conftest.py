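import pytest

from multisit.simulate import (
    ClusterSpec,
    MultiSitSpec,
    UnitSpec,
    ancestral_unit,
    make_gene_cluster,
    make_mature_unit,
    make_multi_sit,
)


@pytest.fixture(scope="session")
def default_unit():
    """One clean mature unit plus its planted truth (seed 1)."""
    return make_mature_unit(UnitSpec(), seed=1)


@pytest.fixture(scope="session")
def triplicate():
    """Default clean triplicate multi-SIT protein plus truth (seed 2)."""
    spec = MultiSitSpec(seed=2)
    protein, truth = make_multi_sit(spec)
    return spec, protein, truth


@pytest.fixture(scope="session")
def reference_unit(triplicate):
    spec, _, _ = triplicate
    return ancestral_unit(spec)


@pytest.fixture(scope="session")
def gene_cluster():
    """Tandem cluster + paralog contigs with truth (seed 1 multi-SIT)."""
    mspec = MultiSitSpec(seed=1)
    contigs, truth = make_gene_cluster(ClusterSpec(), mspec)
    return mspec, contigs, truth
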