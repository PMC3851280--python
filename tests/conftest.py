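import pytest

from exotriage.io import default_gene_knowledge, load_cohort_fixture, load_phenotype_fixture
from exotriage.model import (
    AnnotatedVariant,
    Consequence,
    PredictorCall,
    Zygosity,
)
from exotriage.prioritize import TriageConfig


@pytest.fixture(scope="session")
def knowledge():
    return default_gene_knowledge()


@pytest.fixture(scope="session")
def cohort_fixture():
    return load_cohort_fixture()


@pytest.fixture(scope="session")
def phenotype_fixture():
    return load_phenotype_fixture()


@pytest.fixture
def config():
    return TriageConfig()


def _calls(damaging=0, neutral=0):
    names = ("PROVEAN", "SIFT", "MutationAssessor", "Condel", "PolyPhen2")
    calls = {}
    for i, name in enumerate(names):
        if i < damaging:
            calls[name] = PredictorCall.DAMAGING
        elif i < damaging + neutral:
            calls[name] = PredictorCall.NEUTRAL
        else:
            calls[name] = PredictorCall.UNKNOWN
    return calls


@pytest.fixture
def make_variant():
    """Factory for a valid variant with overridable fields."""

    counter = iter(range(10_000))

    def factory(
        sample_id="S1",
        gene="GENE1",
        consequence=Consequence.NONSYNONYMOUS,
        af_by_db=None,
        damaging=5,
        neutral=0,
        reads_pct=50.0,
        depth=40,
        known_neutral=False,
        splice_distance=None,
        dbsnp_id=None,
        protein_change="p.Test1Test",
        zygosity=Zygosity.HETEROZYGOUS,
        chrom="chr1",
        start=None,
    ):
        i = next(counter)
        pos = start if start is not None else 1000 + i
        return AnnotatedVariant(
            sample_id=sample_id,
            chrom=chrom,
            start=pos,
            end=pos,
            gene=gene,
            consequence=consequence,
            ref_alt_description=f"c.{pos}A>G",
            protein_change=protein_change,
            zygosity=zygosity,
            read_support_fraction=reads_pct,
            total_depth=depth,
            af_by_db=af_by_db or {},
            dbsnp_id=dbsnp_id,
            predictor_calls=_calls(damaging, neutral),
            known_neutral=known_neutral,
            splice_distance_bases=splice_distance,
        )

    return factory
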