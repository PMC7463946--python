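import pytest
from hypothesis import settings

from strqc.catalog import LocusCatalog, LocusSpec, default_catalog

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")
from strqc.io import Dataset, GenotypeRecord, MetadataDeclaration


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def tetra_spec():
    """Generic tetranucleotide spec used by the allele-grammar tests."""
    return LocusSpec(
        canonical_name="TETRA",
        repeat_unit_length=4,
        allele_range=(3, 50),
        allowed_partials=frozenset({1, 2, 3}),
    )


@pytest.fixture(scope="session")
def toy_catalog():
    """Small catalog with disjoint-range loci for swap tests and the
    D2S441/D2S411 near-collision."""
    return LocusCatalog(
        [
            LocusSpec("AMEL", is_sex_marker=True),
            LocusSpec("TOYA", repeat_unit_length=4, allele_range=(6, 11)),
            LocusSpec("TOYB", repeat_unit_length=4, allele_range=(17, 25)),
            LocusSpec("D2S441", repeat_unit_length=4, allele_range=(8, 17)),
            LocusSpec("D2S411", repeat_unit_length=4, allele_range=(8, 17)),
            LocusSpec(
                "vWA",
                aliases=frozenset({"VWA", "HUMVWA"}),
                repeat_unit_length=4,
                allele_range=(10, 25),
            ),
        ]
    )


def make_dataset(rows, loci, declared_n=None, **meta):
    """Build a Dataset from (sample_id, {locus: alleles}) rows."""
    records = [GenotypeRecord(sample_id=s, genotypes=dict(g)) for s, g in rows]
    defaults = dict(
        population_name="test",
        declared_sample_size=declared_n or len(records),
        declared_loci=list(loci),
    )
    defaults.update(meta)
    return Dataset(
        records=records,
        metadata=MetadataDeclaration(**defaults),
        method="CE",
        source_path="<test>",
        loci=list(loci),
    )


@pytest.fixture
def dataset_builder():
    return make_dataset
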