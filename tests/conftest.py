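import pytest

from famvar import io as fio
from famvar.model import VariantKey
from famvar.table1 import data_path

S361L = VariantKey("19", 55441902, "C", "T")
R801H = VariantKey("19", 55437700, "G", "A")


@pytest.fixture(scope="session")
def gs_pedigrees():
    return fio.read_ped(str(data_path("gs13_gs64.ped")))


@pytest.fixture(scope="session")
def gs13(gs_pedigrees):
    return next(p for p in gs_pedigrees if p.family_id == "GS13")


@pytest.fixture(scope="session")
def gs64(gs_pedigrees):
    return next(p for p in gs_pedigrees if p.family_id == "GS64")


@pytest.fixture(scope="session")
def gs_matrix():
    _, matrix = fio.read_vcf_genotypes(str(data_path("nlrp7_variants.vcf")))
    return matrix


@pytest.fixture(scope="session")
def gs_annotations():
    return fio.read_annotation_table(
        str(data_path("nlrp7_annotation.tsv")), ["exac", "inhouse"]
    )


@pytest.fixture(scope="session")
def table1_counts():
    from famvar.table1 import load_table1_counts

    return load_table1_counts()
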