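import numpy as np
import pytest

from ecmprofiler import load_table1_annotations, load_table1_fixture
from ecmprofiler.io import IdentificationRecord

MEF_SAMPLES = ["CD1 P4", "CD1 P9", "MF1xCD1 P4", "MF1xCD1 P9"]


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_main(table1):
    """The 35 rows detected in HUES1 ECM (reference-only collagen rows excluded)."""
    keep = table1.protein_meta.index[~table1.protein_meta["not_in_HUES1"]]
    return table1.subset(proteins=list(keep))


@pytest.fixture(scope="session")
def table1_annotations():
    return load_table1_annotations()


@pytest.fixture
def rng():
    return np.random.default_rng(20130508)


def make_record(
    sample="s1",
    replicate="rep1",
    accession=None,
    symbol="FN1",
    peptides=2,
    probability=0.99,
    spectra=10,
    decoy=False,
):
    return IdentificationRecord(
        sample_id=sample,
        replicate_id=replicate,
        accession=accession or f"ACC_{symbol}",
        gene_symbol=symbol,
        species="human",
        n_unique_peptides=peptides,
        protein_probability=probability,
        spectrum_count=spectra,
        is_decoy=decoy,
    )
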