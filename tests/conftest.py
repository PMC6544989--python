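import numpy as np
import pytest

from backfold import BuiltinEngine, FoldParams, validate_orf


@pytest.fixture(scope="session")
def params():
    return FoldParams()


@pytest.fixture(scope="session")
def engine(params):
    return BuiltinEngine(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_orf():
    # MVGKL* with a mix of family sizes
    orf = validate_orf("small", "ATGGTGGGTAAACTGTAA")
    return orf


def random_orf_record(rng, n_codons=20, rid="r"):
    """A random valid ORF record: ATG + uniform sense codons + stop."""
    from backfold.sequence_io import SENSE_CODONS, STOP_CODONS, OrfRecord, translate

    body = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons - 2)]
    codons = ("ATG", *body, STOP_CODONS[rng.integers(len(STOP_CODONS))])
    return OrfRecord(rid, codons, translate(codons))
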