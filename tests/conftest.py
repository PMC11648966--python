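import numpy as np
import pytest

from glycopair.digestion import PeptideCandidate
from glycopair.glycans import GlycanBox, builtin_oglycan_database


@pytest.fixture(scope="session")
def oglycan_db():
    return builtin_oglycan_database()


@pytest.fixture(scope="session")
def hexnac_index(oglycan_db):
    return next(i for i, c in enumerate(oglycan_db) if str(c) == "HexNAc(1)")


@pytest.fixture
def gastak():
    return PeptideCandidate("GASTAK", ("P1",))


@pytest.fixture
def hexnac_box(oglycan_db, hexnac_index):
    return GlycanBox.from_indices(oglycan_db, [hexnac_index])


def random_glyco_instance(rng, db, max_box=3, max_len=14):
    """A random peptide/box pair with at least one candidate site."""
    AA = "ACDEFGHIKLMNPQRSTVWY"
    while True:
        length = int(rng.integers(6, max_len + 1))
        seq = "".join(
            AA[i] for i in rng.integers(0, len(AA), size=length)
        )
        pep = PeptideCandidate(seq, ("P",))
        if pep.n_candidate_sites >= 1:
            break
    n = int(rng.integers(1, min(max_box, pep.n_candidate_sites) + 1))
    idx = [int(rng.integers(0, len(db))) for _ in range(n)]
    return pep, GlycanBox.from_indices(db, idx)
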