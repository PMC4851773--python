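import random

import pytest

from hitcluster.seqio import SequenceRecord
from hitcluster.synth import FamilySpec, make_hitset


def rec(accession: str, residues: str, description: str = "") -> SequenceRecord:
    return SequenceRecord(accession, residues, description)


@pytest.fixture(scope="session")
def three_family_hitset():
    """3 planted families x 5 members, ~85 % within-family identity,
    lengths within 10 aa of each other."""
    specs = [FamilySpec(n_members=5, seed_length=120, within_identity_target=85.0,
                        length_jitter=2, rng_seed=100 + i, name=f"fam{i}")
             for i in range(3)]
    return make_hitset(specs)


@pytest.fixture()
def rng():
    return random.Random(20160430)
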