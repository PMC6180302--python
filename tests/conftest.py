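import pytest

from ccmscreen.compounds import Fingerprint
from ccmscreen.target_prediction import AssociationDB, DBCompound


def fp(*features) -> Fingerprint:
    return Fingerprint(frozenset(features), radius=2, nbits=None)


@pytest.fixture
def toy_db():
    """Four reference compounds over two targets; scores are hand-traceable."""
    return AssociationDB([
        DBCompound("c1", fp(1, 2), frozenset({"t1"})),
        DBCompound("c2", fp(2), frozenset({"t1"})),
        DBCompound("c3", fp(3), frozenset({"t2"})),
        DBCompound("c4", fp(1, 3), frozenset({"t2"})),
    ])
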