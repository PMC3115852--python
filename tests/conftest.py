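import pytest

from daswriteback import AnnotationStore, Feature, UserAccount, UserTable
from daswriteback.service import WritebackService


@pytest.fixture
def store():
    return AnnotationStore()


@pytest.fixture
def users():
    return UserTable([UserAccount.create("alice", "secret", "Alice A."),
                      UserAccount.create("bob", "hunter2", "Bob B.")])


@pytest.fixture
def service(store, users):
    return WritebackService(store, users)


@pytest.fixture
def feature():
    return Feature(feature_id="f1", label="test domain",
                   type_id="polypeptide_domain", type_cvid="SO:0000417",
                   type_category="structural",
                   method_id="curator inference", method_cvid="ECO:0000205",
                   start=10, end=20, score=0.9,
                   notes=("hand-curated",),
                   links=(("http://example.org/f1", "evidence"),))
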