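import pytest

from oncointerp import build_reference, load_knowledgebase


@pytest.fixture(scope="session")
def kb():
    return load_knowledgebase()


@pytest.fixture(scope="session")
def references():
    return {c: build_reference(c) for c in ("SBS96", "ID83", "SV32")}


@pytest.fixture(scope="session")
def sbs_ref(references):
    return references["SBS96"]
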