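import pytest

from sdpkit import FIXTURE_NAMES, Reasoner, build_fixture, merge_pattern, sdp_axioms


@pytest.fixture(scope="session")
def pattern_ontology():
    return sdp_axioms()


@pytest.fixture(scope="session")
def merged_reasoners():
    """One saturated reasoner per built-in fixture, pattern merged."""
    out = {}
    for fname in FIXTURE_NAMES:
        spec = build_fixture(fname)
        merged = merge_pattern(spec.ontology)
        out[fname] = (spec, merged, Reasoner(merged))
    return out
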