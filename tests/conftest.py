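import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from ribosplit.seqio import MultipleAlignment, SeqRecord


def make_aln(rows: dict[str, str], marker: str = "other") -> MultipleAlignment:
    return MultipleAlignment(tuple(
        SeqRecord(id=k, residues=v, marker=marker) for k, v in rows.items()))


@pytest.fixture
def aln_factory():
    return make_aln
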