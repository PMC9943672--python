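import pytest

from slac.read_model import EndCall, ReadSet, SingleReadRecord
from slac.simulator import YEAST_PHE_GAA_ID, YEAST_PHE_GAA_SEQ


@pytest.fixture
def phe_reference():
    return {YEAST_PHE_GAA_ID: YEAST_PHE_GAA_SEQ}


@pytest.fixture
def phe_fasta(tmp_path, phe_reference):
    path = tmp_path / "reference.fasta"
    with open(path, "w") as fh:
        for tid, seq in phe_reference.items():
            fh.write(f">{tid}\n{seq}\n")
    return path


def make_read(
    i,
    mismatches=(),
    start=1,
    end=len(YEAST_PHE_GAA_SEQ),
    end_call=EndCall.CCA,
    transcript=YEAST_PHE_GAA_ID,
    deletions=(),
):
    return SingleReadRecord(
        read_id=f"r{i}",
        transcript_id=transcript,
        align_start=start,
        align_end=end,
        mismatch_positions=frozenset(mismatches),
        end_call=end_call,
        deletions=frozenset(deletions),
    )


@pytest.fixture
def make_readset(phe_reference):
    def _make(records, sample_id="test"):
        return ReadSet(sample_id=sample_id, records=list(records), reference=dict(phe_reference))

    return _make
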