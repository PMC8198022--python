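import pytest

from taxoprime import Alignment, SeqRecord, datasets


@pytest.fixture(scope="session")
def matrices():
    return datasets.load_all_matrices()


@pytest.fixture(scope="session")
def primer_table():
    return datasets.load_primer_table()


def make_alignment(rows, marker="marker"):
    """rows: iterable of (genus, species, strain, sequence)."""
    recs = [
        SeqRecord(genus=g, species=sp, strain=st, marker=marker, sequence=seq)
        for g, sp, st, seq in rows
    ]
    return Alignment(marker=marker, records=recs)
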