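import random

import pytest

from mfx.seqio import GeneSequence, ReadPair


@pytest.fixture
def rng():
    return random.Random(1234)


def make_pair(pid="p1", fwd="ACGT" * 25, rev="TGCA" * 25, q=35):
    return ReadPair(
        id=pid,
        fwd_seq=fwd,
        rev_seq=rev,
        fwd_qual=[q] * len(fwd),
        rev_qual=[q] * len(rev),
    )


def make_seq(seq_id, taxon="t1", sequence="ACGT" * 30, gene=None, **annotations):
    return GeneSequence(
        seq_id=seq_id,
        taxon_id=taxon,
        gene_id=gene or seq_id,
        sequence=sequence,
        annotations=dict(annotations),
    )


@pytest.fixture
def fastq_pair_files(tmp_path):
    """Write three well-formed read pairs to parallel FASTQ files."""
    fwd = tmp_path / "r1.fastq"
    rev = tmp_path / "r2.fastq"
    fwd.write_text(
        "@p1/1\nACGTACGT\n+\nIIIIIIII\n"
        "@p2/1\nTTTTACGT\n+\n!!!!IIII\n"
        "@p3/1\nGGGGCCCC\n+\nBBBBBBBB\n"
    )
    rev.write_text(
        "@p1/2\nTGCATGCA\n+\nIIIIIIII\n"
        "@p2/2\nACGTACGT\n+\nIIIIIIII\n"
        "@p3/2\nCCCCGGGG\n+\nBBBBBBBB\n"
    )
    return str(fwd), str(rev)
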