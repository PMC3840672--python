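import pytest

from conftest import make_seq
from mfx.refine import (
    Alignment,
    Cluster,
    clean_alignment,
    filter_clusters,
    pad_align,
    read_aligned_fasta,
    translate_alignment,
    trim_ends,
    write_cluster_fasta,
)
from mfx.seqio import SimilarityHit


def hit(q, s, q_start, q_end):
    length = q_end - q_start + 1
    return SimilarityHit(q, s, 95.0, length, 1, 0, q_start, q_end, 1, length, 1e-40, 150.0)


def cluster_over(taxa, length=100, cid="c1"):
    members = [
        make_seq(f"s{i}", taxon=t, sequence="ACGT" * (length // 4)) for i, t in enumerate(taxa)
    ]
    return Cluster(cid, members)


class TestClusterFilters:
    def test_too_few_taxa_dropped(self):
        kept, dropped = filter_clusters([cluster_over(["t1", "t2", "t3"])], min_taxa=4)
        assert not kept and dropped == {"c1": "taxa"}

    def test_short_members_removed_then_recheck(self):
        members = [make_seq(f"s{i}", taxon=f"t{i}", sequence="ACGT" * 30) for i in range(4)]
        members.append(make_seq("short", taxon="t9", sequence="ACGT" * 11))  # 44 nt
        kept, _ = filter_clusters([Cluster("c1", members)], min_taxa=4, min_seq_len=60)
        assert len(kept) == 1
        assert all(m.seq_id != "short" for m in kept[0].members)

    def test_compliant_cluster_unchanged(self):
        c = cluster_over(["t1", "t2", "t3", "t4", "t5"])
        kept, dropped = filter_clusters([c])
        assert kept == [c] and not dropped

    def test_oversized_cluster_dropped(self):
        members = [make_seq(f"s{i}", taxon=f"t{i % 6}", sequence="A" * 80) for i in range(12)]
        kept, dropped = filter_clusters([Cluster("big", members)], min_taxa=4, max_seqs=10)
        assert not kept and dropped == {"big": "size"}


class TestTrimEnds:
    def test_span_envelope(self):
        member = make_seq("a", taxon="t1", sequence="G" * 500)
        other = make_seq("b", taxon="t2", sequence="G" * 400)
        c = Cluster("c1", [member, other])
        hits = [hit(member.label, other.label, 51, 400), hit(other.label, member.label, 1, 350)]
        out = trim_ends(c, hits)
        by_id = {m.seq_id: m for m in out.members}
        assert len(by_id["a"].sequence) == 350  # [51, 400] 1-based -> 350 nt
        assert len(by_id["b"].sequence) == 350

    def test_union_of_overlapping_spans(self):
        member = make_seq("a", taxon="t1", sequence="C" * 400)
        o1 = make_seq("b", taxon="t2", sequence="C" * 400)
        c = Cluster("c1", [member, o1])
        hits = [
            hit(member.label, o1.label, 20, 100),
            hit(member.label, o1.label, 80, 300),
            hit(o1.label, member.label, 1, 400),
        ]
        out = trim_ends(c, hits)
        trimmed = next(m for m in out.members if m.seq_id == "a")
        assert len(trimmed.sequence) == 300 - 20 + 1  # envelope [20, 300]

    def test_member_without_hits_removed(self):
        # a planted chimeric member has no similarity to the rest
        a = make_seq("a", taxon="t1", sequence="A" * 200)
        b = make_seq("b", taxon="t2", sequence="A" * 200)
        chimera = make_seq("x", taxon="t3", sequence="T" * 200)
        c = Cluster("c1", [a, b, chimera])
        hits = [hit(a.label, b.label, 1, 200), hit(b.label, a.label, 1, 200)]
        out = trim_ends(c, hits)
        assert {m.seq_id for m in out.members} == {"a", "b"}

    def test_never_lengthens_and_substring(self):
        member = make_seq("a", taxon="t1", sequence="ACGTAC" * 50)
        other = make_seq("b", taxon="t2", sequence="ACGTAC" * 50)
        c = Cluster("c1", [member, other])
        hits = [hit(member.label, other.label, 30, 270), hit(other.label, member.label, 1, 300)]
        out = trim_ends(c, hits)
        trimmed = next(m for m in out.members if m.seq_id == "a")
        assert len(trimmed.sequence) <= len(member.sequence)
        assert trimmed.sequence in member.sequence

    def test_orf_coordinates_shifted(self):
        member = make_seq("a", taxon="t1", sequence="A" * 300)
        member.annotations["orf"] = {"frame": 1, "start": 90, "end": 240}
        other = make_seq("b", taxon="t2", sequence="A" * 300)
        c = Cluster("c1", [member, other])
        hits = [hit(member.label, other.label, 61, 270), hit(other.label, member.label, 1, 300)]
        out = trim_ends(c, hits)
        orf = next(m for m in out.members if m.seq_id == "a").annotations["orf"]
        assert (orf["start"], orf["end"]) == (30, 180)


class TestCleanAlignment:
    def test_all_gap_column_removed(self):
        aln = Alignment({"a": "A-" + "A" * 20, "b": "A-" + "A" * 20})
        out = clean_alignment(aln, min_block_len=1)
        assert out.length == 21

    def test_gap_free_alignment_unchanged(self):
        aln = Alignment({"a": "ACGT" * 5, "b": "ACGT" * 5})
        out = clean_alignment(aln)
        assert out.rows == aln.rows

    def test_majority_gap_column_removed(self):
        rows = {f"s{i}": ("-" if i < 3 else "A") + "C" * 15 for i in range(5)}
        out = clean_alignment(Alignment(rows), max_gap_fraction=0.5, min_block_len=1)
        assert out.length == 15  # 3/5 gaps = 0.6 > 0.5

    def test_short_blocks_removed(self):
        # 5 clean columns, a gappy break, then 12 clean columns
        rows = {
            "a": "AAAAA" + "-" * 3 + "C" * 12,
            "b": "AAAAA" + "-" * 3 + "C" * 12,
        }
        out = clean_alignment(Alignment(rows), min_block_len=10)
        assert out.rows["a"] == "C" * 12

    def test_everything_removed_returns_empty(self):
        rows = {"a": "----", "b": "----"}
        out = clean_alignment(Alignment(rows))
        assert out.length == 0 and set(out.rows) == {"a", "b"}


class TestTranslate:
    def test_standard_code(self):
        out = translate_alignment(Alignment({"a": "ATGGCT"}))
        assert out.rows["a"] == "MA"

    def test_gap_codon(self):
        out = translate_alignment(Alignment({"a": "---ATG"}))
        assert out.rows["a"] == "-M"

    def test_internal_stop_becomes_x(self):
        out = translate_alignment(Alignment({"a": "ATGTAAGCT"}))
        assert out.rows["a"] == "MXA"

    def test_partial_gap_codon_is_x(self):
        out = translate_alignment(Alignment({"a": "A--ATG"}))
        assert out.rows["a"] == "XM"

    def test_length_not_divisible_errors(self):
        with pytest.raises(ValueError):
            translate_alignment(Alignment({"a": "ACGTA"}))

    def test_protein_length_is_third(self):
        aln = Alignment({"a": "ACG" * 17, "b": "TTT" * 17})
        out = translate_alignment(aln)
        assert all(len(r) == 17 for r in out.rows.values())


class TestAlignerInterface:
    def test_pad_align_rows_equal_length(self):
        c = Cluster(
            "c1",
            [
                make_seq("a", taxon="t1", sequence="ACGT" * 10),
                make_seq("b", taxon="t2", sequence="ACGT" * 8),
            ],
        )
        aln = pad_align(c)
        assert aln.length == 40
        assert aln.rows["t2@b"].endswith("-" * 8)

    def test_fasta_roundtrip_through_external_interface(self, tmp_path):
        c = cluster_over(["t1", "t2"], length=40)
        path = str(tmp_path / "c1.fa")
        write_cluster_fasta(c, path)
        aln = read_aligned_fasta(path)
        assert set(aln.labels) == {m.label for m in c.members}

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            Alignment({"a": "ACGT", "b": "ACG"})
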