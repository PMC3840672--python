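import random

import pytest

from conftest import make_pair, make_seq
from oracles import longest_orf_oracle
from mfx.screen import (
    KmerMatcher,
    estimate_insert_size,
    find_longest_orf,
    flag_transcripts,
    remove_rrna_reads,
    select_exemplars,
    subset_reads,
    template_lengths_from_sam,
)
from mfx.seqio import reverse_complement


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestInsertSize:
    @pytest.mark.parametrize(
        "lengths, mean, var",
        [
            ([266, 266, 266], 266.0, 0.0),
            ([100], 100.0, 0.0),
            ([200, 300], 250.0, 5000.0),
        ],
    )
    def test_closed_forms(self, lengths, mean, var):
        est = estimate_insert_size(lengths)
        assert est.mean == pytest.approx(mean)
        assert est.variance == pytest.approx(var)
        assert est.n_observations == len(lengths)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no proper pairs"):
            estimate_insert_size([])

    def test_template_lengths_from_sam(self, tmp_path):
        sam = tmp_path / "aln.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref1\tLN:5000\n"
            "r1\t99\tref1\t1\t60\t100M\t=\t167\t266\t*\t*\n"
            "r1\t147\tref1\t167\t60\t100M\t=\t1\t-266\t*\t*\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
        )
        lengths = template_lengths_from_sam(str(sam))
        # both mates contribute |TLEN|; the unmapped record (TLEN 0) is skipped
        assert lengths == [266, 266]


class TestSubsets:
    def test_prefix_property(self):
        pairs = [make_pair(pid=f"p{i}") for i in range(100)]
        small, big = subset_reads(pairs, [10, 50])
        assert len(small) == 10 and len(big) == 50
        assert [p.id for p in big[:10]] == [p.id for p in small]

    def test_clamp_with_warning(self, caplog):
        pairs = [make_pair(pid=f"p{i}") for i in range(100)]
        (subset,) = subset_reads(pairs, [200])
        assert len(subset) == 100

    def test_empty_sizes(self):
        assert subset_reads([make_pair()], []) == []


class TestKmerScreening:
    def test_exact_substring_read_removed(self, rng):
        ref = random_seq(rng, 600)
        matcher = KmerMatcher([ref], k=25)
        inside = ref[100:200]
        pair = make_pair(pid="rr", fwd=inside, rev=reverse_complement(inside))
        retained, removed, fraction = remove_rrna_reads([pair], matcher=matcher)
        assert removed and not retained and fraction == 1.0

    def test_unrelated_read_retained(self, rng):
        ref = random_seq(rng, 600)
        other = random_seq(rng, 100)
        matcher = KmerMatcher([ref], k=25)
        retained, removed, fraction = remove_rrna_reads(
            [make_pair(pid="x", fwd=other, rev=reverse_complement(other))], matcher=matcher
        )
        assert retained and not removed and fraction == 0.0

    def test_fraction_partitions_input(self, rng):
        ref = random_seq(rng, 2000)
        matcher = KmerMatcher([ref], k=25)
        pairs = []
        for i in range(20):  # 20% true rRNA pairs
            if i < 4:
                start = rng.randint(0, 1800)
                frag = ref[start : start + 100]
            else:
                frag = random_seq(rng, 100)
            pairs.append(make_pair(pid=f"p{i}", fwd=frag, rev=reverse_complement(frag)))
        retained, removed, fraction = remove_rrna_reads(pairs, matcher=matcher)
        assert len(retained) + len(removed) == len(pairs)
        assert fraction == len(removed) / len(pairs) == pytest.approx(0.2)

    def test_empty_stream_errors(self, rng):
        matcher = KmerMatcher([random_seq(rng, 100)], k=25)
        with pytest.raises(ValueError, match="undefined"):
            remove_rrna_reads([], matcher=matcher)

    def test_transcript_flagging(self, rng):
        ref = random_seq(rng, 500)
        matcher = KmerMatcher([ref], k=25)
        # an 80-nt verbatim segment (56 shared 25-mers) inside short unrelated
        # flanks: 56/106 k-mers shared, over the 50% containment rule
        with_segment = random_seq(rng, 25) + ref[50:130] + random_seq(rng, 25)
        clean = random_seq(rng, 130)
        transcripts = [
            make_seq("hit", sequence=with_segment),
            make_seq("clean", sequence=clean),
        ]
        flag_transcripts(transcripts, matcher, "is_rrna")
        flagged = {t.seq_id: t.annotations["is_rrna"] for t in transcripts}
        assert flagged == {"hit": True, "clean": False}

    def test_half_shared_boundary_flagged(self, rng):
        # construct a transcript sharing exactly >= 50% of its k-mers
        ref = random_seq(rng, 400)
        matcher = KmerMatcher([ref], k=25, min_shared_fraction=0.5)
        shared_part = ref[0:124]  # 100 shared 25-mers
        foreign = random_seq(rng, 100)  # appended: most of its k-mers unshared
        transcript = make_seq("b", sequence=shared_part + foreign)
        frac = matcher.shared_fraction(transcript.sequence)
        flag_transcripts([transcript], matcher, "is_rrna")
        assert transcript.annotations["is_rrna"] == (frac >= 0.5)
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_k_lower_bound(self):
        with pytest.raises(ValueError):
            KmerMatcher(["ACGTACGTACGTACGT"], k=5)


class TestLongestOrf:
    def test_no_stop_anywhere_prefers_frame_plus1(self):
        assert find_longest_orf("A" * 12) == (1, 0, 12)

    def test_reverse_frame_beats_forward(self):
        # +1 has stops flanking a 9-nt run, but the reverse strand of this
        # sequence is stop-free over all 15 nt
        assert find_longest_orf("TAAATGAAAAAATAA") == (-1, 0, 15)

    def test_short_sequence_errors(self):
        with pytest.raises(ValueError):
            find_longest_orf("AC")

    def test_oracle_equivalence_on_random_sequences(self):
        rng = random.Random(2024)
        for _ in range(300):
            seq = random_seq(rng, 300)
            assert find_longest_orf(seq) == longest_orf_oracle(seq), seq


class TestExemplars:
    def test_highest_expression_wins(self):
        iso = [
            make_seq("i1", gene="g", expression=10.0),
            make_seq("i2", gene="g", expression=3.2),
        ]
        exemplars, dropped = select_exemplars(iso)
        assert [e.seq_id for e in exemplars] == ["i1"] and not dropped

    def test_tie_breaks_on_length_then_id(self):
        iso = [
            make_seq("b", gene="g", sequence="A" * 300, expression=5.0),
            make_seq("a", gene="g", sequence="A" * 500, expression=5.0),
        ]
        exemplars, _ = select_exemplars(iso)
        assert exemplars[0].seq_id == "a"
        iso2 = [
            make_seq("z", gene="g", sequence="A" * 300, expression=5.0),
            make_seq("y", gene="g", sequence="C" * 300, expression=5.0),
        ]
        exemplars2, _ = select_exemplars(iso2)
        assert exemplars2[0].seq_id == "y"

    def test_flagged_isoforms_excluded(self):
        iso = [
            make_seq("i1", gene="g", expression=10.0, is_rrna=True),
            make_seq("i2", gene="g", expression=3.2),
        ]
        exemplars, _ = select_exemplars(iso)
        assert [e.seq_id for e in exemplars] == ["i2"]

    def test_fully_flagged_gene_dropped(self):
        iso = [make_seq("i1", gene="g", is_vector=True)]
        exemplars, dropped = select_exemplars(iso)
        assert not exemplars and dropped == ["g"]

    def test_one_exemplar_per_gene(self):
        iso = [
            make_seq(f"g{g}i{i}", gene=f"g{g}", expression=float(i))
            for g in range(5)
            for i in range(3)
        ]
        exemplars, _ = select_exemplars(iso)
        assert sorted(e.gene_id for e in exemplars) == [f"g{g}" for g in range(5)]
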