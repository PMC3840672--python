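"""Screening and annotation: rRNA/vector detection, insert size, ORFs, exemplars.

Read mapping and blastn screens are replaced here by a canonical k-mer
containment matcher: a sequence is flagged when at least
``min_shared_fraction`` of its k-mers occur in the reference k-mer set.  The
matcher fills the same decision role deterministically and without external
binaries, and sits behind a small interface so a mapping-based screener can
be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

from .seqio import GeneSequence, ReadPair, read_fasta, reverse_complement

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: frame scan order used for tie-breaking
FRAME_ORDER = (1, 2, 3, -1, -2, -3)


# ---------------------------------------------------------------------------
# k-mer matcher
# ---------------------------------------------------------------------------

class KmerMatcher:
    """Canonical k-mer containment classifier against a reference set.

    k-mers containing non-ACGT characters are skipped; each k-mer is stored
    as the lexicographic minimum of itself and its reverse complement, so
    matching is strand-symmetric.
    """

    def __init__(
        self,
        references: str | Iterable,
        k: int = 25,
        min_shared_fraction: float = 0.5,
    ):
        if k < 11:
            raise ValueError("k must be >= 11")
        self.k = k
        self.min_shared_fraction = min_shared_fraction
        if isinstance(references, str):
            references = read_fasta(references)
        self.reference_kmers: set[str] = set()
        for ref in references:
            seq = ref.sequence if isinstance(ref, GeneSequence) else str(ref)
            self.reference_kmers.update(self._kmers(seq))
        if not self.reference_kmers:
            raise ValueError("reference k-mer set is empty")

    def _kmers(self, seq: str) -> Iterable[str]:
        seq = seq.upper()
        rc = reverse_complement(seq)
        n = len(seq)
        for i in range(n - self.k + 1):
            kmer = seq[i : i + self.k]
            if set(kmer) <= {"A", "C", "G", "T"}:
                yield min(kmer, rc[n - self.k - i : n - i])

    def shared_fraction(self, seq: str) -> float:
        """Fraction of the sequence's k-mers present in the reference set."""
        kmers = list(self._kmers(seq))
        if not kmers:
            return 0.0
        shared = sum(1 for km in kmers if km in self.reference_kmers)
        return shared / len(kmers)

    def matches(self, seq: str) -> bool:
        return self.shared_fraction(seq) >= self.min_shared_fraction


# ---------------------------------------------------------------------------
# insert size
# ---------------------------------------------------------------------------

@dataclass
class InsertSizeEstimate:
    mean: float
    variance: float
    n_observations: int


def estimate_insert_size(template_lengths: Sequence[int]) -> InsertSizeEstimate:
    """Mean and unbiased sample variance of paired-end template lengths.

    Variance is 0 for a single observation; empty input is an error.
    """
    if len(template_lengths) == 0:
        raise ValueError("no proper pairs")
    arr = np.asarray(template_lengths, dtype=float)
    mean = float(arr.mean())
    variance = float(arr.var(ddof=1)) if arr.size > 1 else 0.0
    return InsertSizeEstimate(mean=mean, variance=variance, n_observations=int(arr.size))


def template_lengths_from_sam(path: str) -> list[int]:
    """Absolute template lengths (TLEN field) from a SAM file, zeros skipped."""
    lengths: list[int] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            t = abs(rec.template_length)
            if t > 0:
                lengths.append(t)
    return lengths


# ---------------------------------------------------------------------------
# read subsetting and rRNA removal
# ---------------------------------------------------------------------------

def subset_reads(
    pairs: Sequence[ReadPair], subset_sizes: Sequence[int], seed: int | None = None
) -> list[list[ReadPair]]:
    """Nested prefix subsets of an (already randomized) pair stream.

    Larger subsets contain smaller ones.  Sizes exceeding the available
    number of pairs are clamped with a warning.  ``seed`` is accepted for
    interface symmetry; the stream order itself carries the randomization.
    """
    subsets = []
    for size in subset_sizes:
        if size > len(pairs):
            logger.warning(
                "requested subset of %d pairs but only %d available; clamping",
                size,
                len(pairs),
            )
            size = len(pairs)
        subsets.append(list(pairs[:size]))
    return subsets


def remove_rrna_reads(
    pairs: Sequence[ReadPair],
    rrna_reference: str | Iterable | None = None,
    matcher: KmerMatcher | None = None,
    k: int = 25,
    min_shared_fraction: float = 0.5,
) -> tuple[list[ReadPair], list[ReadPair], float]:
    """Partition pairs into (retained, removed) by rRNA k-mer containment.

    A pair is removed when either mate shares at least ``min_shared_fraction``
    of its k-mers with the rRNA reference.  Returns the removed fraction of
    all input pairs — reported to aid library-preparation feedback.
    """
    if matcher is None:
        if rrna_reference is None:
            raise ValueError("either an rRNA reference or a matcher is required")
        matcher = KmerMatcher(rrna_reference, k=k, min_shared_fraction=min_shared_fraction)
    if len(pairs) == 0:
        raise ValueError("empty read stream: rRNA fraction undefined")
    retained, removed = [], []
    for pair in pairs:
        if matcher.matches(pair.fwd_seq) or matcher.matches(pair.rev_seq):
            removed.append(pair)
        else:
            retained.append(pair)
    fraction = len(removed) / len(pairs)
    return retained, removed, fraction


def flag_transcripts(
    transcripts: Iterable[GeneSequence],
    matcher: KmerMatcher,
    flag_name: str,
) -> list[GeneSequence]:
    """Set a boolean screening flag (is_rrna / is_vector) on each transcript.

    Transcripts are annotated in place and returned; nothing is deleted here.
    """
    if flag_name not in ("is_rrna", "is_vector"):
        raise ValueError(f"unknown flag {flag_name!r}")
    out = []
    for t in transcripts:
        t.annotations[flag_name] = matcher.matches(t.sequence)
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# longest ORF
# ---------------------------------------------------------------------------

def find_longest_orf(sequence: str) -> tuple[int, int, int]:
    """Longest stop-free codon run over all six reading frames.

    An ORF here is stop-to-stop: a maximal run of codons containing no stop
    codon, with no start-codon requirement (transcriptome fragments often
    truncate 5' ends).  Partial terminal codons are ignored.  Returns
    ``(frame, start, end)`` with frame in {+1,+2,+3,-1,-2,-3} and start/end
    0-based half-open on the forward strand.  Ties are broken by frame order
    +1,+2,+3,-1,-2,-3, then by smaller forward-strand start.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 3:
        raise ValueError("sequence shorter than one codon")
    rc = reverse_complement(seq)
    best_key: tuple[int, int, int] | None = None  # (-length, frame_idx, start); min wins
    best_coords = (1, 0, 0)
    for frame_idx, frame in enumerate(FRAME_ORDER):
        strand_seq = seq if frame > 0 else rc
        for run_start, run_end in _stop_free_runs(strand_seq, abs(frame) - 1):
            fwd_start, fwd_end = _to_forward(run_start, run_end, n, frame)
            key = (-(run_end - run_start), frame_idx, fwd_start)
            if best_key is None or key < best_key:
                best_key = key
                best_coords = (frame, fwd_start, fwd_end)
    return best_coords


def _stop_free_runs(strand_seq: str, offset: int) -> list[tuple[int, int]]:
    """Maximal [start, end) codon-aligned runs free of stop codons in one frame."""
    runs: list[tuple[int, int]] = []
    run_start = offset
    pos = offset
    n = len(strand_seq)
    while pos + 3 <= n:
        if strand_seq[pos : pos + 3] in STOP_CODONS:
            if pos > run_start:
                runs.append((run_start, pos))
            run_start = pos + 3
        pos += 3
    if pos > run_start:
        runs.append((run_start, pos))
    return runs


def _to_forward(start: int, end: int, n: int, frame: int) -> tuple[int, int]:
    """Map a [start, end) interval on the frame's strand to forward-strand coords."""
    if frame > 0:
        return start, end
    return n - end, n - start


def annotate_orfs(transcripts: Iterable[GeneSequence]) -> list[GeneSequence]:
    """Attach the longest-ORF annotation to each transcript (in place)."""
    out = []
    for t in transcripts:
        if len(t.sequence) >= 3:
            frame, start, end = find_longest_orf(t.sequence)
            if end > start:
                t.annotations["orf"] = {"frame": frame, "start": start, "end": end}
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# exemplar selection
# ---------------------------------------------------------------------------

def select_exemplars(
    transcripts: Iterable[GeneSequence],
) -> tuple[list[GeneSequence], list[str]]:
    """Pick one exemplar transcript per gene_id: the splice variant with the
    highest expression; ties go to the longest sequence, then the
    lexicographically smallest seq_id.

    Transcripts flagged is_rrna or is_vector are excluded before selection;
    genes whose transcripts are all flagged are dropped and returned in the
    second element.
    """
    by_gene: dict[str, list[GeneSequence]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    exemplars: list[GeneSequence] = []
    dropped: list[str] = []
    for gene_id in sorted(by_gene):
        candidates = [
            t
            for t in by_gene[gene_id]
            if not t.annotations.get("is_rrna") and not t.annotations.get("is_vector")
        ]
        if not candidates:
            logger.info("gene %s dropped: all isoforms flagged", gene_id)
            dropped.append(gene_id)
            continue
        candidates.sort(
            key=lambda t: (
                -float(t.annotations.get("expression", 0.0)),
                -len(t.sequence),
                t.seq_id,
            )
        )
        exemplars.append(candidates[0])
    return exemplars, dropped
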