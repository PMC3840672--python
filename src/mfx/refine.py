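"""Cluster refinement: sampling/length filters, hit-span end trimming,
simplified alignment cleaning, and codon-to-protein translation.

The multiple aligner itself is an external interface: clusters are written
as unaligned per-cluster FASTA and aligned FASTA is consumed back (a
frameshift-aware aligner is the intended external tool).  ``pad_align`` is a
trivial built-in stand-in used in tests and on the synthetic pipeline, where
family members are columnwise homologous by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Seq import Seq

from .seqio import GeneSequence, SimilarityHit, taxon_of

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class Cluster:
    cluster_id: str
    members: list[GeneSequence]
    source: str = "homologize"  # or "treeprune"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id}: no members")
        labels = [m.label for m in self.members]
        if len(labels) != len(set(labels)):
            raise ValueError(f"cluster {self.cluster_id}: duplicate members")

    @property
    def taxa(self) -> set[str]:
        return {m.taxon_id for m in self.members}


@dataclass
class Alignment:
    """Ordered map of seq label -> aligned row; all rows equal length."""

    rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        for r in self.rows.values():
            return len(r)
        return 0

    @property
    def labels(self) -> list[str]:
        return list(self.rows)


def filter_clusters(
    clusters: Iterable[Cluster],
    min_taxa: int = 4,
    min_seq_len: int = 60,
    max_seqs: int = 100,
) -> tuple[list[Cluster], dict[str, str]]:
    """Sampling and length filters on homolog clusters.

    Sequences shorter than ``min_seq_len`` are removed first; clusters are
    then dropped if they span fewer than ``min_taxa`` distinct taxa or hold
    more than ``max_seqs`` members.  Returns (survivors, drop reasons by
    cluster_id).
    """
    kept: list[Cluster] = []
    dropped: dict[str, str] = {}
    for cluster in clusters:
        members = [m for m in cluster.members if len(m.sequence) >= min_seq_len]
        if not members:
            dropped[cluster.cluster_id] = "length"
            continue
        survivor = Cluster(cluster.cluster_id, members, cluster.source)
        if len(survivor.taxa) < min_taxa:
            dropped[cluster.cluster_id] = "taxa"
        elif len(members) > max_seqs:
            dropped[cluster.cluster_id] = "size"
        else:
            kept.append(survivor)
    for cid, reason in dropped.items():
        logger.info("cluster %s dropped (%s)", cid, reason)
    return kept, dropped


def trim_ends(cluster: Cluster, intra_hits: Iterable[SimilarityHit]) -> Cluster | None:
    """Trim member ends that have no similarity to other members.

    For each member the union of its query-side hit spans against *other*
    members is computed and the sequence cut to the envelope
    [min start, max end] of that union — only the ends are trimmed, interior
    gaps in hit coverage are kept.  Members with no qualifying hits (which
    could be chimeric or misassigned) are removed.  ORF annotations are
    shifted into the new coordinate system.  Returns None if no member
    survives.
    """
    labels = {m.label for m in cluster.members}
    spans: dict[str, list[tuple[int, int]]] = {}
    for hit in intra_hits:
        if hit.query_id in labels and hit.subject_id in labels and hit.query_id != hit.subject_id:
            # convert 1-based inclusive to 0-based half-open
            spans.setdefault(hit.query_id, []).append((hit.q_start - 1, hit.q_end))
    trimmed: list[GeneSequence] = []
    for member in cluster.members:
        member_spans = spans.get(member.label)
        if not member_spans:
            logger.info(
                "cluster %s: member %s removed (no intra-cluster hits)",
                cluster.cluster_id,
                member.label,
            )
            continue
        start = min(s for s, _ in member_spans)
        end = max(e for _, e in member_spans)
        end = min(end, len(member.sequence))
        if end <= start:
            logger.info(
                "cluster %s: member %s removed (empty trim span)",
                cluster.cluster_id,
                member.label,
            )
            continue
        annotations = dict(member.annotations)
        orf = annotations.get("orf")
        if orf is not None:
            new_start = max(orf["start"] - start, 0)
            new_end = min(orf["end"] - start, end - start)
            if new_end > new_start:
                annotations["orf"] = {"frame": orf["frame"], "start": new_start, "end": new_end}
            else:
                annotations.pop("orf")
        trimmed.append(
            GeneSequence(
                seq_id=member.seq_id,
                taxon_id=member.taxon_id,
                gene_id=member.gene_id,
                sequence=member.sequence[start:end],
                annotations=annotations,
            )
        )
    if not trimmed:
        return None
    return Cluster(cluster.cluster_id, trimmed, cluster.source)


def clean_alignment(
    aln: Alignment, max_gap_fraction: float = 0.5, min_block_len: int = 10
) -> Alignment:
    """Simplified gap-block cleaning of a multiple sequence alignment.

    Columns whose gap fraction exceeds ``max_gap_fraction`` are removed;
    the remaining columns are grouped into maximal contiguous runs and runs
    shorter than ``min_block_len`` are removed too.  Row order is preserved.
    An alignment that loses every column is returned empty with a warning.
    """
    labels = aln.labels
    if not labels:
        return Alignment({})
    n_rows = len(labels)
    keep: list[int] = []
    for col in range(aln.length):
        gaps = sum(1 for label in labels if aln.rows[label][col] == GAP)
        if gaps / n_rows <= max_gap_fraction:
            keep.append(col)
    blocks: list[list[int]] = []
    for col in keep:
        if blocks and col == blocks[-1][-1] + 1:
            blocks[-1].append(col)
        else:
            blocks.append([col])
    cols = [c for b in blocks if len(b) >= min_block_len for c in b]
    if not cols:
        logger.warning("alignment cleaning removed every column")
        return Alignment({label: "" for label in labels})
    return Alignment({label: "".join(aln.rows[label][c] for c in cols) for label in labels})


def translate_alignment(aln: Alignment) -> Alignment:
    """Translate an in-frame nucleotide alignment to protein.

    Standard genetic code; the all-gap codon ``---`` becomes ``-``; codons
    containing a partial gap become ``X``; stop codons become ``X`` (internal
    stops additionally log a warning, as they usually indicate a frameshift
    or misannotated frame).  Row lengths must be divisible by 3.
    """
    out: dict[str, str] = {}
    for label, row in aln.rows.items():
        if len(row) % 3 != 0:
            raise ValueError(f"row {label}: length {len(row)} not divisible by 3")
        aas: list[str] = []
        n_codons = len(row) // 3
        for i in range(n_codons):
            codon = row[3 * i : 3 * i + 3]
            if codon == "---":
                aas.append("-")
            elif GAP in codon:
                aas.append("X")
            else:
                aa = str(Seq(codon).translate())
                if aa == "*":
                    if i < n_codons - 1:
                        logger.warning("row %s: internal stop codon at codon %d", label, i)
                    aa = "X"
                aas.append(aa)
        out[label] = "".join(aas)
    return Alignment(out)


def pad_align(cluster: Cluster) -> Alignment:
    """Trivial built-in "aligner": pad every member with trailing gaps.

    Only meaningful where members are already columnwise homologous (as the
    indel-free synthetic gene families are); real data should go through an
    external multiple aligner.
    """
    width = max(len(m.sequence) for m in cluster.members)
    return Alignment({m.label: m.sequence.ljust(width, GAP) for m in cluster.members})


def write_cluster_fasta(cluster: Cluster, path: str) -> None:
    """Emit a cluster as unaligned FASTA for an external aligner."""
    with open(path, "w") as fh:
        for m in cluster.members:
            fh.write(f">{m.label}\n{m.sequence}\n")


def read_aligned_fasta(path: str) -> Alignment:
    """Consume an externally produced aligned FASTA back into an Alignment."""
    from Bio import SeqIO

    rows: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        rows[record.id] = str(record.seq).upper()
    if not rows:
        raise ValueError(f"no records in {path}")
    return Alignment(rows)


def cluster_taxa(aln: Alignment) -> set[str]:
    return {taxon_of(label) for label in aln.labels}
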