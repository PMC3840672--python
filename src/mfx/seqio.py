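"""Domain types, standard-format readers/writers, and the dataset catalog.

Sequence identifiers are namespaced internally as ``<taxon_id>@<seq_id>`` so
that leaves of gene trees and nodes of the homology graph are unambiguous
across datasets; ``@`` is therefore reserved and rejected in user-supplied
identifiers.  All internal coordinates are 0-based half-open; external
formats (the 12-column hit table, partition files) keep their native 1-based
inclusive conventions, converted at the I/O boundary.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

NAMESPACE_SEP = "@"

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "align_len",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
]


def _check_id(value: str, what: str) -> str:
    if not value:
        raise ValueError(f"{what} must be non-empty")
    if NAMESPACE_SEP in value:
        raise ValueError(
            f"{what} {value!r} contains reserved character {NAMESPACE_SEP!r}"
        )
    return value


def make_label(taxon_id: str, seq_id: str) -> str:
    """Build the namespaced ``taxon@seq`` label used on graph nodes and tree leaves."""
    return f"{taxon_id}{NAMESPACE_SEP}{seq_id}"


def split_label(label: str) -> tuple[str, str]:
    """Split a namespaced label back into (taxon_id, seq_id)."""
    if NAMESPACE_SEP not in label:
        raise ValueError(f"label {label!r} is not namespaced as taxon@seq")
    taxon, seq_id = label.split(NAMESPACE_SEP, 1)
    return taxon, seq_id


def taxon_of(label: str) -> str:
    """Taxon part of a namespaced label (the whole label if not namespaced)."""
    return label.split(NAMESPACE_SEP, 1)[0]


@dataclass
class ReadPair:
    """A mated pair of reads with per-base Phred quality scores."""

    id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: list[int]
    rev_qual: list[int]

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual):
            raise ValueError(f"pair {self.id}: forward sequence/quality length mismatch")
        if len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"pair {self.id}: reverse sequence/quality length mismatch")
        for q in self.fwd_qual + self.rev_qual:
            if not 0 <= q <= 93:
                raise ValueError(f"pair {self.id}: Phred quality {q} outside [0, 93]")


@dataclass
class GeneSequence:
    """A nucleotide sequence with taxon/gene annotations.

    ``annotations`` may hold:

    ``orf``
        dict with keys ``frame`` (one of +-1..3), ``start``, ``end``
        (0-based half-open on the forward strand).
    ``is_rrna``, ``is_vector``
        screening flags.
    ``expression``
        non-negative expression value from an external quantifier.
    """

    seq_id: str
    taxon_id: str = ""
    gene_id: str = ""
    sequence: str = ""
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_id(self.seq_id, "seq_id")
        if self.taxon_id:
            _check_id(self.taxon_id, "taxon_id")
        orf = self.annotations.get("orf")
        if orf is not None:
            if not (0 <= orf["start"] < orf["end"] <= len(self.sequence)):
                raise ValueError(
                    f"sequence {self.seq_id}: ORF coordinates "
                    f"[{orf['start']}, {orf['end']}) outside sequence"
                )

    @property
    def label(self) -> str:
        return make_label(self.taxon_id, self.seq_id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimilarityHit:
    """One row of a 12-column tabular similarity search (BLAST outfmt-6 dialect).

    Coordinates are 1-based inclusive, as in the format itself.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.align_len < 1:
            raise ValueError("align_len must be >= 1")


@dataclass
class CatalogEntry:
    catalog_id: str
    species: str
    taxon_id: str
    data_paths: list[str]
    data_kind: str  # "raw_reads" | "assembled_genes"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.catalog_id:
            raise ValueError("catalog_id must be non-empty")
        if not self.data_paths:
            raise ValueError("data_paths must be non-empty")
        if self.data_kind not in ("raw_reads", "assembled_genes"):
            raise ValueError(f"unknown data_kind {self.data_kind!r}")


@dataclass
class StageCount:
    run_id: str
    stage_name: str
    n_sequences: int

    def __post_init__(self) -> None:
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be >= 0")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def _pair_id(record_id: str) -> str:
    for suffix in ("/1", "/2"):
        if record_id.endswith(suffix):
            return record_id[: -len(suffix)]
    return record_id


def read_fastq_pairs(fwd_path: str, rev_path: str) -> Iterator[ReadPair]:
    """Stream mated read pairs from two parallel Phred+33 FASTQ files.

    Record *i* of the forward file mates record *i* of the reverse file.
    Raises ``ValueError`` on malformed records (naming the record index) or
    unequal pair counts.
    """
    fwd_iter = SeqIO.parse(fwd_path, "fastq")
    rev_iter = SeqIO.parse(rev_path, "fastq")
    index = 0
    sentinel = object()
    while True:
        try:
            fwd = next(fwd_iter, sentinel)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record {index} in {fwd_path}: {exc}")
        try:
            rev = next(rev_iter, sentinel)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record {index} in {rev_path}: {exc}")
        if fwd is sentinel and rev is sentinel:
            return
        if fwd is sentinel or rev is sentinel:
            raise ValueError(
                f"unequal pair counts: {fwd_path} and {rev_path} differ at record {index}"
            )
        yield ReadPair(
            id=_pair_id(fwd.id),
            fwd_seq=str(fwd.seq).upper(),
            rev_seq=str(rev.seq).upper(),
            fwd_qual=list(fwd.letter_annotations["phred_quality"]),
            rev_qual=list(rev.letter_annotations["phred_quality"]),
        )
        index += 1


def write_fastq_pairs(pairs: Iterable[ReadPair], fwd_path: str, rev_path: str) -> int:
    """Write pairs to two parallel Phred+33 FASTQ files; returns pair count."""
    n = 0
    with open(fwd_path, "w") as fwd_fh, open(rev_path, "w") as rev_fh:
        for pair in pairs:
            fwd_fh.write(_fastq_record(pair.id + "/1", pair.fwd_seq, pair.fwd_qual))
            rev_fh.write(_fastq_record(pair.id + "/2", pair.rev_seq, pair.rev_qual))
            n += 1
    return n


def _fastq_record(rid: str, seq: str, qual: list[int]) -> str:
    qline = "".join(chr(q + 33) for q in qual)
    return f"@{rid}\n{seq}\n+\n{qline}\n"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str,
    taxon_id: str = "",
    gene_id_func=None,
    namespaced: bool = False,
) -> list[GeneSequence]:
    """Read gene sequences from FASTA.

    The first whitespace-delimited header token is the seq_id.  Sequences are
    uppercased and U is mapped to T.  ``gene_id_func(seq_id) -> gene_id``
    configures how isoform groups are derived from headers (default: the
    seq_id itself, i.e. one gene per sequence).  With ``namespaced=True``
    headers are ``taxon@seq`` labels (as written by
    ``write_fasta(..., namespaced=True)``) and are split back into
    taxon_id/seq_id.
    """
    if gene_id_func is None:
        gene_id_func = lambda sid: sid  # noqa: E731
    out: list[GeneSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(path, "fasta"):
        sid = record.id
        if sid in seen:
            raise ValueError(f"duplicate seq_id {sid!r} in {path}")
        seen.add(sid)
        seq = str(record.seq).upper().replace("U", "T")
        rec_taxon = taxon_id
        if namespaced:
            rec_taxon, sid = split_label(sid)
        out.append(
            GeneSequence(
                seq_id=sid,
                taxon_id=rec_taxon,
                gene_id=gene_id_func(sid),
                sequence=seq,
            )
        )
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: Iterable[GeneSequence], path: str, namespaced: bool = False) -> int:
    """Write sequences to FASTA (IDs optionally namespaced as taxon@seq)."""
    n = 0
    with open(path, "w") as fh:
        for s in seqs:
            name = s.label if namespaced else s.seq_id
            fh.write(f">{name}\n{s.sequence}\n")
            n += 1
    return n


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# 12-column hit table
# ---------------------------------------------------------------------------

def read_hit_table(path: str) -> list[SimilarityHit]:
    """Parse a 12-column tab-separated similarity hit table.

    Accepts scientific-notation e-values.  Raises ``ValueError`` with the
    1-based line number on rows with the wrong column count.
    """
    if os.path.getsize(path) == 0:
        return []
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed hit table {path}: {exc}")
    if df.shape[1] != len(HIT_COLUMNS):
        raise ValueError(
            f"{path}: expected 12 columns, found {df.shape[1]} (line 1)"
        )
    bad = df.isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise ValueError(f"{path}: wrong column count at line {line}")
    df.columns = HIT_COLUMNS
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            SimilarityHit(
                query_id=row.query_id,
                subject_id=row.subject_id,
                percent_identity=float(row.percent_identity),
                align_len=int(row.align_len),
                mismatches=int(row.mismatches),
                gap_opens=int(row.gap_opens),
                q_start=int(row.q_start),
                q_end=int(row.q_end),
                s_start=int(row.s_start),
                s_end=int(row.s_end),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
            )
        )
    return hits


def write_hit_table(hits: Iterable[SimilarityHit], path: str) -> int:
    n = 0
    with open(path, "w") as fh:
        for h in hits:
            fields = [
                h.query_id,
                h.subject_id,
                f"{h.percent_identity:.2f}",
                str(h.align_len),
                str(h.mismatches),
                str(h.gap_opens),
                str(h.q_start),
                str(h.q_end),
                str(h.s_start),
                str(h.s_end),
                f"{h.evalue:.2e}",
                f"{h.bitscore:.1f}",
            ]
            fh.write("\t".join(fields) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

class Catalog:
    """File-backed key-value store of dataset entries, addressed by catalog_id.

    The whole catalog persists as one JSON file, rewritten on every mutation.
    """

    def __init__(self, path: str):
        self.path = path
        self._entries: dict[str, CatalogEntry] = {}
        if os.path.exists(path) and os.path.getsize(path) > 0:
            with open(path) as fh:
                raw = json.load(fh)
            for cid, d in raw.items():
                self._entries[cid] = CatalogEntry(**d)

    def _flush(self) -> None:
        with open(self.path, "w") as fh:
            json.dump({cid: vars(e) for cid, e in self._entries.items()}, fh, indent=1)

    def add(self, entry: CatalogEntry, force: bool = False) -> str:
        for p in entry.data_paths:
            if not os.path.exists(p):
                raise FileNotFoundError(f"catalog entry {entry.catalog_id}: missing path {p}")
        if entry.catalog_id in self._entries and not force:
            raise ValueError(
                f"catalog_id {entry.catalog_id!r} already exists (use force to replace)"
            )
        self._entries[entry.catalog_id] = entry
        self._flush()
        return entry.catalog_id

    def get(self, catalog_id: str) -> CatalogEntry:
        if catalog_id not in self._entries:
            raise KeyError(f"unknown catalog_id {catalog_id!r}")
        return self._entries[catalog_id]

    def __contains__(self, catalog_id: str) -> bool:
        return catalog_id in self._entries

    def ids(self) -> list[str]:
        return sorted(self._entries)
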