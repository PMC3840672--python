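"""Concatenation of per-gene alignments into a partitioned supermatrix.

Rows are taxa; columns are grouped into contiguous per-gene partitions
recorded with 1-based inclusive coordinates (the convention of RAxML-style
partition files).  Missing taxon-by-gene blocks are filled with ``?``, which
is distinct from the alignment-gap character ``-`` so that absent genes and
within-gene gaps stay distinguishable; occupancy counts both as missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .refine import Alignment
from .seqio import taxon_of

MISSING = "?"
GAP = "-"


@dataclass
class Partition:
    gene_name: str
    start: int  # 1-based inclusive
    end: int
    datatype: str = "DNA"  # "DNA" | "PROT"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"partition {self.gene_name}: start > end")
        if self.datatype not in ("DNA", "PROT"):
            raise ValueError(f"partition {self.gene_name}: bad datatype {self.datatype!r}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class Supermatrix:
    taxa: list[str]
    matrix: dict[str, str]
    partitions: list[Partition]

    def __post_init__(self) -> None:
        width = self.width
        for taxon in self.taxa:
            if len(self.matrix[taxon]) != width:
                raise ValueError(f"row {taxon} has wrong length")
        prev_end = 0
        for part in self.partitions:
            if part.start != prev_end + 1:
                raise ValueError(f"partition {part.gene_name} not contiguous")
            prev_end = part.end

    @property
    def width(self) -> int:
        return self.partitions[-1].end if self.partitions else 0

    def partition_block(self, taxon: str, gene_name: str) -> str:
        for part in self.partitions:
            if part.gene_name == gene_name:
                return self.matrix[taxon][part.start - 1 : part.end]
        raise KeyError(f"no partition named {gene_name!r}")


def concatenate(
    alignments: Iterable[tuple[str, Alignment]],
    taxa: Sequence[str] | None = None,
    datatype: str = "DNA",
) -> Supermatrix:
    """Concatenate (gene_name, Alignment) pairs into a supermatrix.

    Alignment rows may be keyed by namespaced labels or plain taxon ids; at
    most one row per taxon per gene is allowed.  Genes are ordered by sorted
    gene_name for reproducibility.  Missing taxon-by-gene blocks are filled
    with ``?``.
    """
    alignments = sorted(alignments, key=lambda pair: pair[0])
    if not alignments:
        raise ValueError("no alignments to concatenate")
    per_gene: list[tuple[str, dict[str, str], int]] = []
    seen_taxa: list[str] = []
    for gene_name, aln in alignments:
        rows: dict[str, str] = {}
        for label, row in aln.rows.items():
            taxon = taxon_of(label)
            if taxon in rows:
                raise ValueError(f"gene {gene_name}: duplicate taxon {taxon}")
            rows[taxon] = row
            if taxon not in seen_taxa:
                seen_taxa.append(taxon)
        per_gene.append((gene_name, rows, aln.length))
    taxa_list = list(taxa) if taxa is not None else sorted(seen_taxa)
    matrix = {taxon: [] for taxon in taxa_list}
    partitions: list[Partition] = []
    cursor = 0
    for gene_name, rows, width in per_gene:
        for taxon in taxa_list:
            matrix[taxon].append(rows.get(taxon, MISSING * width))
        partitions.append(
            Partition(gene_name=gene_name, start=cursor + 1, end=cursor + width, datatype=datatype)
        )
        cursor += width
    return Supermatrix(
        taxa=taxa_list,
        matrix={taxon: "".join(parts) for taxon, parts in matrix.items()},
        partitions=partitions,
    )


def occupancy(sm: Supermatrix) -> tuple[dict[str, float], float]:
    """Per-taxon and overall fraction of non-missing, non-gap characters."""
    per_taxon: dict[str, float] = {}
    total_filled = 0
    width = sm.width
    for taxon in sm.taxa:
        row = sm.matrix[taxon]
        filled = sum(1 for c in row if c not in (MISSING, GAP))
        per_taxon[taxon] = filled / width if width else 0.0
        total_filled += filled
    overall = total_filled / (width * len(sm.taxa)) if width and sm.taxa else 0.0
    return per_taxon, overall


def write_supermatrix(
    sm: Supermatrix,
    fasta_path: str | None = None,
    phylip_path: str | None = None,
    partitions_path: str | None = None,
    protein_model: str | None = None,
) -> None:
    """Write FASTA / relaxed-PHYLIP matrices and a RAxML-style partitions file.

    Partition lines are ``<DATATYPE>, <gene_name> = <start>-<end>``; for
    protein matrices the datatype token can be replaced by a model name
    (e.g. ``WAG``) via ``protein_model``.
    """
    if fasta_path:
        with open(fasta_path, "w") as fh:
            for taxon in sm.taxa:
                fh.write(f">{taxon}\n{sm.matrix[taxon]}\n")
    if phylip_path:
        with open(phylip_path, "w") as fh:
            fh.write(f"{len(sm.taxa)} {sm.width}\n")
            for taxon in sm.taxa:
                fh.write(f"{taxon}  {sm.matrix[taxon]}\n")
    if partitions_path:
        with open(partitions_path, "w") as fh:
            for part in sm.partitions:
                token = part.datatype
                if part.datatype == "PROT" and protein_model:
                    token = protein_model
                fh.write(f"{token}, {part.gene_name} = {part.start}-{part.end}\n")


def read_supermatrix(fasta_path: str, partitions_path: str) -> Supermatrix:
    """Read back a supermatrix written by :func:`write_supermatrix`."""
    from Bio import SeqIO

    matrix: dict[str, str] = {}
    taxa: list[str] = []
    for record in SeqIO.parse(fasta_path, "fasta"):
        taxa.append(record.id)
        matrix[record.id] = str(record.seq)
    partitions: list[Partition] = []
    with open(partitions_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            token, rest = line.split(",", 1)
            gene_name, coords = rest.split("=")
            start, end = coords.strip().split("-")
            datatype = "DNA" if token.strip() == "DNA" else "PROT"
            partitions.append(
                Partition(
                    gene_name=gene_name.strip(),
                    start=int(start),
                    end=int(end),
                    datatype=datatype,
                )
            )
    return Supermatrix(taxa=taxa, matrix=matrix, partitions=partitions)
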