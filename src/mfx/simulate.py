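"""Seeded synthetic-data generator: gene families with known orthology,
paired reads with injected defects, similarity hit tables derived from true
identity, and gene trees with planted duplications.

The generator defines the study conditions every stage is tested under.
Sequence evolution is deliberately simple — i.i.d. substitutions along a
random species tree, uniform over the three alternative bases, no indels —
so that family members remain columnwise homologous by construction and
alignment correctness is trivially checkable.  Read defects (adapter,
composition skew, low quality, rRNA origin) are constructed to be
unambiguously detectable, so a defect manifest can be compared exactly
against sanitizer output.  Everything is a pure function of the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .sanitize import default_adapters
from .seqio import GeneSequence, ReadPair, SimilarityHit, read_fasta, reverse_complement
from .treeprune import GeneTree, parse_newick

BASES = "ACGT"


@dataclass
class SimConfig:
    n_taxa: int = 5
    n_single_copy: int = 50
    n_duplicated: int = 10
    #: sequences with no homolog anywhere (assembly noise / lineage-specific
    #: genes); they exercise the homology-graph drop seen on real data
    n_orphans: int = 40
    seq_len_range: tuple[int, int] = (300, 900)
    #: substitution probability per site per tree branch
    substitution_rate: float = 0.02
    read_len: int = 100
    n_read_pairs: int = 25000
    insert_mean: float = 266.0
    insert_sd: float = 30.0
    frac_rrna: float = 0.20
    frac_adapter: float = 0.05
    frac_skewed: float = 0.03
    frac_lowq: float = 0.02
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        fracs = self.frac_rrna + self.frac_adapter + self.frac_skewed + self.frac_lowq
        if fracs > 1:
            raise ValueError("defect fractions sum above 1")
        if self.insert_mean < self.read_len:
            raise ValueError("insert_mean must be >= read_len")

    @property
    def taxa(self) -> list[str]:
        return [f"t{i + 1}" for i in range(self.n_taxa)]


def paper_test_preset(seed: int = 42) -> SimConfig:
    """Scale echoing the bundled test-set role: 5 taxa, ~70 genes each,
    25,000 100-bp read pairs."""
    return SimConfig(n_taxa=5, n_single_copy=50, n_duplicated=10, seed=seed)


def synthetic_rrna_reference() -> list[GeneSequence]:
    """The bundled synthetic rRNA reference panel (seeded random sequences
    standing in the role of a curated rRNA set)."""
    path = resources.files("mfx.data") / "rrna_synthetic.fa"
    return read_fasta(str(path), taxon_id="")


# ---------------------------------------------------------------------------
# gene families
# ---------------------------------------------------------------------------

def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(length))


def _evolve(seq: str, rate: float, rng: random.Random) -> str:
    """One branch of evolution: each site substitutes with probability ``rate``
    to one of the three alternative bases."""
    if rate <= 0:
        return seq
    out = list(seq)
    for i, base in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in BASES if b != base])
    return "".join(out)


def _random_join_topology(items: list, rng: random.Random) -> object:
    """Random binary topology over items, as nested 2-tuples."""
    pool = list(items)
    while len(pool) > 1:
        i = rng.randrange(len(pool))
        a = pool.pop(i)
        j = rng.randrange(len(pool))
        b = pool.pop(j)
        pool.append((a, b))
    return pool[0]


def _evolve_along(topology, root_seq: str, rate: float, rng: random.Random) -> dict[str, str]:
    """Evolve a root sequence down a nested-tuple topology; leaves are taxon ids."""
    out: dict[str, str] = {}

    def walk(node, seq):
        seq = _evolve(seq, rate, rng)
        if isinstance(node, tuple):
            for child in node:
                walk(child, seq)
        else:
            out[node] = seq

    walk(topology, root_seq)
    return out


def simulate_gene_families(cfg: SimConfig) -> tuple[list[GeneSequence], pd.DataFrame]:
    """Simulate single-copy and duplicated gene families over a random species tree.

    Returns the sequences (taxon-annotated) and a truth table with one row per
    sequence: label, taxon, family, copy.  Single-copy families have exactly
    one sequence per taxon; duplicated families plant one duplication, with a
    second paralog copy present in a random taxon subset.  Deterministic
    given ``cfg.seed``.
    """
    rng = random.Random(cfg.seed)
    species_tree = _random_join_topology(cfg.taxa, rng)
    sequences: list[GeneSequence] = []
    truth_rows: list[dict] = []

    def emit(family: str, copy: str, taxon: str, seq: str) -> None:
        seq_id = f"{family}{'' if copy == 'a' else '_' + copy}_{taxon}"
        gs = GeneSequence(
            seq_id=seq_id,
            taxon_id=taxon,
            gene_id=family,
            sequence=seq,
            annotations={"expression": round(rng.uniform(1.0, 100.0), 2)},
        )
        sequences.append(gs)
        truth_rows.append(
            {"label": gs.label, "taxon": taxon, "family": family, "copy": copy}
        )

    n_total = cfg.n_single_copy + cfg.n_duplicated
    for fam_idx in range(n_total):
        family = f"fam{fam_idx + 1:03d}"
        length = rng.randint(*cfg.seq_len_range)
        root = _random_seq(rng, length)
        if fam_idx < cfg.n_single_copy:
            for taxon, seq in _evolve_along(species_tree, root, cfg.substitution_rate, rng).items():
                emit(family, "a", taxon, seq)
        else:
            # duplication on the root branch: two diverged ancestors, copy b
            # retained only in a random subset of taxa
            anc_a = _evolve(root, cfg.substitution_rate, rng)
            anc_b = _evolve(root, cfg.substitution_rate, rng)
            subset = set(rng.sample(cfg.taxa, rng.randint(2, cfg.n_taxa)))
            for taxon, seq in _evolve_along(species_tree, anc_a, cfg.substitution_rate, rng).items():
                emit(family, "a", taxon, seq)
            for taxon, seq in _evolve_along(species_tree, anc_b, cfg.substitution_rate, rng).items():
                if taxon in subset:
                    emit(family, "b", taxon, seq)
    for orphan_idx in range(cfg.n_orphans):
        family = f"orphan{orphan_idx + 1:03d}"
        taxon = cfg.taxa[orphan_idx % cfg.n_taxa]
        emit(family, "a", taxon, _random_seq(rng, rng.randint(*cfg.seq_len_range)))
    truth = pd.DataFrame(truth_rows)
    return sequences, truth


# ---------------------------------------------------------------------------
# similarity hits from true identity
# ---------------------------------------------------------------------------

def simulate_hit_table(
    sequences: list[GeneSequence],
    min_identity: float = 0.70,
    min_len: int = 50,
) -> list[SimilarityHit]:
    """Emit a 12-column-style hit for every sequence pair whose positional
    identity over the shared prefix reaches ``min_identity``.

    This bypasses an external all-by-all search: the simulator's families are
    indel-free, so positional identity over the shared prefix is the true
    alignment identity.
    """
    encoded = [
        np.frombuffer(s.sequence.encode(), dtype=np.uint8) for s in sequences
    ]
    hits: list[SimilarityHit] = []
    for i in range(len(sequences)):
        for j in range(i + 1, len(sequences)):
            L = min(encoded[i].size, encoded[j].size)
            if L < min_len:
                continue
            matches = int((encoded[i][:L] == encoded[j][:L]).sum())
            ident = matches / L
            if ident < min_identity:
                continue
            bitscore = round(2.0 * ident * L, 1)
            # an all-by-all search reports both directions of every pair
            for qi, si in ((i, j), (j, i)):
                hits.append(
                    SimilarityHit(
                        query_id=sequences[qi].label,
                        subject_id=sequences[si].label,
                        percent_identity=round(100.0 * ident, 2),
                        align_len=L,
                        mismatches=L - matches,
                        gap_opens=0,
                        q_start=1,
                        q_end=L,
                        s_start=1,
                        s_end=L,
                        evalue=1e-50,
                        bitscore=bitscore,
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# gene trees with planted duplications
# ---------------------------------------------------------------------------

def simulate_gene_trees(
    groups: list[tuple[str, list[str]]],
    truth: pd.DataFrame,
    seed: int = 0,
) -> list[GeneTree]:
    """Generate a gene tree per (tree_id, member labels) group.

    The topology groups paralog copies (per the truth table) into separate
    clades joined at the base — the signature a duplication leaves in a real
    gene tree — with random topology within each copy clade.  Internal nodes
    carry bootstrap-style supports in [85, 100].
    """
    rng = random.Random(seed)
    copy_of = dict(zip(truth["label"], truth["family"] + "/" + truth["copy"]))
    trees: list[GeneTree] = []
    for tree_id, labels in groups:
        by_copy: dict[str, list[str]] = {}
        for label in sorted(labels):
            by_copy.setdefault(copy_of.get(label, "?"), []).append(label)

        def subtree(items: list[str]) -> str:
            topo = _random_join_topology(items, rng)

            def render(node) -> str:
                if isinstance(node, tuple):
                    kids = ",".join(f"{render(c)}:0.1" for c in node)
                    return f"({kids}){rng.randint(85, 100)}"
                return node

            text = render(topo)
            return text

        clades = [subtree(members) for _, members in sorted(by_copy.items())]
        topo = _random_join_topology(clades, rng)

        def render_top(node) -> str:
            if isinstance(node, tuple):
                kids = ",".join(f"{render_top(c)}:0.1" for c in node)
                return f"({kids}){rng.randint(85, 100)}"
            return node

        body = render_top(topo)
        if not body.startswith("("):
            body = f"({body}:0.1)"
        trees.append(parse_newick(body + ";", tree_id=tree_id))
    return trees


# ---------------------------------------------------------------------------
# paired reads with injected defects
# ---------------------------------------------------------------------------

def simulate_reads(
    transcripts: list[GeneSequence],
    cfg: SimConfig,
) -> tuple[list[ReadPair], dict[str, str]]:
    """Simulate paired reads from transcripts, injecting unambiguous defects.

    Fragments are drawn with a normal insert length (truncated to
    [read_len, transcript length]); mates are the fragment's two ends, the
    reverse mate reverse-complemented.  Defect pairs are injected at the
    configured fractions: an adapter embedded verbatim in the forward mate,
    composition forced to a homopolymer, qualities drawn far below the mean-
    quality threshold, or both mates drawn from the bundled synthetic rRNA
    reference.  Returns the pairs (in seeded random order) and a manifest
    mapping pair id to its ground-truth class in
    {clean, adapter, composition, quality, rrna}.
    """
    if not transcripts:
        raise ValueError("no transcripts to simulate reads from")
    rng = random.Random(cfg.seed + 1)
    usable = [t for t in transcripts if len(t.sequence) >= cfg.read_len]
    if not usable:
        raise ValueError("no transcript is at least read_len long")
    rrna_refs = synthetic_rrna_reference()
    adapter = default_adapters()[0]
    n = cfg.n_read_pairs
    n_rrna = round(cfg.frac_rrna * n)
    n_adapter = round(cfg.frac_adapter * n)
    n_skewed = round(cfg.frac_skewed * n)
    n_lowq = round(cfg.frac_lowq * n)
    classes = (
        ["rrna"] * n_rrna
        + ["adapter"] * n_adapter
        + ["composition"] * n_skewed
        + ["quality"] * n_lowq
    )
    classes += ["clean"] * (n - len(classes))
    rng.shuffle(classes)

    def fragment_from(seq: str) -> str:
        max_insert = len(seq)
        insert = int(round(rng.gauss(cfg.insert_mean, cfg.insert_sd)))
        insert = max(cfg.read_len, min(insert, max_insert))
        pos = rng.randint(0, len(seq) - insert)
        return seq[pos : pos + insert]

    def clean_quals() -> list[int]:
        return [rng.randint(30, 40) for _ in range(cfg.read_len)]

    pairs: list[ReadPair] = []
    manifest: dict[str, str] = {}
    for idx, cls in enumerate(classes):
        pid = f"pair{idx + 1:06d}"
        if cls == "rrna":
            src = rng.choice(rrna_refs).sequence
        else:
            src = rng.choice(usable).sequence
        frag = fragment_from(src)
        fwd = frag[: cfg.read_len]
        rev = reverse_complement(frag)[: cfg.read_len]
        fwd_q, rev_q = clean_quals(), clean_quals()
        if cls == "adapter":
            # embed the adapter verbatim mid-read; surrounding transcript
            # sequence keeps composition balanced and quality high
            at = rng.randint(0, cfg.read_len - len(adapter))
            fwd = fwd[:at] + adapter + fwd[at + len(adapter) :]
        elif cls == "composition":
            fwd = rng.choice(BASES) * cfg.read_len
        elif cls == "quality":
            fwd_q = [rng.randint(5, 20) for _ in range(cfg.read_len)]
        pairs.append(ReadPair(id=pid, fwd_seq=fwd, rev_seq=rev, fwd_qual=fwd_q, rev_qual=rev_q))
        manifest[pid] = cls
    return pairs, manifest


def write_manifest(manifest: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for pid in sorted(manifest):
            fh.write(f"{pid}\t{manifest[pid]}\n")


# ---------------------------------------------------------------------------
# template-length SAM for insert-size estimation
# ---------------------------------------------------------------------------

def simulate_template_lengths(
    n: int, mean: float = 266.0, sd: float = 30.0, seed: int = 0
) -> list[int]:
    """Truncated-normal template lengths (>= 1), seeded."""
    rng = random.Random(seed)
    return [max(1, int(round(rng.gauss(mean, sd)))) for _ in range(n)]


def write_template_sam(template_lengths: list[int], path: str, ref_len: int = 100000) -> None:
    """Write a minimal SAM carrying one properly paired record pair per
    template length (TLEN +L on the forward mate, -L on the reverse)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:ref1\tLN:{ref_len}\n")
        for i, tlen in enumerate(template_lengths):
            pos = 1 + (i % max(1, ref_len - tlen - 200))
            mate_pos = pos + max(0, tlen - 100)
            fh.write(
                f"pair{i}\t99\tref1\t{pos}\t60\t100M\t=\t{mate_pos}\t{tlen}\t*\t*\n"
            )
            fh.write(
                f"pair{i}\t147\tref1\t{mate_pos}\t60\t100M\t=\t{pos}\t{-tlen}\t*\t*\n"
            )
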