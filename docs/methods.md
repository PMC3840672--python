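# Methods

`mfx` builds phylogenomic supermatrices from transcriptome-derived gene
sequences. This note documents the models and procedures it implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Pipeline overview

The matrix-construction funnel runs:

1. **catalog** — datasets (paired FASTQ or assembled FASTA) are registered
   with metadata and content paths in a file-backed catalog.
2. **sanitize** — paired reads are filtered by mean quality, adapter
   content, and base-composition skew, then order-randomized (pairing
   preserved) so later prefix subsets are unbiased samples.
3. **screen** — rRNA/vector detection on reads and transcripts, insert-size
   estimation, longest-ORF annotation, exemplar isoform selection.
4. **homologize** — an all-by-all similarity hit table (produced externally,
   e.g. by tblastx) becomes a weighted graph; Markov Clustering cuts it into
   putative gene families.
5. **multalign** — sampling/length filters, hit-span end trimming, external
   multiple alignment, simplified gap-block cleaning.
6. **treeprune** — gene trees (inferred externally, e.g. by RAxML) are
   decomposed into maximally inclusive subtrees with at most one sequence
   per taxon; each is a putative ortholog set.
7. **supermatrix** — ortholog alignments are concatenated into a partitioned
   matrix with occupancy diagnostics.

Sequence identifiers are namespaced `taxon@seq_id` internally; `@` is
reserved. Internal coordinates are 0-based half-open; the hit-table and
partition-file formats keep their native 1-based inclusive conventions,
converted at the I/O boundary.

## Read sanitization

A pair is discarded whole (never trimmed) when either mate fails a test;
the recorded reason is the first failure in the fixed order quality →
adapter → composition.

- `mean_quality_min` (Phred, default 28): mean per-mate quality floor. A
  second, stricter value (`assemble_quality_min`, default 33) is carried in
  the config for pre-assembly filtering. Both are conventions — reasonable
  strict defaults, fully exposed.
- Adapter test: exact substring match of any configured adapter (optionally
  only its first *k* bases). The bundled default set holds the two standard
  TruSeq read-through adapters.
- Composition test: any of A, C, G, T below 5% or above 60% of non-N bases
  (strict inequalities). All-N mates are degenerate and treated as skewed.
  Each mate is tested independently and the pair discarded on any failure.
- Randomization is a seeded Fisher–Yates shuffle of the surviving pairs; the
  seed is recorded in the stats for provenance.

## Screening by k-mer containment

Read mapping and blastn screens are replaced by a canonical k-mer
containment matcher: a sequence is classified as derived from the reference
when at least `min_shared_fraction` (default 0.5) of its k-mers (default
k=25, strand-canonical, N-containing k-mers skipped) occur in the reference
k-mer set. The matcher fills the same decision role deterministically with
no external binaries and sits behind a small interface, so a mapping-based
screener can be substituted without touching callers. Transcripts are only
flagged (`is_rrna`, `is_vector`), never deleted, at this stage; reads are
partitioned into retained/removed and the removed fraction reported.

The bundled rRNA panel (`data/rrna_synthetic.fa`) is **synthetic** — seeded
random sequences standing in the structural role of a curated rRNA
reference. Any real reference FASTA can be supplied instead.

## Insert size

Mean and unbiased sample variance of template lengths (variance 0 at n=1).
When read from SAM, the absolute value of every non-zero template-length
field is one observation, so both mates of a proper pair contribute; the
mean is unaffected and n doubles.

## Longest ORF

An ORF is stop-to-stop: a maximal run of codons free of TAA/TAG/TGA in one
of the six reading frames, with **no start-codon requirement**, because
transcriptome fragments frequently truncate 5′ ends. Partial terminal
codons are ignored (each frame scans ⌊L/3⌋ codons). The longest run in
nucleotides wins; ties break by frame order +1, +2, +3, −1, −2, −3, then by
smaller forward-strand start. Coordinates are always reported on the
forward strand, 0-based half-open. "Likely coding" is judged by length
alone; protein-database support is out of scope.

## Exemplar selection

Per gene (isoform group): flagged transcripts are excluded, then the
highest-expression isoform wins; ties go to the longest sequence, then the
lexicographically smallest seq_id. Expression values are consumed from an
external quantifier (missing → 0); their units are whatever that tool
produced. Genes whose isoforms are all flagged are dropped and logged.

## Homology graph and MCL

An edge joins two sequences when at least one directional hit passes
`evalue <= 1e-20` **and** `align_len >= 50` (both exposed); the weight is
the maximum bitscore over passing hits in either direction. Bitscore was
chosen over −log e-value because it is database-size independent.

Clustering is a from-scratch dense-matrix MCL:

- self-loops at the maximum incident edge weight (1.0 on isolated nodes), a
  standard regularization that prevents immediate attractor loss;
- column-normalize; iterate expansion (matrix power, default 2) then
  inflation (elementwise power, default 2.0, renormalized) with pruning of
  entries below 1e-5, until the maximum entry change falls below 1e-6 or
  100 iterations pass (non-convergence returns the current clustering with
  a warning);
- clusters are read off attractors (positive diagonal); a node supported by
  several attractors follows the lexicographically smallest one, and
  attractor systems collapse onto their smallest member, so every node lands
  in exactly one cluster.

Each connected component is iterated independently — exact, since flow never
crosses components — keeping the dense matrices small. Plain connected
components are also available as an alternative clustering mode
(`--mode components`), since they bound every MCL clustering from above.

## Cluster refinement

- Filters: members shorter than 60 nt are removed first; clusters with
  fewer than 4 distinct taxa or more than 100 members are dropped. The
  filter *kinds* are fixed; the values are conventions, all CLI-exposed.
- End trimming: per member, the union of its query-side hit spans against
  other cluster members defines an envelope [min start, max end]; the
  sequence is cut to that envelope (interior coverage gaps kept — only ends
  are trimmed). Members with no intra-cluster hits are removed, as
  unsupported sequence may be chimeric. ORF coordinates are shifted.
- Alignment is an external interface: clusters go out as unaligned FASTA
  and come back aligned. The built-in `pad_align` (pad to max length) is
  valid only where members are columnwise homologous, as the simulator's
  indel-free families are; real data should use a translation-aware aligner.
- Cleaning is an explicitly simplified gap-block filter (not a GBLOCKS
  reimplementation): columns with gap fraction > 0.5 are removed, then
  surviving runs shorter than 10 columns are removed. Externally cleaned
  alignments can bypass it.
- Translation uses the standard code; `---` → `-`, partially gapped codons
  → `X`, stop codons → `X` (internal stops additionally warn, since they
  usually indicate a frame problem).

## Gene-tree ortholog decomposition

Trees are treated as unrooted (ML gene trees are), so candidate subtrees
are the two leaf-sets induced by deleting each branch, plus the whole leaf
set. Greedy extraction repeats: among candidates with at most one sequence
per taxon, take the one with the most leaves (ties → most distinct taxa →
lexicographically smallest sorted label list); emit it, delete its leaves,
suppress the degree-2 nodes this creates, and continue over the residual
forest until no leaves remain. Output sets are disjoint, cover every leaf,
and are each taxon-unique; extraction order (rank) is deterministic. The
tie-break order is this package's convention. Singleton sets are emitted —
downstream taxon-sampling filters drop them; the decomposition itself does
not filter.

Support filtering averages bootstrap values over the internal nodes that
carry them; a tree with no support values anywhere is an error (and the
batch filter excludes such trees with a warning rather than keeping them
silently).

## Supermatrix

Genes are concatenated in sorted gene-name order (reproducibility; no
natural order exists). Missing taxon-by-gene blocks are filled with `?`,
distinct from the alignment gap `-`; occupancy counts both as missing.
Partition coordinates are 1-based inclusive, written as
`DNA, gene = start-end` (a protein model token such as `WAG` can replace
the datatype for protein matrices). FASTA and relaxed PHYLIP writers plus a
reader give a round-trip identity.

## Synthetic data generator

The generator emulates, at desk scale, the structure the pipeline exists to
exploit:

- **Gene families**: a random species tree over `n_taxa=5` taxa; 50
  single-copy families (one sequence per taxon) and 10 duplicated families
  (one planted duplication; the second paralog copy retained in a random
  taxon subset of ≥ 2), root lengths uniform in 300–900 nt, i.i.d.
  substitutions at 0.02 per site per branch, uniform over the three
  alternative bases, **no indels** — so family members stay columnwise
  homologous and alignment correctness is trivially checkable. 40 orphan
  sequences with no homologs anywhere exercise the drop at the homology
  step that dominates on real data. A truth table maps every sequence to
  (family, copy).
- **Hit tables** are derived from true positional identity (a hit per
  ordered pair at ≥ 70% identity over the shared prefix), bypassing an
  external search; both directions are emitted, as an all-by-all search
  would.
- **Gene trees** are generated directly from the truth (copies form
  separate clades, supports 85–100), independent of any inference tool.
- **Reads**: 25,000 pairs of 100 bp by default, normal insert (mean 266 bp,
  sd 30, truncated to [read length, transcript length]), reverse mate
  reverse-complemented. Defects are injected at fixed fractions — adapter
  5% (embedded verbatim), composition 3% (homopolymer), quality 2%
  (qualities 5–20), rRNA 20% (fragments of the bundled synthetic panel,
  inside the wide per-library range seen in practice) — each constructed to
  be unambiguously detectable, so the sanitizer's discard counts can be
  compared exactly to the manifest.

What it does **not** emulate: indel evolution, position-dependent quality
profiles, sequencing error, isoform structure beyond duplicate full-length
copies, rate heterogeneity, compositional bias. Consequently, passing tests
demonstrate algorithmic correctness of each stage and of their composition
— not robustness to alignment ambiguity, assembly artifacts, or model
violations on real libraries.

## Verification scale

Oracle-equivalence checks run at sizes chosen to keep the default suite
fast while remaining genuinely exhaustive where that is feasible: the
ortholog-decomposition oracle enumerates **every** unrooted topology ×
every 4-taxon leaf labeling for 2–5 leaves (16k+ trees) and adds seeded
random draws at 6–8 leaves; MCL is compared to an independently coded dense
iteration on 200 seeded random graphs of ≤ 8 nodes; the ORF finder is
compared to a brute-force 6-frame scan on 1,000 random 300-mers; the
end-to-end run uses the full default preset.

## Known limitations

- MCL cluster read-out resolves overlapping attractor support
  lexicographically; pathological near-symmetric graphs could in principle
  read out differently from other MCL implementations (the iteration itself
  is canonical).
- The gap-block cleaner is intentionally simpler than GBLOCKS; its defaults
  are not tuned to any empirical benchmark.
- `pad_align` must not be used on real (indel-containing) data.
- The k-mer screen trades sensitivity for determinism relative to a mapper:
  highly diverged rRNA below ~50% k-mer containment would be missed.
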