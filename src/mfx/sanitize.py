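"""Paired-read sanitization: quality, adapter, and base-composition filters.

Reads are discarded whole (never trimmed) if either mate fails any test, and
surviving pairs are emitted in a seeded pseudo-random order with mates kept
together — randomization makes downstream prefix subsetting unbiased.

A pair is discarded when

* either mate's mean Phred quality falls below ``mean_quality_min``, or
* either mate contains a configured adapter sequence verbatim, or
* either mate's base composition is skewed: any of A, C, G, T makes up
  strictly less than ``comp_low`` or strictly more than ``comp_high`` of the
  non-N bases (defaults 5% and 60%).

The discard reason recorded is the first failing test in the fixed order
quality -> adapter -> composition.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from .seqio import ReadPair, read_fasta


def default_adapters() -> tuple[str, ...]:
    """Adapter sequences bundled with the package (standard TruSeq read-through)."""
    path = resources.files("mfx.data") / "adapters.fa"
    return tuple(s.sequence for s in read_fasta(str(path)))


@dataclass
class SanitizeConfig:
    mean_quality_min: float = 28.0
    #: stricter threshold intended for pre-assembly filtering
    assemble_quality_min: float = 33.0
    comp_low: float = 0.05
    comp_high: float = 0.60
    adapters: tuple[str, ...] = ()
    #: match only the first k bases of each adapter; None = full adapter
    adapter_prefix_len: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.comp_low < self.comp_high <= 1:
            raise ValueError("require 0 <= comp_low < comp_high <= 1")
        if self.mean_quality_min < 0:
            raise ValueError("mean_quality_min must be >= 0")
        if not self.adapters:
            self.adapters = default_adapters()

    @property
    def adapter_probes(self) -> tuple[str, ...]:
        k = self.adapter_prefix_len
        return tuple(a[:k] if k else a for a in self.adapters)


@dataclass
class SanitizeStats:
    n_input_pairs: int = 0
    n_kept_pairs: int = 0
    discards: dict[str, int] = field(
        default_factory=lambda: {"quality": 0, "adapter": 0, "composition": 0}
    )
    seed: int = 0

    def check(self) -> None:
        if self.n_input_pairs != self.n_kept_pairs + sum(self.discards.values()):
            raise AssertionError("sanitize stats do not conserve pair counts")


def base_composition_skewed(sequence: str, comp_low: float = 0.05, comp_high: float = 0.60) -> bool:
    """True iff any of A,C,G,T has frequency < comp_low or > comp_high among non-N bases.

    An all-N (or empty-after-N-exclusion) sequence is degenerate and treated
    as skewed.
    """
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return True
    for b in "ACGT":
        freq = counts[b] / denom
        if freq < comp_low or freq > comp_high:
            return True
    return False


def _mean_quality(qual: list[int]) -> float:
    return sum(qual) / len(qual) if qual else 0.0


def filter_read_pair(pair: ReadPair, cfg: SanitizeConfig) -> tuple[bool, str | None]:
    """Return (keep, reason); reason is the first failing test or None."""
    if (
        _mean_quality(pair.fwd_qual) < cfg.mean_quality_min
        or _mean_quality(pair.rev_qual) < cfg.mean_quality_min
    ):
        return False, "quality"
    for probe in cfg.adapter_probes:
        if probe and (probe in pair.fwd_seq or probe in pair.rev_seq):
            return False, "adapter"
    if base_composition_skewed(pair.fwd_seq, cfg.comp_low, cfg.comp_high) or (
        base_composition_skewed(pair.rev_seq, cfg.comp_low, cfg.comp_high)
    ):
        return False, "composition"
    return True, None


def sanitize_stream(
    pairs: Iterable[ReadPair], cfg: SanitizeConfig
) -> tuple[list[ReadPair], SanitizeStats]:
    """Filter a finite stream of pairs and shuffle the survivors.

    The output permutation is a pure function of (input order, cfg.seed);
    mates are never separated.
    """
    stats = SanitizeStats(seed=cfg.seed)
    kept: list[ReadPair] = []
    for pair in pairs:
        stats.n_input_pairs += 1
        keep, reason = filter_read_pair(pair, cfg)
        if keep:
            kept.append(pair)
        else:
            stats.discards[reason] += 1
    stats.n_kept_pairs = len(kept)
    stats.check()
    random.Random(cfg.seed).shuffle(kept)
    return kept, stats
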