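import numpy as np
import pytest

from mfx.sanitize import SanitizeConfig, sanitize_stream
from mfx.simulate import (
    SimConfig,
    paper_test_preset,
    simulate_gene_families,
    simulate_gene_trees,
    simulate_hit_table,
    simulate_reads,
    simulate_template_lengths,
    synthetic_rrna_reference,
    write_template_sam,
)
from mfx.screen import estimate_insert_size, template_lengths_from_sam
from mfx.treeprune import mean_support, prune_orthologs


def small_cfg(**kw):
    kw.setdefault("n_taxa", 4)
    kw.setdefault("n_single_copy", 6)
    kw.setdefault("n_duplicated", 2)
    kw.setdefault("n_orphans", 3)
    kw.setdefault("n_read_pairs", 200)
    kw.setdefault("seed", 7)
    return SimConfig(**kw)


class TestGeneFamilies:
    def test_deterministic_given_seed(self):
        s1, t1 = simulate_gene_families(small_cfg())
        s2, t2 = simulate_gene_families(small_cfg())
        assert [(x.label, x.sequence) for x in s1] == [(x.label, x.sequence) for x in s2]
        assert t1.equals(t2)

    def test_single_copy_truth_one_per_taxon(self):
        cfg = small_cfg()
        _, truth = simulate_gene_families(cfg)
        fam = truth[truth.family == "fam001"]
        assert sorted(fam.taxon) == cfg.taxa
        assert set(fam["copy"]) == {"a"}

    def test_zero_rate_identical_members(self):
        cfg = small_cfg(substitution_rate=0.0)
        seqs, truth = simulate_gene_families(cfg)
        by_label = {s.label: s.sequence for s in seqs}
        fam = truth[truth.family == "fam001"]
        assert len({by_label[l] for l in fam.label}) == 1

    def test_truth_covers_every_sequence_once(self):
        seqs, truth = simulate_gene_families(small_cfg())
        assert sorted(truth.label) == sorted(s.label for s in seqs)
        assert truth.label.is_unique

    def test_duplicated_families_have_two_copies(self):
        _, truth = simulate_gene_families(small_cfg())
        dup = truth[truth.family == "fam007"]  # first duplicated family
        assert set(dup["copy"]) == {"a", "b"}


class TestHitTable:
    def test_family_members_hit_each_other(self):
        seqs, truth = simulate_gene_families(small_cfg())
        hits = simulate_hit_table(seqs)
        fam = set(truth[truth.family == "fam001"].label)
        seen = {
            frozenset((h.query_id, h.subject_id))
            for h in hits
            if h.query_id in fam and h.subject_id in fam
        }
        assert len(seen) == len(fam) * (len(fam) - 1) // 2

    def test_no_cross_family_hits(self):
        seqs, truth = simulate_gene_families(small_cfg())
        family_of = dict(zip(truth.label, truth.family))
        hits = simulate_hit_table(seqs)
        assert all(family_of[h.query_id] == family_of[h.subject_id] for h in hits)

    def test_both_directions_emitted(self):
        seqs, _ = simulate_gene_families(small_cfg())
        hits = simulate_hit_table(seqs)
        directed = {(h.query_id, h.subject_id) for h in hits}
        assert all((b, a) in directed for a, b in directed)


class TestGeneTrees:
    def test_supports_present_and_high(self):
        seqs, truth = simulate_gene_families(small_cfg())
        labels = list(truth[truth.family == "fam001"].label)
        (tree,) = simulate_gene_trees([("g1", labels)], truth, seed=3)
        assert mean_support(tree) >= 85.0
        assert sorted(tree.leaf_labels) == sorted(labels)

    def test_duplication_is_prunable(self):
        seqs, truth = simulate_gene_families(small_cfg())
        dup_fam = truth[truth.family == "fam007"]
        (tree,) = simulate_gene_trees([("g", list(dup_fam.label))], truth, seed=3)
        sets = prune_orthologs(tree)
        copies = {frozenset(dup_fam[dup_fam["copy"] == c].label) for c in ("a", "b")}
        assert {s.leaf_labels for s in sets} == copies


class TestReads:
    def test_exact_pair_count(self):
        cfg = small_cfg()
        seqs, _ = simulate_gene_families(cfg)
        pairs, manifest = simulate_reads(seqs, cfg)
        assert len(pairs) == cfg.n_read_pairs == len(manifest)

    def test_manifest_counts_match_fractions(self):
        cfg = small_cfg(n_read_pairs=1000)
        seqs, _ = simulate_gene_families(cfg)
        _, manifest = simulate_reads(seqs, cfg)
        counts = {}
        for cls in manifest.values():
            counts[cls] = counts.get(cls, 0) + 1
        assert counts["rrna"] == round(cfg.frac_rrna * 1000)
        assert counts["adapter"] == round(cfg.frac_adapter * 1000)
        assert counts["composition"] == round(cfg.frac_skewed * 1000)
        assert counts["quality"] == round(cfg.frac_lowq * 1000)

    def test_sanitize_reproduces_manifest_partition(self):
        # cross-module check: the sanitizer's discard reasons equal the
        # generator's ground-truth defect classes exactly
        cfg = small_cfg(n_read_pairs=1000)
        seqs, _ = simulate_gene_families(cfg)
        pairs, manifest = simulate_reads(seqs, cfg)
        kept, stats = sanitize_stream(pairs, SanitizeConfig(seed=cfg.seed))
        truth_counts = {}
        for cls in manifest.values():
            truth_counts[cls] = truth_counts.get(cls, 0) + 1
        assert stats.discards == {
            "quality": truth_counts["quality"],
            "adapter": truth_counts["adapter"],
            "composition": truth_counts["composition"],
        }
        assert {p.id for p in kept} == {
            pid for pid, cls in manifest.items() if cls in ("clean", "rrna")
        }

    def test_insert_mean_below_read_len_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(insert_mean=50.0)


class TestTemplateSam:
    def test_roundtrip_through_sam(self, tmp_path):
        lengths = simulate_template_lengths(50, mean=266, sd=30, seed=4)
        path = str(tmp_path / "t.sam")
        write_template_sam(lengths, path)
        back = template_lengths_from_sam(path)
        # each template contributes |TLEN| once per mate
        assert sorted(back) == sorted(lengths + lengths)
        est = estimate_insert_size(back)
        assert est.mean == pytest.approx(np.mean(lengths))


class TestPreset:
    def test_preset_scale(self):
        cfg = paper_test_preset()
        assert cfg.n_taxa == 5
        assert cfg.read_len == 100
        assert cfg.n_read_pairs == 25000
        assert cfg.insert_mean == 266.0

    def test_rrna_reference_is_nonempty(self):
        refs = synthetic_rrna_reference()
        assert refs and all(len(r.sequence) >= 100 for r in refs)
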