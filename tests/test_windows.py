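"""Repeat filtering, window aggregation, genome features, size classes."""

import numpy as np
import pandas as pd
import pytest

import teindel as td
from teindel.indels import IndelEvent, call_indels
from teindel.io import Gene, GenomeAnnotation
from teindel.windows import FilterConfig


def _aln(copy_id, chrom, start, length, subfam="fam", repeat_class="LINE/CR1"):
    seq = "A" * length
    return td.RepeatAlignment(
        copy_id, subfam, chrom, start, start + length, "+", seq, seq, 0,
        repeat_class=repeat_class,
    )


def _event(kind, length, copy_id, pos=10, subfam="fam"):
    return IndelEvent(
        kind=kind, length=length, master_pos=pos, copy_id=copy_id,
        subfamily=subfam, inserted_seq="A" * length if kind == "insertion" else "",
    )


@pytest.fixture
def annotation():
    gene = Gene("g1", "chr1", 1000, 2000, "+", [(1000, 1200), (1800, 2000)])
    return GenomeAnnotation([gene], chrom_sizes={"chr1": 10_000, "chrUn_x": 10_000})


class TestFilterRepeats:
    def test_intronic_repeat_kept(self, annotation):
        kept = td.filter_repeats([_aln("a", "chr1", 1300, 200)], annotation)
        assert len(kept) == 1

    def test_one_bp_exon_overlap_dropped(self, annotation):
        # exon ends at 1200 (half-open): repeat [1199, 1399) overlaps by 1 bp
        kept = td.filter_repeats([_aln("a", "chr1", 1199, 200)], annotation)
        assert kept == []

    def test_repeat_touching_exon_boundary_kept(self, annotation):
        kept = td.filter_repeats([_aln("a", "chr1", 1200, 200)], annotation)
        assert len(kept) == 1

    def test_unassigned_contig_dropped(self, annotation):
        kept = td.filter_repeats([_aln("a", "chrUn_x", 5000, 100)], annotation)
        assert kept == []

    def test_non_line_class_dropped(self, annotation):
        alns = [
            _aln("a", "chr1", 3000, 100, repeat_class="SINE/MIR"),
            _aln("b", "chr1", 4000, 100, repeat_class="LTR/ERV"),
            _aln("c", "chr1", 5000, 100, repeat_class="LINE/L1"),
        ]
        kept = td.filter_repeats(alns, annotation)
        assert [a.copy_id for a in kept] == ["c"]

    def test_custom_unassigned_pattern(self, annotation):
        cfg = FilterConfig(unassigned_pattern=r"^scaffold")
        kept = td.filter_repeats([_aln("a", "scaffold_12", 0, 50)], annotation, cfg)
        assert kept == []


class TestWindowRates:
    def test_window_arithmetic(self):
        alns = [_aln("a", "chr1", 0, 1000)]
        events = [
            _event("deletion", 20, "a"),
            _event("insertion", 10, "a", pos=40),
        ]
        w = td.window_rates(alns, events, window_size=1_000_000)
        row = w.iloc[0]
        assert row["repeat_bp"] == 1000
        assert row["deletion_rate"] == pytest.approx(0.02)
        assert row["insertion_rate"] == pytest.approx(0.01)
        assert row["deletion_bias"] == pytest.approx(2.0)
        assert row["net_loss"] == pytest.approx(0.01)

    def test_zero_insertions_leave_bias_missing(self):
        alns = [_aln("a", "chr1", 0, 1000)]
        w = td.window_rates(alns, [_event("deletion", 5, "a")], 1_000_000)
        assert np.isnan(w.iloc[0]["deletion_bias"])
        assert w.iloc[0]["deletion_rate"] == pytest.approx(0.005)

    def test_empty_windows_have_missing_rates(self):
        alns = [_aln("a", "chr1", 0, 100)]
        w = td.window_rates(alns, [], window_size=1000, chrom_sizes={"chr1": 5000})
        assert len(w) == 5
        assert np.isnan(w.iloc[1]["deletion_rate"])
        assert not np.isnan(w.iloc[0]["deletion_rate"])

    def test_net_loss_identity(self, contraction_sim):
        sim = contraction_sim
        events = [e for a in sim.alignments for e in call_indels(a)]
        w = td.window_rates(sim.alignments, events, 50_000)
        ok = w.dropna(subset=["net_loss"])
        assert np.allclose(
            ok["net_loss"], ok["deletion_rate"] - ok["insertion_rate"]
        )

    def test_conservation_under_partitioning(self, contraction_sim):
        """Summed window bp must equal summed event bp, and 1 Mb vs 5 Mb
        aggregation must agree when re-summed genome-wide."""
        sim = contraction_sim
        events = [e for a in sim.alignments for e in call_indels(a)]
        total_del = sum(e.length for e in events if e.kind == "deletion")
        total_ins = sum(e.length for e in events if e.kind == "insertion")
        w1 = td.window_rates(sim.alignments, events, 50_000)
        w5 = td.window_rates(sim.alignments, events, 250_000)
        for w in (w1, w5):
            assert w["deleted_bp"].sum() == total_del
            assert w["inserted_bp"].sum() == total_ins
            assert w["repeat_bp"].sum() == w1["repeat_bp"].sum()

    def test_unique_only_mode_drops_recurrent(self):
        alns = [_aln("a", "chr1", 0, 1000), _aln("b", "chr1", 2000, 1000)]
        events = [
            _event("deletion", 5, "a", pos=10),
            _event("deletion", 5, "b", pos=10),  # same key: recurrent
            _event("deletion", 3, "a", pos=50),
        ]
        w = td.window_rates(alns, events, 1_000_000, unique_only=True)
        assert w.iloc[0]["deleted_bp"] == 3

    def test_normalized_divergence_requires_t_bar(self):
        alns = [_aln("a", "chr1", 0, 100)]
        with pytest.raises(ValueError):
            td.window_rates(alns, [], 1000, activities={"fam": 0.5})

    def test_window_size_validated(self):
        with pytest.raises(ValueError):
            td.window_rates([], [], 0)


class TestGenomeFeatures:
    def _windows(self, n=1, size=1_000_000):
        return pd.DataFrame(
            {
                "chromosome": ["chr1"] * n,
                "start": [i * size for i in range(n)],
                "end": [(i + 1) * size for i in range(n)],
            }
        )

    def test_mean_intron_length(self):
        g = Gene("g", "chr1", 0, 1000, "+", [(0, 100), (200, 300), (600, 1000)])
        ann = GenomeAnnotation([g], chrom_sizes={"chr1": 1_000_000})
        w = td.genome_features(ann, [], self._windows(), window_size=1_000_000)
        assert w.iloc[0]["mean_intron_length"] == pytest.approx(200)  # (100+300)/2

    def test_first_intron_respects_strand(self):
        plus = Gene("p", "chr1", 0, 1000, "+", [(0, 100), (200, 300), (600, 1000)])
        minus = Gene("m", "chr1", 0, 1000, "-", [(0, 100), (200, 300), (600, 1000)])
        w_plus = td.genome_features(
            GenomeAnnotation([plus], {"chr1": 10**6}), [], self._windows(), 10**6
        )
        w_minus = td.genome_features(
            GenomeAnnotation([minus], {"chr1": 10**6}), [], self._windows(), 10**6
        )
        assert w_plus.iloc[0]["mean_first_intron_length"] == pytest.approx(100)
        assert w_minus.iloc[0]["mean_first_intron_length"] == pytest.approx(300)

    def test_fully_covered_intron_has_zero_unique_bp(self):
        g = Gene("g", "chr1", 0, 450, "+", [(0, 100), (250, 450)])
        ann = GenomeAnnotation([g], chrom_sizes={"chr1": 10**6})
        line = _aln("a", "chr1", 100, 150)
        w = td.genome_features(ann, [line], self._windows(), 10**6)
        assert w.iloc[0]["unique_intronic_bp"] == 0

    def test_gene_density_counts_starts_per_mb(self):
        genes = [
            Gene(f"g{i}", "chr1", 1000 * i, 1000 * i + 500, "+", [(1000 * i, 1000 * i + 500)])
            for i in range(3)
        ]
        ann = GenomeAnnotation(genes, chrom_sizes={"chr1": 10**6})
        w = td.genome_features(ann, [], self._windows(), 10**6)
        assert w.iloc[0]["gene_density"] == pytest.approx(3.0)

    def test_unique_intergenic_bp_subtracts_line_cover(self):
        g1 = Gene("g1", "chr1", 0, 300, "+", [(0, 300)])
        g2 = Gene("g2", "chr1", 500, 900, "+", [(500, 900)])
        ann = GenomeAnnotation([g1, g2], chrom_sizes={"chr1": 1000})
        line = _aln("a", "chr1", 350, 50)  # inside intergenic [300, 500)
        w = td.genome_features(ann, [line], self._windows(size=1000), 1000)
        # intergenic bp = 200 + 100; 50 covered by the LINE
        assert w.iloc[0]["unique_intergenic_bp"] == pytest.approx(250)

    def test_intergenic_spacer_by_midpoint(self):
        g1 = Gene("g1", "chr1", 0, 300, "+", [(0, 300)])
        g2 = Gene("g2", "chr1", 500, 900, "+", [(500, 900)])
        ann = GenomeAnnotation([g1, g2], chrom_sizes={"chr1": 1000})
        w = td.genome_features(ann, [], self._windows(size=1000), 1000)
        # intergenic intervals [300,500) and [900,1000): mean 150
        assert w.iloc[0]["intergenic_spacer_length"] == pytest.approx(150)


class TestSizeClassSummary:
    def test_hand_counted_table(self):
        events = [
            _event("deletion", 1, "a"),
            _event("deletion", 2, "b"),
            _event("deletion", 3, "c"),
            _event("deletion", 21, "d"),
        ]
        t = td.size_class_summary(events).set_index(["kind", "size_class"])
        assert t.loc[("deletion", "small"), "n_events"] == 2
        assert t.loc[("deletion", "small"), "bp"] == 3
        assert t.loc[("deletion", "intermediate"), "bp"] == 3
        assert t.loc[("deletion", "long"), "bp"] == 21
        assert t.loc[("insertion", "small"), "n_events"] == 0

    def test_empty_event_list(self):
        t = td.size_class_summary([])
        assert (t["n_events"] == 0).all() and (t["bp"] == 0).all()

    def test_intermediate_dominates_with_default_lengths(self, flat_family_sim):
        events = [e for a in flat_family_sim.alignments for e in call_indels(a)]
        t = td.size_class_summary(events).set_index(["kind", "size_class"])
        for kind in ("insertion", "deletion"):
            bp = t.loc[kind]["bp"]
            assert bp["intermediate"] == bp.max()
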