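"""Generator ground truth: determinism, event fidelity, recovery, placement."""

import io
import json

import numpy as np
import pytest

import teindel as td
from teindel.simulate import SimConfigError, simulate_genome
from teindel.indels import call_indels


def _flat_config(**kw):
    defaults = dict(
        seed=1,
        chromosomes=[td.ChromosomeSpec("chr1", 4_000_000)],
        subfamilies=[td.SubfamilySpec("f1", 1000, 0.0, 0.0, 500)],
        recomb_window=100_000,
    )
    defaults.update(kw)
    return td.SimConfig(**defaults)


class TestSimulateFamily:
    def test_zero_rates_give_identical_copies(self):
        cfg = _flat_config(
            substitution_rate=0.0, insertion_rate=0.0, deletion_rate=0.0
        )
        copies, truths = td.simulate_family(cfg, cfg.subfamilies[0])
        for c, t in zip(copies, truths):
            assert c.master_aln == c.copy_aln
            assert "-" not in c.master_aln
            assert t.n_substitutions == 0 and not t.deletions and not t.insertions

    def test_fixed_seed_is_byte_identical(self):
        cfg = _flat_config()
        c1, _ = td.simulate_family(cfg, cfg.subfamilies[0])
        c2, _ = td.simulate_family(cfg, cfg.subfamilies[0])
        assert all(
            a.master_aln == b.master_aln and a.copy_aln == b.copy_aln
            for a, b in zip(c1, c2)
        )

    def test_called_events_match_truth_exactly(self):
        cfg = _flat_config(truncation_prob=0.3)
        copies, truths = td.simulate_family(cfg, cfg.subfamilies[0])
        for aln, truth in zip(copies, truths):
            events = call_indels(aln)
            got_del = sorted(
                (e.master_pos, e.length) for e in events if e.kind == "deletion"
            )
            got_ins = sorted(
                (e.master_pos, e.length, e.inserted_seq)
                for e in events
                if e.kind == "insertion"
            )
            assert got_del == sorted(truth.deletions)
            assert got_ins == sorted(truth.insertions)

    def test_truncated_copies_have_no_terminal_events(self):
        """5'-truncation clips the alignment; it must never surface as a
        deletion event, and all truth events must survive intact."""
        cfg = _flat_config(truncation_prob=1.0)
        copies, truths = td.simulate_family(cfg, cfg.subfamilies[0])
        assert any(t.truncated for t in truths)
        for aln, truth in zip(copies, truths):
            events = call_indels(aln)
            assert len([e for e in events if e.kind == "deletion"]) == len(
                truth.deletions
            )
            for e in events:
                assert e.master_pos > aln.m_start

    def test_master_length_zero_rejected(self):
        cfg = _flat_config()
        bad = td.SubfamilySpec("bad", 0, 0.0, 0.1, 10)
        with pytest.raises(SimConfigError):
            cfg2 = _flat_config()
            cfg2.subfamilies = [bad]
            td.simulate_family(cfg2, bad)

    def test_epoch_outside_unit_interval_rejected(self):
        with pytest.raises(SimConfigError):
            _flat_config(
                subfamilies=[td.SubfamilySpec("f", 100, 0.5, 1.2, 10)]
            ).validate()


class TestRateRecovery:
    def test_indel_and_substitution_rates_recovered(self, flat_family_sim):
        """Configured deletion 0.05, insertion 0.015, substitution 0.10 per
        bp over unit elapsed time must be recovered by the calling pipeline
        within 10% relative error at 2,000 copies x 1 kb."""
        sim = flat_family_sim
        cfg = sim.config
        events = [e for a in sim.alignments for e in call_indels(a)]
        repeat_bp = sum(a.master_span for a in sim.alignments)
        del_rate = sum(e.length for e in events if e.kind == "deletion") / repeat_bp
        ins_rate = sum(e.length for e in events if e.kind == "insertion") / repeat_bp
        assert del_rate == pytest.approx(cfg.deletion_rate, rel=0.10)
        assert ins_rate == pytest.approx(cfg.insertion_rate, rel=0.10)

        mism = sites = 0
        for a in sim.alignments:
            d = td.substitution_divergence(a, model="p")
            mism += d.p_distance * d.sites
            sites += d.sites
        assert mism / sites == pytest.approx(cfg.substitution_rate, rel=0.10)

    def test_deletion_bias_recovered(self, flat_family_sim):
        sim = flat_family_sim
        events = [e for a in sim.alignments for e in call_indels(a)]
        bias = sum(e.length for e in events if e.kind == "deletion") / sum(
            e.length for e in events if e.kind == "insertion"
        )
        assert abs(bias - sim.config.deletion_bias) < 0.35


class TestSimulateGenome:
    def test_null_link_gives_no_correlation(self):
        """beta = 0: window recombination rate and true deletion rate must
        be uncorrelated (|tau| < 0.1 at 200 windows)."""
        cfg = td.SimConfig(
            seed=0,
            chromosomes=[td.ChromosomeSpec("chr1", 10_000_000)],
            subfamilies=[td.SubfamilySpec("f1", 600, 0.0, 0.2, 1600)],
            recomb_window=50_000,
            beta=0.0,
        )
        sim = simulate_genome(cfg)
        w = sim.truth.windows.dropna(subset=["true_deletion_rate"])
        res = td.kendall_tau_b(w["recomb_rate"], w["true_deletion_rate"])
        assert abs(res.tau) < 0.1

    def test_positive_link_raises_deletion_rate_with_recombination(self):
        cfg = td.SimConfig(
            seed=0,
            chromosomes=[td.ChromosomeSpec("chr1", 10_000_000)],
            subfamilies=[td.SubfamilySpec("f1", 600, 0.0, 0.2, 1600)],
            recomb_window=50_000,
            beta=2.0,
        )
        sim = simulate_genome(cfg)
        w = sim.truth.windows.dropna(subset=["true_deletion_rate"])
        res = td.kendall_tau_b(w["recomb_rate"], w["true_deletion_rate"])
        assert res.tau > 0 and res.p_value < 0.05

    def test_w_chromosome_never_recombines(self, sex_sim):
        t = sex_sim.recomb_map.table
        assert (t.loc[t.chromosome == "chrW", "rate"] == 0).all()
        z = t.loc[t.chromosome == "chrZ", "rate"].mean()
        auto = t.loc[t.chromosome.isin(["chr1", "chr2"]), "rate"].mean()
        assert z < auto

    def test_placement_overflow_rejected(self):
        cfg = _flat_config(
            chromosomes=[td.ChromosomeSpec("chr1", 50_000)],
            subfamilies=[td.SubfamilySpec("f1", 1000, 0.0, 0.1, 500)],
            recomb_window=50_000,
        )
        with pytest.raises(SimConfigError, match="overflow"):
            simulate_genome(cfg)

    def test_nested_fragments_share_copy_id_and_are_adjacent(self, contraction_sim):
        by_id = {}
        for a in contraction_sim.alignments:
            by_id.setdefault(a.copy_id, []).append(a)
        split = {k: v for k, v in by_id.items() if len(v) > 1}
        assert split  # the scenario nests
        for frags in split.values():
            frags.sort(key=lambda a: a.g_start)
            f1, f2 = frags
            assert f1.m_end == f2.m_start  # contiguous in consensus coords
            assert f2.g_start > f1.g_end  # a nested element sits between


class TestFixtureEmission:
    def test_emit_then_parse_identity(self, null_sim, tmp_path):
        files = td.emit_fixtures(null_sim, tmp_path)
        with open(files["repeats.out"]) as o, open(files["repeats.align"]) as a:
            parsed = td.parse_repeat_alignments(o, a)
        assert len(parsed) == len(null_sim.alignments)
        key = lambda x: (x.chromosome, x.g_start)
        for p, s in zip(sorted(parsed, key=key), sorted(null_sim.alignments, key=key)):
            assert p.master_aln == s.master_aln and p.copy_aln == s.copy_aln

    def test_manifest_hash_tracks_config(self, tmp_path):
        c1 = _flat_config(seed=5)
        c2 = _flat_config(seed=5, deletion_rate=0.06)
        h1a, h1b, h2 = (
            c1.content_hash(),
            _flat_config(seed=5).content_hash(),
            c2.content_hash(),
        )
        assert h1a == h1b and h1a != h2
        td.emit_fixtures(simulate_genome(c1), tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["config_hash"] == h1a and manifest["seed"] == 5

    def test_three_scenarios_generate(self, tmp_path):
        for name in ("null", "contraction", "sex-chromosome"):
            files = td.run_simulation(name, tmp_path / name, seed=1)
            assert "manifest.json" in files
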