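"""Rank correlation, stratified bootstrap, randomization test, BH, SFS test."""

import numpy as np
import pandas as pd
import pytest

import teindel as td
from teindel.stats import BootstrapSpec, RandomizationResult

from conftest import brute_force_tau_b


class TestKendallTauB:
    def test_perfect_concordance(self):
        assert td.kendall_tau_b([1, 2, 3], [1, 2, 3]).tau == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert td.kendall_tau_b([1, 2, 3], [3, 2, 1]).tau == pytest.approx(-1.0)

    def test_pair_count_example(self):
        # 5 concordant, 1 discordant of 6 pairs
        res = td.kendall_tau_b([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.tau == pytest.approx(4 / 6)

    def test_missing_pairs_dropped(self):
        res = td.kendall_tau_b([1, 2, np.nan, 4], [1, 3, 2, 4])
        assert res.n == 3

    def test_all_tied_flagged(self):
        res = td.kendall_tau_b([1, 1, 1], [1, 2, 3])
        assert np.isnan(res.tau) and res.p_value == 1.0

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(5, 25))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert td.kendall_tau_b(x, y).tau == pytest.approx(
                brute_force_tau_b(x, y), abs=1e-12
            )


def _toy_elements(rng, n_per=40, strata=("s1", "s2"), sep=False):
    rows = []
    for cat in ("Z", "autosome"):
        for i in range(n_per):
            stratum = strata[i % len(strata)]
            if sep:
                d = 30 if cat == "Z" else 0
                ins = 1 if cat == "Z" else 30
            else:
                d = int(rng.poisson(10))
                ins = 1 + int(rng.poisson(5))
            rows.append(
                {
                    "category": cat,
                    "stratum": stratum,
                    "length": float(rng.lognormal(5, 0.5)),
                    "deleted_bp": d,
                    "inserted_bp": ins,
                }
            )
    return pd.DataFrame(rows)


class TestStratifiedBootstrap:
    def test_maximal_separation_gives_floor_p(self):
        rng = np.random.default_rng(0)
        df = _toy_elements(rng, sep=True)
        spec = BootstrapSpec(("Z", "autosome"), replicates=500, seed=1)
        res = td.stratified_bootstrap_diff(spec, df)
        assert res.p_two_sided <= 2 / 500

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(1)
        df = _toy_elements(rng)
        spec = BootstrapSpec(("Z", "autosome"), replicates=300, seed=9)
        r1 = td.stratified_bootstrap_diff(spec, df)
        r2 = td.stratified_bootstrap_diff(spec, df)
        assert r1.p_two_sided == r2.p_two_sided
        assert r1.observed == r2.observed

    def test_mean_length_statistic(self):
        rng = np.random.default_rng(2)
        df = _toy_elements(rng)
        spec = BootstrapSpec(
            ("Z", "autosome"), replicates=200, seed=3, statistic="mean-length-diff"
        )
        res = td.stratified_bootstrap_diff(spec, df)
        expected = (
            df[df.category == "Z"]["length"].mean()
            - df[df.category == "autosome"]["length"].mean()
        )
        assert res.observed == pytest.approx(expected)

    def test_stratum_absent_from_one_category_excluded(self):
        rng = np.random.default_rng(3)
        df = _toy_elements(rng)
        extra = df.iloc[:1].copy()
        extra["stratum"] = "only-z"
        extra["category"] = "Z"
        res = td.stratified_bootstrap_diff(
            BootstrapSpec(("Z", "autosome"), replicates=50, seed=4),
            pd.concat([df, extra], ignore_index=True),
        )
        assert res.excluded_strata == ["only-z"]


class TestChromosomeRandomization:
    def _windows(self, rng, n_chrom=3, n_win=30, concordant=False):
        rows = []
        for c in range(n_chrom):
            x = rng.normal(size=n_win)
            y = np.sort(rng.normal(size=n_win))[np.argsort(np.argsort(x))] if concordant else rng.normal(size=n_win)
            for xi, yi in zip(x, y):
                rows.append({"chromosome": f"chr{c}", "x": xi, "y": yi})
        return pd.DataFrame(rows)

    def test_perfect_concordance_extreme_rank(self):
        rng = np.random.default_rng(4)
        df = self._windows(rng, n_chrom=1, concordant=True)
        res = td.chromosome_randomization_test(
            df, "x", "y", min_windows=20, replicates=999, seed=5
        )
        assert res.mean_tau == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_small_chromosomes_excluded(self):
        rng = np.random.default_rng(5)
        df = self._windows(rng, n_chrom=2, n_win=30)
        small = self._windows(rng, n_chrom=1, n_win=5)
        small["chromosome"] = "chr_small"
        res = td.chromosome_randomization_test(
            pd.concat([df, small]), "x", "y", min_windows=20, replicates=99, seed=6
        )
        assert set(res.per_chromosome["chromosome"]) == {"chr0", "chr1"}

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(6)
        df = self._windows(rng)
        kw = dict(min_windows=20, replicates=500, seed=7)
        assert (
            td.chromosome_randomization_test(df, "x", "y", **kw).p_value
            == td.chromosome_randomization_test(df, "x", "y", **kw).p_value
        )

    def test_per_chromosome_tau_matches_public_tau(self):
        rng = np.random.default_rng(7)
        df = self._windows(rng)
        res = td.chromosome_randomization_test(
            df, "x", "y", min_windows=20, replicates=9, seed=8
        )
        for row in res.per_chromosome.itertuples():
            sub = df[df.chromosome == row.chromosome]
            assert row.tau == pytest.approx(
                td.kendall_tau_b(sub["x"], sub["y"]).tau, abs=1e-12
            )


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert td.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_by_hand_uniform_grid(self):
        assert td.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_step_up_by_hand_two_values(self):
        assert td.bh_adjust([0.005, 0.05]) == pytest.approx([0.01, 0.05])

    def test_monotone_capped_and_dominating(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=20)
        adj = td.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0) and np.all(adj >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            td.bh_adjust([0.5, 1.5])


class TestSFSContingency:
    def _poly(self, counts):
        # counts: dict kind -> (n_rare, n_common)
        recs = []
        for kind, (r, c) in counts.items():
            recs += [
                td.PolymorphicIndel("chr1", i, kind, 0.01, "intergenic")
                for i in range(r)
            ]
            recs += [
                td.PolymorphicIndel("chr1", i, kind, 0.3, "intergenic")
                for i in range(c)
            ]
        return recs

    def test_hand_computed_chi_square(self):
        recs = self._poly({"insertion": (20, 80), "deletion": (40, 60)})
        res = td.sfs_contingency_test(recs, "intergenic")
        assert res.chi_square == pytest.approx(9.524, abs=1e-3)
        assert res.proportion_rare["insertion"] == pytest.approx(0.2)
        assert res.proportion_rare["deletion"] == pytest.approx(0.4)

    def test_equal_proportions_give_zero(self):
        recs = self._poly({"insertion": (30, 70), "deletion": (30, 70)})
        assert td.sfs_contingency_test(recs, "intergenic").chi_square == pytest.approx(0.0)

    def test_empty_kind_rejected(self):
        recs = self._poly({"insertion": (10, 10), "deletion": (0, 0)})
        with pytest.raises(ValueError):
            td.sfs_contingency_test(recs, "intergenic")

    def test_context_filtering(self):
        recs = self._poly({"insertion": (10, 10), "deletion": (10, 10)})
        with pytest.raises(ValueError):
            td.sfs_contingency_test(recs, "intron")
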