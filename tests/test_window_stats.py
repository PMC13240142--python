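import math

import numpy as np
import pytest
from conftest import make_gm

import oracles
from divscan.genotype_io import MISSING
from divscan.window_stats import (
    TajimaConstants,
    WindowSpec,
    genome_scan,
    make_windows,
    read_scan_tsv,
    site_pi,
    site_wc_components,
    window_pi,
    window_tajima_d,
    window_weighted_fst,
    write_scan_tsv,
)


class TestMakeWindows:
    def test_100kb_chrom_default_spec(self):
        wins = make_windows({"chr1": 100_000}, WindowSpec())
        assert len(wins) == 10
        assert wins[0] == ("chr1", 1, 100_000)
        assert wins[-1] == ("chr1", 90_001, 100_000)

    def test_short_chrom_single_truncated(self):
        assert make_windows({"c": 5000}, WindowSpec()) == [("c", 1, 5000)]

    def test_interior_position_covered_ten_times(self):
        wins = make_windows({"c": 1_000_000}, WindowSpec())
        covering = [w for w in wins if w[1] <= 500_000 <= w[2]]
        assert len(covering) == 10

    def test_sorted_multi_chrom(self):
        wins = make_windows({"chr2": 30_000, "chr1": 30_000}, WindowSpec(10_000, 10_000))
        assert wins == sorted(wins)
        assert len(wins) == 6

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            WindowSpec(size=5, step=10)


class TestSitePi:
    def test_example_two_diploids(self):
        # 0/0 and 0/1: m=4, j=1 -> 2*1*3/(4*3) = 0.5
        assert site_pi(np.array([0, 1])) == pytest.approx(0.5)

    def test_monomorphic(self):
        assert site_pi(np.array([0, 0, 0])) == 0.0

    def test_single_pair_differs(self):
        # one diploid het: m=2, j=1 -> 1.0
        assert site_pi(np.array([1, MISSING])) == pytest.approx(1.0)

    def test_undefined_below_two_alleles(self):
        assert math.isnan(site_pi(np.array([MISSING, MISSING])))

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            col = oracles.random_genotype_matrix(rng, 8, 1, missing_rate=0.2)[:, 0]
            got = site_pi(col)
            want = oracles.site_pi_pairs(col)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-12)


class TestWcComponents:
    def test_identical_populations_a_near_zero(self):
        # identical genotype arrays: s^2 = 0, so a is the (small, negative)
        # finite-sample correction term, never positive
        col = np.array([0, 1, 2, 1, 0] * 2)
        a, b, c = site_wc_components(col, np.arange(5), np.arange(5, 10))
        assert a <= 1e-12
        assert abs(a) < 0.1

    def test_fixed_difference_ratio_one(self):
        col = np.array([0] * 10 + [2] * 10)
        a, b, c = site_wc_components(col, np.arange(10), np.arange(10, 20))
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(1)
        idx_a, idx_b = np.arange(5), np.arange(5, 10)
        for _ in range(300):
            col = oracles.random_genotype_matrix(rng, 10, 1, missing_rate=0.15)[:, 0]
            got = site_wc_components(col, idx_a, idx_b)
            want = oracles.wc_components_scalar(col, idx_a, idx_b)
            for g, w in zip(got, want):
                if math.isnan(w):
                    assert math.isnan(g)
                else:
                    assert g == pytest.approx(w, rel=1e-12, abs=1e-15)


class TestTajimaConstants:
    @pytest.mark.parametrize("n", [4, 10, 28, 68])
    def test_all_positive(self, n):
        k = TajimaConstants.from_n(n)
        for name in ("a1", "a2", "b1", "b2", "c1", "c2", "e1", "e2"):
            assert getattr(k, name) > 0, name

    def test_hand_computed_n4(self):
        k = TajimaConstants.from_n(4)
        assert k.a1 == pytest.approx(1 + 1 / 2 + 1 / 3)
        assert k.a2 == pytest.approx(1 + 1 / 4 + 1 / 9)
        assert k.b1 == pytest.approx(5 / 9)
        assert k.b2 == pytest.approx(2 * 23 / (9 * 4 * 3))


class TestWindowOps:
    def test_window_pi_scaling(self):
        gm = make_gm(np.array([[0], [1]]), positions=[50])
        assert window_pi(gm, ("chr1", 1, 100), "P1") == pytest.approx(0.005)
        assert window_pi(gm, ("chr1", 1, 200), "P1") == pytest.approx(0.0025)

    def test_window_pi_empty(self):
        gm = make_gm(np.array([[0], [1]]), positions=[500])
        assert window_pi(gm, ("chr1", 1, 100), "P1") == 0.0

    def test_pi_invariant_to_monomorphic_sites(self):
        gm1 = make_gm(np.array([[0, 0], [1, 0]]), positions=[50, 60])
        gm2 = make_gm(np.array([[0], [1]]), positions=[50])
        w = ("chr1", 1, 100)
        assert window_pi(gm1, w, "P1") == pytest.approx(window_pi(gm2, w, "P1"))

    def test_single_fixed_difference_window_fst_one(self):
        gm = make_gm(
            np.array([[0]] * 5 + [[2]] * 5), positions=[10], pops=["A"] * 5 + ["B"] * 5
        )
        assert window_weighted_fst(gm, ("chr1", 1, 100), ("A", "B")) == pytest.approx(1.0)

    def test_no_usable_sites_undefined(self):
        calls = np.array([[MISSING], [0], [0], [0]])
        gm = make_gm(calls, positions=[10], pops=["A", "A", "B", "B"])
        gm2 = make_gm(
            np.array([[MISSING], [MISSING], [0], [0]]),
            positions=[10],
            pops=["A", "A", "B", "B"],
        )
        assert math.isnan(window_weighted_fst(gm2, ("chr1", 20, 30), ("A", "B")))

    def test_tajima_no_segregating_undefined(self):
        gm = make_gm(np.zeros((5, 3), dtype=np.int8))
        assert math.isnan(window_tajima_d(gm, ("chr1", 1, 10), "P1"))

    def test_tajima_matches_oracle_no_missing(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, size=(5, 3)).astype(np.int8)
        gm = make_gm(calls)
        got = window_tajima_d(gm, ("chr1", 1, 10), "P1")
        want = oracles.tajima_d_scalar(calls, np.arange(5), np.arange(3))
        assert got == pytest.approx(want, rel=1e-12)

    def test_tajima_sign(self):
        # all singletons -> D < 0; intermediate-frequency variants -> D > 0
        n = 10
        singles = np.zeros((n, 6), dtype=np.int8)
        for s in range(6):
            singles[s % n, s] = 1
        gm_neg = make_gm(singles)
        assert window_tajima_d(gm_neg, ("chr1", 1, 10), "P1") < 0
        inter = np.zeros((n, 6), dtype=np.int8)
        inter[: n // 2, :] = 2
        gm_pos = make_gm(inter)
        assert window_tajima_d(gm_pos, ("chr1", 1, 10), "P1") > 0


class TestOracleEquivalence:
    """Window statistics match independent scalar oracles on random matrices."""

    @pytest.mark.parametrize("seed", range(20))
    def test_all_three_statistics(self, seed):
        rng = np.random.default_rng(seed)
        n_samples = int(rng.integers(6, 21))
        n_sites = int(rng.integers(5, 51))
        calls = oracles.random_genotype_matrix(rng, n_samples, n_sites, 0.1)
        half = n_samples // 2
        pops = ["A"] * half + ["B"] * (n_samples - half)
        positions = np.sort(
            rng.choice(np.arange(1, 1000), size=n_sites, replace=False)
        )
        gm = make_gm(calls, positions=positions.tolist(), pops=pops)
        window = ("chr1", 1, 1000)
        site_idx = np.arange(n_sites)
        idx_a, idx_b = np.arange(half), np.arange(half, n_samples)

        got_pi = window_pi(gm, window, "A")
        want_pi = oracles.window_pi_scalar(calls, idx_a, site_idx, 1000)
        assert got_pi == pytest.approx(want_pi, rel=1e-10, abs=1e-15)

        got_fst = window_weighted_fst(gm, window, ("A", "B"))
        want_fst = oracles.window_fst_scalar(calls, idx_a, idx_b, site_idx)
        if math.isnan(want_fst):
            assert math.isnan(got_fst)
        else:
            assert got_fst == pytest.approx(want_fst, rel=1e-10)

        got_d = window_tajima_d(gm, window, "B")
        want_d = oracles.tajima_d_scalar(calls, idx_b, site_idx)
        if math.isnan(want_d):
            assert math.isnan(got_d)
        else:
            assert got_d == pytest.approx(want_d, rel=1e-10)


class TestGenomeScan:
    def test_window_count_1mb(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(8, 200)).astype(np.int8)
        pos = np.sort(rng.choice(1_000_000, size=200, replace=False) + 1)
        gm = make_gm(calls, positions=pos.tolist(), pops=["A"] * 4 + ["B"] * 4)
        stats = genome_scan(gm, WindowSpec(), chrom_lengths={"chr1": 1_000_000})
        assert len(stats) == 100

    def test_identical_populations_fst_near_zero(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 3, size=(6, 300)).astype(np.int8)
        calls = np.vstack([calls, calls])  # two clones of one population
        pos = np.sort(rng.choice(200_000, size=300, replace=False) + 1)
        gm = make_gm(calls, positions=pos.tolist(), pops=["A"] * 6 + ["B"] * 6)
        stats = genome_scan(
            gm, WindowSpec(10_000, 10_000), chrom_lengths={"chr1": 200_000}
        )
        vals = [w.fst[("A", "B")] for w in stats if math.isfinite(w.fst[("A", "B")])]
        # clones: no among-population variance, only the small negative
        # finite-sample correction survives
        assert max(vals) <= 1e-12
        assert min(vals) > -0.25

    def test_scan_composes_single_window_ops(self, toy_two_pop_gm):
        gm = toy_two_pop_gm
        stats = genome_scan(gm, WindowSpec(100, 100), chrom_lengths={"chr1": 100})
        assert len(stats) == 1
        ws = stats[0]
        w = ("chr1", 1, 100)
        assert ws.pi["A"] == pytest.approx(window_pi(gm, w, "A"))
        assert ws.fst[("A", "B")] == pytest.approx(
            window_weighted_fst(gm, w, ("A", "B"))
        )
        got_d = window_tajima_d(gm, w, "B")
        assert ws.tajima_d["B"] == pytest.approx(got_d, nan_ok=True)

    def test_empty_matrix_warns(self, caplog):
        gm = make_gm(np.empty((4, 0), dtype=np.int8))
        with caplog.at_level("WARNING"):
            stats = genome_scan(gm, WindowSpec(), chrom_lengths={"chr1": 50_000})
        assert all(w.n_variants == 0 for w in stats)
        assert any("empty" in r.message for r in caplog.records)

    def test_permuting_samples_never_changes_statistics(self, toy_two_pop_gm):
        gm = toy_two_pop_gm
        rng = np.random.default_rng(11)
        perm = rng.permutation(gm.n_samples)
        gm2 = make_gm(
            gm.calls[perm],
            positions=[s.pos for s in gm.sites],
            pops=[gm.pop_of[gm.samples[i]] for i in perm],
        )
        s1 = genome_scan(gm, WindowSpec(30, 10), pops=["A", "B"],
                         chrom_lengths={"chr1": 60})
        s2 = genome_scan(gm2, WindowSpec(30, 10), pops=["A", "B"],
                         chrom_lengths={"chr1": 60})
        for a, b in zip(s1, s2):
            for p in a.pi:
                assert a.pi[p] == pytest.approx(b.pi[p], nan_ok=True)
                assert a.tajima_d[p] == pytest.approx(b.tajima_d[p], nan_ok=True)
            for k in a.fst:
                assert a.fst[k] == pytest.approx(b.fst[k], nan_ok=True)

    def test_fst_never_exceeds_one(self):
        rng = np.random.default_rng(13)
        calls = oracles.random_genotype_matrix(rng, 12, 400, 0.05)
        pos = np.sort(rng.choice(100_000, size=400, replace=False) + 1)
        gm = make_gm(calls, positions=pos.tolist(), pops=["A"] * 6 + ["B"] * 6)
        stats = genome_scan(gm, WindowSpec(5000, 1000), chrom_lengths={"chr1": 100_000})
        for w in stats:
            v = w.fst[("A", "B")]
            assert math.isnan(v) or v <= 1.0 + 1e-12

    def test_tsv_round_trip(self, toy_two_pop_gm, tmp_path):
        stats = genome_scan(
            toy_two_pop_gm, WindowSpec(30, 10), chrom_lengths={"chr1": 60}
        )
        path = str(tmp_path / "scan.tsv")
        write_scan_tsv(stats, path)
        back = read_scan_tsv(path)
        assert len(back) == len(stats)
        for a, b in zip(stats, back):
            assert (a.chrom, a.start, a.end) == (b.chrom, b.start, b.end)
            for p in a.pi:
                assert b.pi[p] == pytest.approx(a.pi[p], nan_ok=True)
            for k in a.fst:
                assert b.fst[k] == pytest.approx(a.fst[k], nan_ok=True)


def test_mean_fst_near_zero_identical_pops_many_windows():
    # expectation ~ 0 for identical populations over >= 200 windows
    rng = np.random.default_rng(21)
    n_sites = 2000
    calls = rng.integers(0, 3, size=(20, n_sites)).astype(np.int8)
    pos = np.sort(rng.choice(2_000_000, size=n_sites, replace=False) + 1)
    gm = make_gm(calls, positions=pos.tolist(), pops=["A"] * 10 + ["B"] * 10)
    stats = genome_scan(gm, WindowSpec(10_000, 10_000), chrom_lengths={"chr1": 2_000_000})
    vals = np.array([w.fst[("A", "B")] for w in stats])
    vals = vals[np.isfinite(vals)]
    assert len(vals) >= 200
    assert abs(vals.mean()) < 0.01
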