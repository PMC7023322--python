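"""Windowed diversity, Tajima's D, Weir–Cockerham F_st vs brute-force oracles."""

import itertools

import numpy as np
import pytest

from sweepscan import (
    PopulationMap,
    log2_pi_ratio,
    make_windows,
    windowed_pi,
    windowed_tajima_d,
    windowed_wc_fst,
    z_transform,
)
from sweepscan.window_stats import tajima_constants, tajima_d_from_counts

from conftest import make_gm, random_gm


# ---------------------------------------------------------------------------
# brute-force oracles (scalar, loop-based, independent of the implementation)
# ---------------------------------------------------------------------------

def site_alleles(column, sample_idx):
    """Observed alleles (0/1 each) for one site in one group."""
    alleles = []
    for i in sample_idx:
        g = int(column[i])
        if g < 0:
            continue
        alleles.extend([1] * g + [0] * (2 - g))
    return alleles


def brute_pi_sum(gm, sample_idx, lo, hi):
    """Mean pairwise difference summed over sites in [lo, hi]."""
    total = 0.0
    for j in range(gm.n_sites):
        if not (lo <= gm.sites.loc[j, "pos"] <= hi):
            continue
        alleles = site_alleles(gm.calls[:, j], sample_idx)
        if len(alleles) < 2:
            continue
        pairs = list(itertools.combinations(alleles, 2))
        total += sum(abs(a - b) for a, b in pairs) / len(pairs) * 1  # mean diff
        # mean over pairs * 1 site = per-site mean pairwise difference
    return total


def brute_wc_site(col, idx1, idx2):
    """Scalar Weir–Cockerham components from the published formulas."""
    stats = []
    for idx in (idx1, idx2):
        gs = [int(col[i]) for i in idx if col[i] >= 0]
        n = len(gs)
        if n < 1:
            return None
        p = sum(gs) / (2.0 * n)
        h = sum(1 for g in gs if g == 1) / n
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    r = 2
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return None
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return None
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def brute_window_fst(gm, idx1, idx2, lo, hi):
    num = den = 0.0
    any_site = False
    for j in range(gm.n_sites):
        if not (lo <= gm.sites.loc[j, "pos"] <= hi):
            continue
        comp = brute_wc_site(gm.calls[:, j], idx1, idx2)
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
        any_site = True
    if not any_site or den == 0:
        return float("nan")
    return num / den


def brute_tajima_d(gm, sample_idx, lo, hi):
    """Independent D: brute-force pairwise diversity, S count, and constants."""
    n = 2 * len(sample_idx)
    pi = brute_pi_sum(gm, sample_idx, lo, hi)
    s = 0
    for j in range(gm.n_sites):
        if not (lo <= gm.sites.loc[j, "pos"] <= hi):
            continue
        alleles = site_alleles(gm.calls[:, j], sample_idx)
        if 0 < sum(alleles) < len(alleles):
            s += 1
    if s == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    var = (c1 / a1) * s + (c2 / (a1**2 + a2)) * s * (s - 1)
    return (pi - s / a1) / var**0.5


# ---------------------------------------------------------------------------
# window grid
# ---------------------------------------------------------------------------

class TestMakeWindows:
    def test_default_grid_on_250kb(self):
        grid = make_windows({"chr1": 250_000})
        starts = list(grid.windows["start"])
        assert starts == [1, 50_001, 100_001, 150_001, 200_001]
        assert list(grid.windows["end"])[0] == 100_000

    def test_short_chromosome_single_window(self):
        grid = make_windows({"chr1": 99_999})
        assert grid.n_windows == 1

    def test_tiling_when_step_equals_size(self):
        grid = make_windows({"chr1": 300_000}, 100_000, 100_000)
        assert list(grid.windows["start"]) == [1, 100_001, 200_001]

    def test_empty_extents_error(self):
        with pytest.raises(ValueError):
            make_windows({})


# ---------------------------------------------------------------------------
# windowed pi
# ---------------------------------------------------------------------------

class TestWindowedPi:
    def test_single_site_closed_form(self):
        # two diploids both heterozygous: c_ref = c_alt = 2 -> 2*2*2/(4*3)
        gm = make_gm([[1], [1]], positions=[500])
        grid = make_windows({"chr1": 500})
        pi = windowed_pi(gm, gm.sample_ids, grid)
        assert pi[0] == pytest.approx((2 / 3) / 100_000)

    def test_monomorphic_window_zero(self):
        gm = make_gm([[0, 2], [0, 2]], positions=[10, 20])
        grid = make_windows({"chr1": 100})
        # site 2 fixed ALT -> both sites monomorphic within the group
        assert windowed_pi(gm, gm.sample_ids, grid)[0] == 0.0

    def test_matches_brute_force_pairwise(self, rng):
        for _ in range(25):
            gm = random_gm(rng, n_samples=10, n_sites=50, missing_rate=0.1)
            grid = make_windows({"chr1": 100_000})
            group = gm.sample_ids[:6]
            idx = gm.sample_indices(group)
            pi = windowed_pi(gm, group, grid)
            for w, row in enumerate(grid.windows.itertuples()):
                expected = brute_pi_sum(gm, idx, row.start, row.end) / 100_000
                assert pi[w] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_sample_order_and_relabeling(self, rng):
        gm = random_gm(rng, n_samples=8, n_sites=40)
        grid = make_windows({"chr1": 100_000})
        group = list(gm.sample_ids)
        pi = windowed_pi(gm, group, grid)
        np.testing.assert_allclose(pi, windowed_pi(gm, group[::-1], grid))
        flipped = gm.calls.copy()
        called = flipped >= 0
        flipped[called] = 2 - flipped[called]
        gm2 = make_gm(flipped, positions=gm.sites["pos"])
        np.testing.assert_allclose(pi, windowed_pi(gm2, group, grid), atol=1e-15)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

class TestTajimaD:
    def test_no_segregating_sites_undefined(self):
        gm = make_gm([[0, 2], [0, 2]], positions=[10, 20])
        grid = make_windows({"chr1": 100})
        d, s = windowed_tajima_d(gm, gm.sample_ids, grid)
        assert np.isnan(d[0]) and s[0] == 0

    def test_hand_built_window_matches_independent_computation(self):
        # 2 diploids = 4 haplotypes, 3 segregating sites
        gm = make_gm([[1, 0, 2], [0, 1, 1]], positions=[100, 200, 300])
        grid = make_windows({"chr1": 300})
        d, s = windowed_tajima_d(gm, gm.sample_ids, grid)
        assert s[0] == 3
        expected = brute_tajima_d(gm, [0, 1], 1, 100_000)
        assert d[0] == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            gm = random_gm(rng, n_samples=8, n_sites=40, missing_rate=0.05)
            grid = make_windows({"chr1": 100_000}, 50_000, 25_000)
            group = gm.sample_ids[:5]
            idx = gm.sample_indices(group)
            d, _ = windowed_tajima_d(gm, group, grid)
            for w, row in enumerate(grid.windows.itertuples()):
                expected = brute_tajima_d(gm, idx, row.start, row.end)
                if np.isnan(expected):
                    assert np.isnan(d[w])
                else:
                    assert d[w] == pytest.approx(expected, abs=1e-10)

    def test_constants_against_closed_forms(self):
        k = tajima_constants(4)
        assert k["a1"] == pytest.approx(1 + 1 / 2 + 1 / 3)
        assert k["b1"] == pytest.approx(5 / 9)
        with pytest.raises(ValueError):
            tajima_constants(3)
        assert np.isnan(tajima_d_from_counts(1.0, 0, 10))


# ---------------------------------------------------------------------------
# Weir–Cockerham F_st
# ---------------------------------------------------------------------------

class TestWcFst:
    def test_fixed_difference_gives_one(self, two_pop_map):
        calls = np.array([[2, 2], [2, 2], [0, 0], [0, 0], [0, 0]], dtype=np.int8)
        gm = make_gm(calls, positions=[100, 200])
        grid = make_windows({"chr1": 200})
        fst = windowed_wc_fst(gm, two_pop_map(gm, 2), grid)
        assert fst[0] == pytest.approx(1.0)

    def test_identical_pops_near_zero_no_clamping(self, rng, two_pop_map):
        block = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
        calls = np.vstack([block, block])
        gm = make_gm(calls)
        grid = make_windows({"chr1": 100_000})
        fst = windowed_wc_fst(gm, two_pop_map(gm, 4), grid)
        assert fst[0] <= 1e-9  # small negative estimates are allowed

    def test_matches_brute_force_components(self, rng, two_pop_map):
        for _ in range(25):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            gm = random_gm(rng, n_samples=n1 + n2, n_sites=50, missing_rate=0.1)
            pm = two_pop_map(gm, n1)
            grid = make_windows({"chr1": 100_000}, 50_000, 50_000)
            fst = windowed_wc_fst(gm, pm, grid)
            idx1 = gm.sample_indices(pm.samples_in("non_sport"))
            idx2 = gm.sample_indices(pm.samples_in("sport"))
            for w, row in enumerate(grid.windows.itertuples()):
                expected = brute_window_fst(gm, idx1, idx2, row.start, row.end)
                if np.isnan(expected):
                    assert np.isnan(fst[w])
                else:
                    assert fst[w] == pytest.approx(expected, abs=1e-10)

    def test_window_value_changes_only_for_windows_entered_and_left(self, rng, two_pop_map):
        # moving one SNP across a window boundary affects exactly the
        # windows it leaves/enters
        gm = random_gm(rng, n_samples=8, n_sites=30, span=150_000)
        pm = two_pop_map(gm, 4)
        grid = make_windows({"chr1": 150_000})
        base = windowed_wc_fst(gm, pm, grid)
        sites = gm.sites.copy()
        j = gm.n_sites // 2
        old_pos = int(sites.loc[j, "pos"])
        new_pos = old_pos + 50_000  # shift by one step
        sites.loc[j, "pos"] = new_pos
        order = np.argsort(sites["pos"].to_numpy(), kind="stable")
        gm2 = make_gm(gm.calls[:, order], positions=sites["pos"].to_numpy()[order])
        moved = windowed_wc_fst(gm2, pm, grid)
        affected = {
            w for w, row in enumerate(grid.windows.itertuples())
            if (row.start <= old_pos <= row.end) != (row.start <= new_pos <= row.end)
        }
        for w in range(grid.n_windows):
            if w not in affected:
                same = (np.isnan(base[w]) and np.isnan(moved[w])) or \
                    base[w] == pytest.approx(moved[w], abs=1e-12)
                assert same


# ---------------------------------------------------------------------------
# z-transform and log2 ratio
# ---------------------------------------------------------------------------

class TestZTransform:
    def test_simple_example(self):
        np.testing.assert_allclose(z_transform([1.0, 2.0, 3.0]), [-1, 0, 1])

    def test_mean_zero_unit_sd(self, rng):
        x = rng.normal(size=200)
        z = z_transform(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_undefined_entries_preserved(self):
        z = z_transform([1.0, np.nan, 3.0])
        assert np.isnan(z[1]) and not np.isnan(z[0])

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            z_transform([2.0, 2.0, 2.0])


class TestLog2Ratio:
    def test_cases(self):
        out = log2_pi_ratio(
            np.array([1.0, 2.0, 1.0, 0.0]), np.array([1.0, 1.0, 0.0, 0.0])
        )
        assert out[0] == 0.0
        assert out[1] == 1.0
        assert np.isposinf(out[2])  # focal diversity zero -> ranks at the top
        assert np.isnan(out[3])
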