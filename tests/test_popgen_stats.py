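"""Statistic correctness against independent brute-force oracles.

Every estimator is checked twice: frozen worked examples computed by hand,
and randomized comparisons against a second implementation that takes a
different computational route (raw-data ANOVA for F_ST, all-pairs identity
counting for EHH, direct haplotype enumeration for the H statistics).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscape.io_formats import HaplotypeMatrix
from sweepscape.popgen_stats import (
    HStats,
    ehh_curve,
    fst_wc_from_counts,
    global_fst_wc,
    h_statistics,
    ld_r2_decay,
    pair_r2,
    site_fst_wc,
    xpehh_scan,
)


def random_hm(rng, n_per_pop=8, n_sites=12, pops=("P1", "P2")):
    h = n_per_pop * len(pops)
    alleles = rng.integers(0, 2, size=(h, n_sites)).astype(np.uint8)
    # keep every site polymorphic so nothing degenerates silently
    for j in range(n_sites):
        if alleles[:, j].sum() in (0, h):
            alleles[rng.integers(h), j] ^= 1
    return HaplotypeMatrix(
        chrom="c",
        positions=np.arange(1, n_sites + 1) * 97,
        alleles=alleles,
        sample_ids=[f"s{i//2}" for i in range(h)],
        pop_of_haplotype=np.array(
            [p for p in pops for _ in range(n_per_pop)], dtype=object
        ),
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def anova_oracle(groups):
    """F_ST from raw 0/1 observations via literal one-way ANOVA sums."""
    r = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([np.mean(g) for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((np.asarray(g) - m) ** 2).sum()
                    for g, m in zip(groups, means)))
    msp = ssb / (r - 1)
    msg = ssw / (ns.sum() - r)
    n_c = (ns.sum() - (ns ** 2).sum() / ns.sum()) / (r - 1)
    denom = msp + (n_c - 1) * msg
    return (msp - msg) / denom if denom else float("nan")


class TestFst:
    def test_fixed_difference_is_one(self):
        assert fst_wc_from_counts([10, 10], [1.0, 0.0]) == pytest.approx(1.0)

    def test_equal_frequencies_nonpositive(self):
        for p in (0.1, 0.5, 0.9):
            assert fst_wc_from_counts([12, 30], [p, p]) <= 0.0

    def test_hand_computed_anova_value(self):
        # n=10 haplotypes each, p=0.8 vs 0.2:
        # MSP=1.8, MSG=3.2/18=8/45, n_c=10 -> theta = (1.8-8/45)/3.4 = 73/153
        theta = fst_wc_from_counts([10, 10], [0.8, 0.2])
        assert theta == pytest.approx(73 / 153, abs=1e-12)
        assert theta == pytest.approx(0.477, abs=5e-4)

    def test_monomorphic_pooled_is_nan_not_zero(self):
        assert np.isnan(fst_wc_from_counts([10, 10], [0.0, 0.0]))
        assert np.isnan(fst_wc_from_counts([10, 10], [1.0, 1.0]))

    def test_matches_raw_data_anova_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            na, nb = rng.integers(2, 40, size=2)
            ka = rng.integers(0, na + 1)
            kb = rng.integers(0, nb + 1)
            ga = np.r_[np.ones(ka), np.zeros(na - ka)]
            gb = np.r_[np.ones(kb), np.zeros(nb - kb)]
            mine = fst_wc_from_counts([na, nb], [ka / na, kb / nb])
            ref = anova_oracle([ga, gb])
            if np.isnan(ref):
                assert np.isnan(mine)
            else:
                assert mine == pytest.approx(ref, abs=1e-12)

    def test_site_values_and_symmetry(self, tiny_hm):
        v12 = site_fst_wc(tiny_hm, "P1", "P2")
        v21 = site_fst_wc(tiny_hm, "P2", "P1")
        assert np.allclose(v12, v21, equal_nan=True)
        a = tiny_hm.submatrix("P1")
        b = tiny_hm.submatrix("P2")
        for j in range(tiny_hm.n_sites):
            ref = anova_oracle([a[:, j].astype(float), b[:, j].astype(float)])
            assert v12[j] == pytest.approx(ref, abs=1e-12)

    def test_absent_population_is_hard_error(self, tiny_hm):
        with pytest.raises(KeyError):
            site_fst_wc(tiny_hm, "P1", "NOPE")

    def test_global_estimator_tracks_site_values(self, tiny_hm):
        g = global_fst_wc(tiny_hm, "P1", "P2")
        per_site = site_fst_wc(tiny_hm, "P1", "P2")
        ok = per_site[np.isfinite(per_site)]
        assert ok.min() - 1e-9 <= g <= ok.max() + 1e-9


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------

def ehh_pairs_oracle(alleles, core, j):
    """Fraction of pairs identical at every site between core and j,
    excluding the core itself (EHH(0) := 1)."""
    lo, hi = (core + 1, j + 1) if j > core else (j, core)
    span = alleles[:, lo:hi]
    n = alleles.shape[0]
    total = n * (n - 1) / 2
    same = sum(
        np.array_equal(span[a], span[b])
        for a in range(n) for b in range(a + 1, n)
    )
    return same / total


class TestEhh:
    def test_identical_carriers_stay_at_one(self):
        alleles = np.tile(np.array([0, 1, 0, 1, 1], dtype=np.uint8), (6, 1))
        hm = HaplotypeMatrix(
            "c", np.array([10, 20, 30, 40, 50]), alleles,
            [f"s{i//2}" for i in range(6)],
            np.array(["X"] * 6, dtype=object),
        )
        curve = ehh_curve(hm, 2, "all", max_distance=100)
        assert np.allclose(curve.values, 1.0)

    def test_partition_2_1_1_gives_one_sixth(self):
        # 4 carriers of allele 1 at the core; over the two flanking sites
        # they split into classes {2, 1, 1} -> EHH = C(2,2)/C(4,2) = 1/6
        alleles = np.array([
            [1, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [1, 0, 1],
            [0, 0, 0],
            [0, 1, 1],
        ], dtype=np.uint8)
        hm = HaplotypeMatrix(
            "c", np.array([10, 20, 30]), alleles,
            [f"s{i//2}" for i in range(6)],
            np.array(["X"] * 6, dtype=object),
        )
        curve = ehh_curve(hm, 0, 1, max_distance=100)
        # at the farthest site the 4 carriers partition {2,1,1}
        assert curve.values[-1] == pytest.approx(1 / 6)

    def test_matches_all_pairs_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            hm = random_hm(rng, n_per_pop=6, n_sites=10)
            core = int(rng.integers(hm.n_sites))
            curve = ehh_curve(hm, core, "all", max_distance=10_000)
            for d, v in zip(curve.distances, curve.values):
                j = int(np.searchsorted(hm.positions,
                                        hm.positions[core] + d))
                ref = 1.0 if d == 0 else ehh_pairs_oracle(hm.alleles, core, j)
                assert v == pytest.approx(ref, abs=1e-12)

    def test_monotone_and_ihh_monotone_in_distance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            hm = random_hm(rng, n_per_pop=8, n_sites=15)
            curve = ehh_curve(hm, 7, "all", max_distance=10_000)
            for sign in (-1, 1):
                _, v = curve.side(sign)
                assert np.all(np.diff(v) <= 1e-12)
            short = ehh_curve(hm, 7, "all", max_distance=300).ihh()
            long = ehh_curve(hm, 7, "all", max_distance=10_000).ihh()
            assert 0 <= short <= long + 1e-12

    def test_fewer_than_two_carriers_is_undefined(self):
        alleles = np.zeros((4, 3), dtype=np.uint8)
        alleles[0, 1] = 1
        alleles[0, 0] = 1
        alleles[1, 2] = 1
        hm = HaplotypeMatrix(
            "c", np.array([1, 2, 3]), alleles,
            ["a", "a", "b", "b"], np.array(["X"] * 4, dtype=object),
        )
        curve = ehh_curve(hm, 1, 1, max_distance=10)
        assert curve.n_carriers == 1
        assert np.isnan(curve.values).all()


class TestXpehh:
    def test_identical_populations_score_zero(self):
        rng = np.random.default_rng(3)
        block = rng.integers(0, 2, size=(8, 10)).astype(np.uint8)
        block[:, block.sum(0) == 0] ^= 1
        alleles = np.vstack([block, block])
        hm = HaplotypeMatrix(
            "c", np.arange(1, 11) * 50, alleles,
            [f"s{i//2}" for i in range(16)],
            np.array(["A"] * 8 + ["B"] * 8, dtype=object),
        )
        tr = xpehh_scan(hm, "A", "B", standardize=False)
        assert np.allclose(tr.scores, 0.0, atol=1e-12)

    def test_swapping_populations_flips_sign(self):
        rng = np.random.default_rng(4)
        hm = random_hm(rng, n_per_pop=8, n_sites=12)
        ab = xpehh_scan(hm, "P1", "P2", standardize=False)
        ba = xpehh_scan(hm, "P2", "P1", standardize=False)
        assert np.array_equal(ab.positions, ba.positions)
        assert np.allclose(ab.scores, -ba.scores, atol=1e-12)

    def test_empty_site_set_is_error(self, tiny_hm):
        with pytest.raises(ValueError, match="empty"):
            xpehh_scan(tiny_hm, "P1", "P2", sites=[])

    def test_sweep_elevates_scores_inside_swept_interval(self, sweep_ensemble):
        """Across the sweep replicates, standardized XP-EHH (swept pop vs
        reference) is higher near the selected site than away from it."""
        inside, outside = [], []
        for hm in sweep_ensemble[:20]:
            pos = hm.provenance["selected_position"]
            tr = xpehh_scan(hm, "AFR", "EUR", standardize=True)
            near = np.abs(tr.positions - pos) <= 10_000
            if near.any() and (~near).any():
                inside.append(tr.scores[near].mean())
                outside.append(tr.scores[~near].mean())
        assert np.mean(inside) > np.mean(outside)


# ---------------------------------------------------------------------------
# H statistics
# ---------------------------------------------------------------------------

def h_oracle(rows):
    """Direct enumeration of haplotype classes from row tuples."""
    counts = {}
    for row in map(tuple, rows):
        counts[row] = counts.get(row, 0) + 1
    p = sorted((c / len(rows) for c in counts.values()), reverse=True)
    h1 = sum(x * x for x in p)
    h12 = h1 if len(p) < 2 else (p[0] + p[1]) ** 2 + sum(x * x for x in p[2:])
    return h1, h1 - p[0] ** 2, h12


class TestHStatistics:
    def test_single_shared_haplotype(self):
        h = HStats.from_frequencies([1.0])
        assert (h.h1, h.h2, h.h12) == (1.0, 0.0, 1.0)

    def test_two_equal_haplotypes(self):
        h = HStats.from_frequencies([0.5, 0.5])
        assert h.h1 == pytest.approx(0.5)
        assert h.h12 == pytest.approx(1.0)
        assert h.h2 == pytest.approx(0.25)
        assert h.ratio == pytest.approx(0.5)

    def test_three_class_spectrum(self):
        h = HStats.from_frequencies([0.5, 0.25, 0.25])
        assert h.h1 == pytest.approx(0.375)
        assert h.h12 == pytest.approx(0.625)
        assert h.ratio == pytest.approx(1 / 3)

    def test_window_statistics_match_enumeration(self, tiny_hm):
        for start, stop in [(0, 3), (1, 6), (0, 6)]:
            for pop in ("P1", "P2"):
                h = h_statistics(tiny_hm, (start, stop), pop)
                rows = tiny_hm.submatrix(pop)[:, start:stop]
                ref = h_oracle(rows)
                assert (h.h1, h.h2, h.h12) == pytest.approx(ref, abs=1e-12)

    def test_tie_breaking_does_not_change_h12_or_ratio(self):
        base = HStats.from_frequencies([0.4, 0.4, 0.2])
        perm = HStats.from_frequencies([0.2, 0.4, 0.4])
        assert base.h12 == pytest.approx(perm.h12)
        assert base.ratio == pytest.approx(perm.ratio)

    def test_ratio_rises_as_sweep_softens(self):
        hard = HStats.from_frequencies([0.7, 0.1, 0.1, 0.1])
        soft = HStats.from_frequencies([0.4, 0.4, 0.1, 0.1])
        assert soft.ratio > hard.ratio

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 20), min_size=1, max_size=8))
    def test_invariants_hold_for_any_spectrum(self, counts):
        total = sum(counts)
        h = HStats.from_frequencies([c / total for c in counts])
        assert 0 < h.h1 <= 1.0 + 1e-12
        assert h.h12 >= h.h1 - 1e-12
        assert 0 <= h.ratio < 1


# ---------------------------------------------------------------------------
# r^2 / LD decay
# ---------------------------------------------------------------------------

class TestLd:
    def test_duplicated_site_is_perfectly_linked(self):
        x = np.array([0, 0, 1, 1, 0, 1, 1, 0])
        assert pair_r2(x, x.copy()) == pytest.approx(1.0)

    def test_hand_computed_contingency_example(self):
        # pA=pB=0.5, pAB=3/8: D=0.125 -> r2 = 0.125^2 / 0.0625 = 0.25
        x = np.array([0, 0, 1, 1, 0, 1, 0, 1])
        y = np.array([0, 1, 1, 1, 0, 1, 0, 0])
        assert pair_r2(x, y) == pytest.approx(0.25)

    def test_shuffled_pairs_are_unlinked_on_average(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, size=400)
        vals = []
        for _ in range(100):
            y = rng.permutation(x)
            vals.append(pair_r2(x, y))
        assert np.mean(vals) < 0.05

    def test_decay_table_and_distance(self):
        rng = np.random.default_rng(6)
        # 60 iid sites: r^2 ~ 1/(n-1) everywhere, so the decay distance is
        # the first bin midpoint at any threshold above sampling noise
        alleles = rng.integers(0, 2, size=(40, 60)).astype(np.uint8)
        alleles[:, alleles.sum(0) == 0] ^= 1
        alleles[:, alleles.sum(0) == 40] ^= 1
        hm = HaplotypeMatrix(
            "c", np.arange(1, 61) * 100, alleles,
            [f"s{i//2}" for i in range(40)],
            np.array(["X"] * 20 + ["Y"] * 20, dtype=object),
        )
        rows, decay = ld_r2_decay(hm, "X", bin_edges=[0, 2000, 4000, 6000],
                                  threshold=0.1)
        assert len(rows) == 3
        assert decay == pytest.approx(1000)

    def test_monomorphic_pair_skipped(self):
        x = np.array([1, 1, 1, 1])
        y = np.array([0, 1, 0, 1])
        assert np.isnan(pair_r2(x, y))
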