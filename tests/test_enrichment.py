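"""Fisher-exact enrichment, Bonferroni handling and confounder checks."""

from math import comb

import numpy as np
import pytest

from sweepscape.catalog import GRFCatalog, GeneRecord
from sweepscape.enrichment import (
    DEPLETION,
    ENRICHMENT,
    NO_DIFFERENCE,
    P_FLOOR,
    class_enrichment,
    confounder_checks,
    fisher_enrichment,
)


def hypergeom_pmf(k, n_grf, n_non, n_draw):
    return comb(n_grf, k) * comb(n_non, n_draw - k) / comb(n_grf + n_non, n_draw)


def two_sided_enumeration(a, b, c, d):
    """Exact two-sided p: sum of tables at most as probable as observed."""
    n_grf, n_non, n_draw = a + b, c + d, a + c
    obs = hypergeom_pmf(a, n_grf, n_non, n_draw)
    lo = max(0, n_draw - n_non)
    hi = min(n_grf, n_draw)
    return sum(
        p for k in range(lo, hi + 1)
        if (p := hypergeom_pmf(k, n_grf, n_non, n_draw)) <= obs * (1 + 1e-12)
    )


def make_universe(n_grf, n_non):
    universe = {f"R{i}" for i in range(n_grf)} | {f"N{i}" for i in range(n_non)}
    flags = {g: g.startswith("R") for g in universe}
    return universe, flags


class TestFisherEnrichment:
    def test_floor_times_family_reproduces_minimum_adjusted_p(self):
        # an overwhelmingly enriched table bottoms out at the 2.2e-16 floor;
        # Bonferroni with the 18-test family gives 3.96e-15
        universe, flags = make_universe(400, 1700)
        candidates = {f"R{i}" for i in range(300)} | {f"N{i}" for i in range(100)}
        row = fisher_enrichment(candidates, universe, flags, family_size=18)
        assert row.p_raw == P_FLOOR
        assert row.p_adjusted == pytest.approx(3.96e-15, rel=1e-6)
        assert row.verdict == ENRICHMENT

    def test_exact_p_matches_hypergeometric_enumeration(self):
        universe, flags = make_universe(8, 12)
        candidates = {f"R{i}" for i in range(4)} | {"N0"}
        row = fisher_enrichment(candidates, universe, flags, family_size=1)
        a, b, c, d = row.table
        assert (a, b, c, d) == (4, 4, 1, 11)
        assert row.p_raw == pytest.approx(two_sided_enumeration(4, 4, 1, 11),
                                          rel=1e-9)
        # the upper-tail probability of the same table is 896/15504
        tail = sum(hypergeom_pmf(k, 8, 12, 5) for k in range(4, 6))
        assert tail == pytest.approx(896 / 15504, rel=1e-12)
        assert row.odds_ratio == pytest.approx(11.0)

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            n_grf = int(rng.integers(2, 15))
            n_non = int(rng.integers(2, 15))
            universe, flags = make_universe(n_grf, n_non)
            k = int(rng.integers(1, n_grf + n_non))
            candidates = set(rng.choice(sorted(universe), size=k, replace=False))
            row = fisher_enrichment(candidates, universe, flags, family_size=1)
            assert row.p_raw == pytest.approx(
                max(P_FLOOR, two_sided_enumeration(*row.table)), rel=1e-9
            )

    def test_odds_ratio_inverts_under_group_swap(self):
        universe, flags = make_universe(30, 50)
        rng = np.random.default_rng(14)
        candidates = set(rng.choice(sorted(universe), size=20, replace=False))
        row = fisher_enrichment(candidates, universe, flags, family_size=1)
        inverted = fisher_enrichment(
            candidates, universe, {g: not f for g, f in flags.items()},
            family_size=1,
        )
        assert row.p_raw == pytest.approx(inverted.p_raw, rel=1e-9)
        assert row.odds_ratio == pytest.approx(1.0 / inverted.odds_ratio)

    def test_uniform_candidates_rarely_flagged(self):
        """Type-I control: uniformly drawn candidate sets almost never earn
        an Enrichment/Depletion verdict at alpha 0.001."""
        universe, flags = make_universe(120, 280)
        ordered = sorted(universe)
        rng = np.random.default_rng(15)
        verdicts = []
        for _ in range(200):
            cand = set(rng.choice(ordered, size=40, replace=False))
            verdicts.append(
                fisher_enrichment(cand, universe, flags, family_size=1,
                                  alpha=0.001).verdict
            )
        assert np.mean([v == NO_DIFFERENCE for v in verdicts]) >= 0.95

    def test_verdict_boundaries(self):
        universe, flags = make_universe(100, 100)
        depleted = {f"N{i}" for i in range(60)}
        row = fisher_enrichment(depleted, universe, flags, family_size=1,
                                alpha=0.001)
        assert row.verdict == DEPLETION and row.odds_ratio < 1

    def test_empty_universe_and_bad_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fisher_enrichment(set(), set(), {}, family_size=1)
        with pytest.raises(ValueError, match="subset"):
            fisher_enrichment({"X"}, {"Y"}, {"Y": True}, family_size=1)


class TestClassEnrichment:
    def catalog(self, sizes):
        records = {}
        i = 0
        for cls, n in sizes.items():
            for _ in range(n):
                gid = f"G{i}"
                records[gid] = GeneRecord(gid, gid, is_grf=True, tf_class=cls,
                                          sources=frozenset({"x"}))
                i += 1
        return GRFCatalog(records=records)

    def test_concentrated_class_flagged(self):
        cat = self.catalog({"KRAB-ZNF": 40, "bHLH": 40, "Forkhead": 40})
        candidates = {g for g, r in cat.records.items()
                      if r.tf_class == "KRAB-ZNF"}
        rows = {r.label: r for r in class_enrichment(cat, candidates)}
        assert rows["KRAB-ZNF"].verdict == ENRICHMENT
        assert rows["bHLH"].verdict in (DEPLETION, NO_DIFFERENCE)

    def test_planted_class_recovered_across_seeds(self):
        cat = self.catalog({"K": 30, "L": 30, "M": 30, "N": 30})
        members_k = [g for g, r in cat.records.items() if r.tf_class == "K"]
        others = [g for g in cat.records if g not in members_k]
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            cand = set(rng.choice(members_k, size=20, replace=False))
            cand |= set(rng.choice(others, size=5, replace=False))
            rows = {r.label: r for r in class_enrichment(cat, cand)}
            hits += rows["K"].verdict == ENRICHMENT
        assert hits == 20

    def test_class_without_members_omitted(self):
        cat = self.catalog({"K": 10})
        rows = class_enrichment(cat, set(), classes=["K", "GHOST"])
        assert [r.label for r in rows] == ["K"]


class TestConfounderChecks:
    def test_identical_distributions_give_zero_ks(self):
        # consecutive gene pairs share a rate, so the GRF (even-index) and
        # non-GRF (odd-index) rate distributions are identical
        rates = {f"G{i}": float((i // 2) % 10) for i in range(40)}
        flags = {f"G{i}": i % 2 == 0 for i in range(40)}
        lengths = {f"G{i}": 100.0 + i for i in range(40)}
        scores = {f"G{i}": float(i) for i in range(40)}
        out = confounder_checks(lengths, scores, rates, flags)
        assert out["ks_D"] == pytest.approx(0.0, abs=1e-12)

    def test_scores_equal_lengths_gives_rho_one(self):
        lengths = {f"G{i}": float(i + 1) for i in range(30)}
        flags = {f"G{i}": i < 15 for i in range(30)}
        rates = {f"G{i}": float(i % 7) for i in range(30)}
        out = confounder_checks(lengths, dict(lengths), rates, flags)
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_spearman_matches_average_rank_oracle(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        lengths = {f"G{i}": float(v) for i, v in enumerate(x)}
        scores = {f"G{i}": float(v) for i, v in enumerate(y)}
        flags = {f"G{i}": i % 2 == 0 for i in range(60)}
        rates = {f"G{i}": float(i) for i in range(60)}
        out = confounder_checks(lengths, scores, rates, flags)

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            ranks[order] = np.arange(1, len(v) + 1)
            return ranks  # no ties in gaussian draws

        rx, ry = avg_ranks(x), avg_ranks(y)
        rho = np.corrcoef(rx, ry)[0, 1]
        assert out["spearman_rho"] == pytest.approx(rho, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        lengths = {f"G{i}": 5.0 for i in range(20)}
        scores = {f"G{i}": float(i) for i in range(20)}
        flags = {f"G{i}": i % 2 == 0 for i in range(20)}
        rates = {f"G{i}": float(i) for i in range(20)}
        out = confounder_checks(lengths, scores, rates, flags)
        assert np.isnan(out["spearman_rho"])
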