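"""The forward Wright-Fisher generator against population-genetic theory.

Closed-form neutral expectations (Watterson's segregating-site count, the
1/i site-frequency spectrum), drift-divergence ordering, singleton
thinning arithmetic, sweep conditioning, determinism, and the on-disk
fixture bundle's ground-truth bookkeeping.
"""

import json

import numpy as np
import pytest
from scipy import stats

from sweepscape.io_formats import HaplotypeMatrix
from sweepscape.popgen_stats import global_fst_wc
from sweepscape.synthetic_data import (
    ClusterSpec,
    DemographyModel,
    FixtureConfig,
    SweepConfig,
    make_fixture_bundle,
    simulate_three_pop,
    thin_singletons,
)


def tiny_model(**kw):
    base = dict(
        n_ancestral=150, n_afr=80, n_eur=80, n_eas=80, n_ooa=80,
        t_split_afr=60, t_split_eurasn=30, burn_in=300,
        seed_diversity=False, mu=1e-6, r=1e-6,
    )
    base.update(kw)
    return DemographyModel(**base)


class TestNeutralExpectations:
    def test_watterson_segregating_sites(self, one_pop_reps):
        """Mean segregating-site count matches theta * a_{n-1} at
        equilibrium (theta = 4 N mu L = 6, pooled sample of 30)."""
        s_mean = np.mean([r.n_sites for r in one_pop_reps])
        n = one_pop_reps[0].n_haplotypes
        assert n == 30
        theta = 4 * 60 * 1e-6 * 25_000
        expected = theta * sum(1 / i for i in range(1, n))
        assert abs(s_mean / expected - 1) < 0.08

    def test_site_frequency_spectrum_close_to_neutral_shape(self, one_pop_reps):
        """Per-replicate chi-square against the 1/i spectrum (bins merged
        to expected >= 5) is not rejected at alpha = 0.01 in >= 95% of
        replicates; moderate recombination keeps sites quasi-independent,
        as the chi-square approximation requires."""
        rejections = 0
        tested = 0
        for rep in one_pop_reps:
            ac = rep.derived_counts()
            n = rep.n_haplotypes
            counts = np.bincount(ac, minlength=n)[1:n]
            weights = 1.0 / np.arange(1, n)
            expected = counts.sum() * weights / weights.sum()
            bins = []
            cur_o = cur_e = 0.0
            for o, e in zip(counts, expected):
                cur_o += o
                cur_e += e
                if cur_e >= 5:
                    bins.append((cur_o, cur_e))
                    cur_o = cur_e = 0.0
            if cur_e > 0 and bins:
                o, e = bins[-1]
                bins[-1] = (o + cur_o, e + cur_e)
            if len(bins) < 2:
                continue
            obs = np.array([b[0] for b in bins])
            exp = np.array([b[1] for b in bins])
            chi2 = float(((obs - exp) ** 2 / exp).sum())
            tested += 1
            rejections += stats.chi2.sf(chi2, len(bins) - 1) < 0.01
        assert tested > 150
        assert rejections / tested <= 0.05

    def test_longer_divergence_means_more_differentiation(self):
        """F_ST(AFR, EUR) ordered correctly between split times of
        0.05 * 2N and 0.5 * 2N generations in every paired replicate."""
        def model(t):
            return tiny_model(
                n_ancestral=100, n_afr=100, n_eur=100, n_eas=100, n_ooa=100,
                t_split_afr=t, t_split_eurasn=max(1, t // 2), burn_in=400,
            )
        correct = 0
        for s in range(20):
            short = simulate_three_pop(model(10), 20, 30_000, seed=700 + s)
            long = simulate_three_pop(model(100), 20, 30_000, seed=800 + s)
            correct += (global_fst_wc(long, "AFR", "EUR")
                        > global_fst_wc(short, "AFR", "EUR"))
        assert correct >= 19


class TestDeterminismAndContracts:
    def test_same_seed_gives_identical_output(self):
        a = simulate_three_pop(tiny_model(), 12, 10_000, seed=99)
        b = simulate_three_pop(tiny_model(), 12, 10_000, seed=99)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.positions, b.positions)
        c = simulate_three_pop(tiny_model(), 12, 10_000, seed=100)
        assert not (a.n_sites == c.n_sites
                    and np.array_equal(a.alleles, c.alleles))

    def test_missing_seed_is_an_error(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_three_pop(tiny_model(), 12, 10_000)

    def test_output_is_polymorphic_and_labelled(self):
        hm = simulate_three_pop(tiny_model(), 12, 10_000, seed=5)
        ac = hm.derived_counts()
        assert np.all((ac > 0) & (ac < hm.n_haplotypes))
        assert hm.populations == ["AFR", "EAS", "EUR"]
        assert np.all(np.diff(hm.positions) > 0)

    def test_sweep_conditioning_and_trajectory(self):
        sweep = SweepConfig(position_bp=5_000, s=0.3, target_pop="AFR",
                            onset=50, complete=False, target_frequency=0.6)
        hm = simulate_three_pop(tiny_model(), 12, 10_000, sweep=sweep, seed=21)
        prov = hm.provenance
        assert prov["sweep"]["target_pop"] == "AFR"
        final = prov["trajectory"][-1]
        assert final[0] == 0 and final[1] > 0
        assert max(f for _, f in prov["trajectory"]) >= 0.6

    def test_sweep_position_must_be_inside_sequence(self):
        sweep = SweepConfig(position_bp=50_000, s=0.1, target_pop="AFR")
        with pytest.raises(ValueError, match="inside"):
            simulate_three_pop(tiny_model(), 12, 10_000, sweep=sweep, seed=1)


class TestSweepSignal:
    def test_sweeps_raise_h12_over_neutral_mean(self, neutral_ensemble,
                                                sweep_ensemble):
        from conftest import h12_profile
        sweep_h12 = [float(h12_profile(hm, "AFR").max())
                     for hm in sweep_ensemble]
        null_h12 = [d["h12:AFR"] for d in neutral_ensemble]
        assert np.mean(sweep_h12) > np.mean(null_h12)


class TestThinSingletons:
    def build(self, n_singletons=100, n_other=20):
        h = 10
        cols = []
        for i in range(n_singletons):
            col = np.zeros(h, dtype=np.uint8)
            col[i % h] = 1
            cols.append(col)
        for i in range(n_other):
            col = np.zeros(h, dtype=np.uint8)
            col[: 2 + (i % 3)] = 1
            cols.append(col)
        alleles = np.stack(cols, axis=1)
        return HaplotypeMatrix(
            "c", np.arange(1, alleles.shape[1] + 1) * 10, alleles,
            [f"s{i//2}" for i in range(h)],
            np.array(["X"] * 5 + ["Y"] * 5, dtype=object),
        )

    def singleton_count(self, hm):
        ac = hm.derived_counts()
        return int((np.minimum(ac, hm.n_haplotypes - ac) == 1).sum())

    def test_48_percent_of_100_singletons_leaves_52(self):
        hm = self.build()
        thinned = thin_singletons(hm, 0.48, seed=1)
        assert self.singleton_count(thinned) == 52
        assert thinned.n_sites == hm.n_sites - 48

    def test_zero_fraction_is_identity(self):
        hm = self.build()
        out = thin_singletons(hm, 0.0, seed=1)
        assert np.array_equal(out.alleles, hm.alleles)

    def test_full_fraction_removes_all_singletons_only(self):
        hm = self.build()
        out = thin_singletons(hm, 1.0, seed=1)
        assert self.singleton_count(out) == 0
        assert out.n_sites == 20  # every non-singleton site intact

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            thin_singletons(self.build(), 1.2, seed=1)


class TestFixtureBundle:
    def small_config(self, with_sweep=False):
        sweep = SweepConfig(position_bp=5_000, s=0.3, target_pop="AFR",
                            onset=50, complete=False, target_frequency=0.6)
        return FixtureConfig(
            clusters=[ClusterSpec("c0", length=10_000, n_genes=2,
                                  sweep=sweep if with_sweep else None)],
            model=tiny_model(),
            n_haplotypes=16,
            n_background_blocks=2,
            block_length=10_000,
            block_genes=3,
            n_background_genes=4,
            gene_length=1_500,
        )

    def test_minimal_bundle_files_and_empty_sweep_list(self, tmp_path):
        manifest = make_fixture_bundle(self.small_config(), seed=3,
                                       outdir=tmp_path)
        assert len(manifest["files"]) >= 7
        for path in manifest["files"].values():
            assert (tmp_path / path.split("/")[-1]).exists()
        assert manifest["sweeps"] == []
        assert manifest["planted_candidate_genes"] == []

    def test_planted_sweep_interval_inside_a_cluster(self, tmp_path):
        manifest = make_fixture_bundle(self.small_config(with_sweep=True),
                                       seed=4, outdir=tmp_path)
        assert len(manifest["sweeps"]) == 1
        sw = manifest["sweeps"][0]
        cluster = next(c for c in manifest["clusters"]
                       if c["name"] == sw["cluster"])
        assert cluster["interval"][0] <= sw["position"] <= cluster["interval"][1]
        assert manifest["planted_candidate_genes"]

    def test_manifest_is_valid_json_on_disk(self, tmp_path):
        manifest = make_fixture_bundle(self.small_config(), seed=5,
                                       outdir=tmp_path)
        on_disk = json.loads((tmp_path / "manifest.json").read_text())
        assert on_disk["chrom"] == manifest["chrom"]
        assert on_disk["model"]["n_afr"] == 80
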