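"""Shared fixtures: desk-scale simulation ensembles and the on-disk bundle.

The expensive session fixtures (neutral null ensemble, sweep replicates,
fixture bundle, single-population equilibrium replicates) are built once
and shared across test modules; every one is fully seeded, so the whole
suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from sweepscape.io_formats import HaplotypeMatrix
from sweepscape.popgen_stats import h_statistics
from sweepscape.synthetic_data import (
    DemographyModel,
    FixtureConfig,
    SweepConfig,
    make_fixture_bundle,
    simulate_one_pop,
    simulate_three_pop,
    thin_singletons,
)

# the desk-scale study conditions: region length, sample size, thinning,
# H12 window, and the number of neutral / sweep replicates
REGION_LENGTH = 50_000
N_HAPLOTYPES = 100
THIN_FRACTION = 0.48
H12_WINDOW = (40, 10)
N_NULL = 120
N_SWEEP = 25

SWEEP = SweepConfig(
    position_bp=REGION_LENGTH / 2, s=0.05, target_pop="AFR",
    onset=225, complete=True,
)


def h12_profile(hm: HaplotypeMatrix, pop: str,
                window: tuple[int, int] = H12_WINDOW) -> np.ndarray:
    """H12 over sliding windows, the region statistic used throughout."""
    size, step = window
    n = hm.n_sites
    if n == 0:
        return np.array([1.0])
    ws = min(size, n)
    return np.array([
        h_statistics(hm, (s, s + ws), pop).h12
        for s in range(0, max(1, n - ws + 1), step)
    ])


@pytest.fixture(scope="session")
def desk_model() -> DemographyModel:
    return DemographyModel()


@pytest.fixture(scope="session")
def neutral_ensemble(desk_model) -> list[dict]:
    """H12 region statistics of N_NULL neutral thinned replicates."""
    out = []
    for s in range(N_NULL):
        hm = simulate_three_pop(
            desk_model, N_HAPLOTYPES, REGION_LENGTH, seed=50_000 + s
        )
        hm = thin_singletons(hm, THIN_FRACTION, seed=s)
        out.append({
            f"h12:{pop}": float(h12_profile(hm, pop).max())
            for pop in ("AFR", "EUR", "EAS")
        })
    return out


@pytest.fixture(scope="session")
def sweep_ensemble(desk_model) -> list[HaplotypeMatrix]:
    """N_SWEEP completed-hard-sweep replicates (selection in AFR)."""
    out = []
    for s in range(N_SWEEP):
        hm = simulate_three_pop(
            desk_model, N_HAPLOTYPES, REGION_LENGTH, sweep=SWEEP,
            seed=90_000 + s,
        )
        out.append(thin_singletons(hm, THIN_FRACTION, seed=s))
    return out


@pytest.fixture(scope="session")
def one_pop_reps() -> list[HaplotypeMatrix]:
    """200 equilibrium single-population replicates (theta = 6, rho = 12).

    Used for the Watterson and site-frequency-spectrum checks; moderate
    recombination makes sites quasi-independent so the chi-square
    goodness-of-fit test is approximately valid.
    """
    reps = []
    for s in range(200):
        reps.append(simulate_one_pop(
            n_diploids=60, length=25_000, mu=1e-6, r=2e-6,
            generations=600, n_sample=10, seed=30_000 + s,
        ))
    return reps


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The default on-disk bundle plus its manifest."""
    outdir = tmp_path_factory.mktemp("bundle")
    manifest = make_fixture_bundle(FixtureConfig(), seed=11, outdir=outdir)
    return {"dir": outdir, "manifest": manifest}


@pytest.fixture(scope="session")
def pipeline_result(fixture_bundle, neutral_ensemble, tmp_path_factory):
    """One full pipeline run on the default bundle, reusing the session
    null ensemble; shared by the pipeline and acceptance tests."""
    from sweepscape.config import AnalysisConfig
    from sweepscape.pipeline import run_full_pipeline

    outdir = tmp_path_factory.mktemp("pipeline_out")
    cfg = AnalysisConfig(
        seed=7, n_perm=300, n_sim=len(neutral_ensemble),
        h12_window=H12_WINDOW, min_ehh_span=20_000,
    )
    cache = {REGION_LENGTH: neutral_ensemble}
    result = run_full_pipeline(fixture_bundle["dir"], cfg, outdir,
                               null_cache=cache)
    return {"result": result, "outdir": outdir, "config": cfg}


@pytest.fixture()
def tiny_hm() -> HaplotypeMatrix:
    """A small handmade matrix: 8 haplotypes x 6 sites, two populations."""
    alleles = np.array([
        [0, 0, 1, 0, 1, 0],
        [0, 0, 1, 0, 1, 0],
        [0, 1, 1, 0, 0, 0],
        [0, 1, 0, 1, 0, 0],
        [1, 0, 0, 1, 0, 1],
        [1, 0, 0, 1, 0, 1],
        [1, 1, 0, 0, 0, 1],
        [1, 1, 1, 0, 0, 1],
    ], dtype=np.uint8)
    return HaplotypeMatrix(
        chrom="chrT",
        positions=np.array([100, 200, 350, 500, 720, 990]),
        alleles=alleles,
        sample_ids=["a", "a", "b", "b", "c", "c", "d", "d"],
        pop_of_haplotype=np.array(
            ["P1", "P1", "P1", "P1", "P2", "P2", "P2", "P2"], dtype=object
        ),
    )
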