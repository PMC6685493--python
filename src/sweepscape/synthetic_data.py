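"""Synthetic haplotype data with the structure the sweep scan assumes.

A forward-in-time Wright-Fisher diploid simulator with recombination and
infinite-sites mutation generates three diverged populations (an African-like
population and two out-of-Africa daughters, labelled AFR / EUR / EAS) from a
single ancestral population via two splits.  Optional positive selection on a
single site produces hard, soft, complete or incomplete sweeps.  Singleton
thinning mimics the deficit of rare alleles in low-coverage sequencing.
:func:`make_fixture_bundle` writes a coherent on-disk bundle (VCF, BED,
score tracks, genetic map, gene catalog, ZNF protein/CDS, coding variants,
manifest) so that every pipeline stage can be exercised without external
data.

The simulator is run at desk scale (rescaled population size, default
N = 500 diploids per population) rather than at human parameters; split
times are chosen so that the Weir-Cockerham F_ST between the two derived
populations lands in the 0.1-0.2 working range under neutrality.  Seeds are
mandatory everywhere: a run without a seed raises instead of drawing silent
randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .io_formats import (
    GenomicInterval,
    GeneticMap,
    HaplotypeMatrix,
    ScoreTrack,
    write_genetic_map,
    write_haplotypes_vcf,
    write_intervals_bed,
    write_score_track,
)

POP_LABELS = ("AFR", "EUR", "EAS")


@dataclass
class DemographyModel:
    """Two-split, three-population demography (sizes in diploids).

    The ancestral population splits ``t_split_afr`` generations before
    present into an African-like population and an out-of-Africa branch;
    that branch splits again ``t_split_eurasn`` generations before present
    into the two derived populations.  ``burn_in`` generations of neutral
    evolution precede the first split (default ``8 * n_ancestral``) so the
    ancestral population is near mutation-drift equilibrium.
    """

    n_ancestral: int = 2000  # large, diverse pre-bottleneck pool
    n_afr: int = 500
    n_eur: int = 500
    n_eas: int = 500
    n_ooa: int = 500  # out-of-Africa branch between the two splits
    t_split_afr: int = 350
    t_split_eurasn: int = 200
    migration: float = 0.0  # per-gamete probability of a migrant parent
    mu: float = 1e-7  # mutations per bp per generation
    r: float = 0.5e-7  # crossovers per bp per generation
    burn_in: Optional[int] = None
    # start the ancestral population from an equilibrium site-frequency
    # spectrum (sites independent) and let the burn-in build linkage; much
    # cheaper than burning in from a monomorphic start
    seed_diversity: bool = True

    def __post_init__(self) -> None:
        for name in ("n_ancestral", "n_afr", "n_eur", "n_eas", "n_ooa"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.t_split_eurasn > self.t_split_afr:
            raise ValueError("t_split_afr (older) must be >= t_split_eurasn")
        if not (0.0 <= self.migration < 1.0):
            raise ValueError("migration must be in [0, 1)")

    @property
    def total_burn_in(self) -> int:
        if self.burn_in is not None:
            return self.burn_in
        # a seeded start needs only enough generations to build linkage;
        # a cold start must accumulate diversity from scratch
        return 2_000 if self.seed_diversity else 8 * self.n_ancestral


@dataclass
class SweepConfig:
    """A selective sweep on one site in one population.

    ``initial_frequency`` near 1/2N gives a hard sweep (single origin);
    larger values start from standing variation (soft).  ``complete`` sweeps
    are conditioned on fixation in the target population at sampling;
    incomplete sweeps turn selection off once ``target_frequency`` is
    reached and are conditioned on the allele surviving to sampling.
    """

    position_bp: float
    s: float
    target_pop: str = "EUR"
    onset: int = 300  # generations before present
    initial_frequency: float = 0.0  # 0 -> 1/(2N) of the onset-time population
    complete: bool = True
    target_frequency: float = 0.9

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("selection coefficient s must be > 0")
        if not (0.0 <= self.initial_frequency < 1.0):
            raise ValueError("initial frequency must be in [0, 1)")
        if self.target_pop not in POP_LABELS:
            raise ValueError(f"target_pop must be one of {POP_LABELS}")


class SweepLostError(RuntimeError):
    """Raised when the selected allele is lost in every retry."""


# ---------------------------------------------------------------------------
# Wright-Fisher engine
# ---------------------------------------------------------------------------

class _State:
    """Live populations sharing one global site table (unsorted columns)."""

    def __init__(self) -> None:
        self.positions = np.zeros(0, dtype=np.float64)
        self.sel_flag = np.zeros(0, dtype=bool)
        self.pops: dict[str, np.ndarray] = {}  # name -> (2N, C) uint8

    def total_haplotypes(self) -> int:
        return sum(a.shape[0] for a in self.pops.values())

    def sel_col(self) -> int:
        idx = np.flatnonzero(self.sel_flag)
        return int(idx[0]) if idx.size else -1

    def sel_freq(self, pop: str) -> float:
        c = self.sel_col()
        if c < 0:
            return 0.0
        a = self.pops[pop]
        return float(a[:, c].sum()) / a.shape[0]


def _gametes(
    parent: np.ndarray,
    positions: np.ndarray,
    n: int,
    r_l: float,
    length: float,
    rng: np.random.Generator,
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Draw ``n`` recombinant gametes from a diploid parent pool."""
    n_dip = parent.shape[0] // 2
    if weights is None:
        pidx = rng.integers(n_dip, size=n)
    else:
        pidx = rng.choice(n_dip, size=n, p=weights)
    which = rng.integers(2, size=n)
    out = parent[2 * pidx + which]  # fancy indexing already copies
    n_x = rng.poisson(r_l, size=n)
    for i in np.flatnonzero(n_x):
        bp = np.sort(rng.uniform(0.0, length, n_x[i]))
        take_other = (np.searchsorted(bp, positions) & 1).astype(bool)
        other = parent[2 * pidx[i] + 1 - which[i]]
        out[i, take_other] = other[take_other]
    return out


def _selection_weights(alleles: np.ndarray, col: int, s: float) -> np.ndarray:
    copies = alleles[0::2, col].astype(np.float64) + alleles[1::2, col]
    w = (1.0 + s) ** copies
    return w / w.sum()


def _step(
    state: _State,
    sizes: dict[str, int],
    length: float,
    mu: float,
    r: float,
    migration: float,
    rng: np.random.Generator,
    sel_pop: Optional[str] = None,
    s: float = 0.0,
    prune: bool = True,
) -> None:
    """Advance every live population by one non-overlapping generation."""
    names = list(state.pops)
    mu_l = mu * length
    r_l = r * length
    weights = {}
    if sel_pop is not None and s > 0.0 and state.sel_col() >= 0:
        weights[sel_pop] = _selection_weights(
            state.pops[sel_pop], state.sel_col(), s
        )
    new_pops: dict[str, np.ndarray] = {}
    for name in names:
        n_hap = 2 * sizes[name]
        if migration > 0.0 and len(names) > 1:
            others = [o for o in names if o != name]
            src = np.full(n_hap, -1)
            mig = rng.random(n_hap) < migration
            src[mig] = rng.integers(len(others), size=int(mig.sum()))
            parts = []
            order = np.concatenate(
                [np.flatnonzero(src == -1)]
                + [np.flatnonzero(src == k) for k in range(len(others))]
            )
            counts = [int((src == -1).sum())] + [
                int((src == k).sum()) for k in range(len(others))
            ]
            pools = [name] + others
            for pool, cnt in zip(pools, counts):
                if cnt:
                    parts.append(
                        _gametes(
                            state.pops[pool], state.positions, cnt, r_l,
                            length, rng, weights.get(pool),
                        )
                    )
            block = np.concatenate(parts, axis=0) if parts else np.zeros(
                (0, len(state.positions)), dtype=np.uint8
            )
            child = np.empty_like(block)
            child[order] = block
        else:
            child = _gametes(
                state.pops[name], state.positions, n_hap, r_l, length, rng,
                weights.get(name),
            )
        new_pops[name] = child
    state.pops = new_pops

    # new mutations: infinite sites, uniform positions, one carrier each
    blocks = []
    new_pos = []
    for name in names:
        n_hap = state.pops[name].shape[0]
        n_mut = rng.poisson(mu_l * n_hap)
        if n_mut:
            blocks.append((name, rng.integers(n_hap, size=n_mut)))
            new_pos.append(rng.uniform(0.0, length, n_mut))
    if blocks:
        n_new = sum(len(c) for _, c in blocks)
        offsets = {}
        off = 0
        for name, carriers in blocks:
            offsets[name] = (off, carriers)
            off += len(carriers)
        for name in names:
            n_hap = state.pops[name].shape[0]
            cols = np.zeros((n_hap, n_new), dtype=np.uint8)
            if name in offsets:
                o, carriers = offsets[name]
                cols[carriers, o + np.arange(len(carriers))] = 1
            state.pops[name] = np.concatenate([state.pops[name], cols], axis=1)
        state.positions = np.concatenate([state.positions] + new_pos)
        state.sel_flag = np.concatenate(
            [state.sel_flag, np.zeros(n_new, dtype=bool)]
        )

    # prune columns that are globally lost or globally fixed (done every few
    # generations: stale columns are harmless, column copies are not free)
    if not prune:
        return
    pooled = sum(a.sum(axis=0, dtype=np.int64) for a in state.pops.values())
    tot = state.total_haplotypes()
    keep = ((pooled > 0) & (pooled < tot)) | state.sel_flag
    if not keep.all():
        for name in names:
            state.pops[name] = state.pops[name][:, keep]
        state.positions = state.positions[keep]
        state.sel_flag = state.sel_flag[keep]


def _split(state: _State, parent: str, daughters: dict[str, int],
           length: float, r: float, rng: np.random.Generator) -> None:
    """Replace ``parent`` by daughter populations, each founded by one
    Wright-Fisher generation drawn from the parent pool."""
    par = state.pops.pop(parent)
    r_l = r * length
    for name, n_dip in daughters.items():
        state.pops[name] = _gametes(par, state.positions, 2 * n_dip, r_l,
                                    length, rng)


def _seed_equilibrium_sfs(
    state: _State, model: DemographyModel, length: float,
    rng: np.random.Generator,
) -> None:
    """Fill the ancestral population with equilibrium-SFS standing variation.

    Site count ~ Poisson(theta * a_{2N-1}) with derived counts drawn from
    the neutral 1/i spectrum; carriers are assigned independently per site,
    so linkage starts at zero and is built by the subsequent burn-in."""
    n_hap = 2 * model.n_ancestral
    theta = 4 * model.n_ancestral * model.mu * length
    i = np.arange(1, n_hap)
    probs = (1.0 / i) / (1.0 / i).sum()
    n_sites = rng.poisson(theta * (1.0 / i).sum())
    counts = rng.choice(i, size=n_sites, p=probs)
    alleles = np.zeros((n_hap, n_sites), dtype=np.uint8)
    for j, c in enumerate(counts):
        alleles[rng.choice(n_hap, size=c, replace=False), j] = 1
    state.pops["ANC"] = alleles
    state.positions = rng.uniform(0.0, length, n_sites)
    state.sel_flag = np.zeros(n_sites, dtype=bool)


def _lineage_pop(target: str, t: int, model: DemographyModel) -> str:
    """Name of the live population containing ``target``'s ancestors at
    ``t`` generations before present."""
    if t > model.t_split_afr:
        return "ANC"
    if target == "AFR":
        return "AFR"
    if t > model.t_split_eurasn:
        return "OOA"
    return target


def _resolve_live(state: _State, pop: str) -> str:
    """Map a lineage name onto the population actually alive in ``state``
    (splits scheduled at this generation may not have executed yet)."""
    if pop in state.pops:
        return pop
    if pop in ("EUR", "EAS") and "OOA" in state.pops:
        return "OOA"
    if "ANC" in state.pops:
        return "ANC"
    raise KeyError(pop)


def _inject_sweep(state: _State, sweep: SweepConfig, pop: str,
                  rng: np.random.Generator) -> None:
    a = state.pops[pop]
    n_hap = a.shape[0]
    k = max(1, int(round(sweep.initial_frequency * n_hap)))
    carriers = rng.choice(n_hap, size=k, replace=False)
    for name in state.pops:
        h = state.pops[name].shape[0]
        col = np.zeros((h, 1), dtype=np.uint8)
        if name == pop:
            col[carriers, 0] = 1
        state.pops[name] = np.concatenate([state.pops[name], col], axis=1)
    state.positions = np.concatenate([state.positions, [sweep.position_bp]])
    state.sel_flag = np.concatenate([state.sel_flag, [True]])


def _finalize(
    state: _State,
    model: DemographyModel,
    n_haplotypes: int,
    length: float,
    chrom: str,
    rng: np.random.Generator,
) -> tuple[HaplotypeMatrix, Optional[int]]:
    """Sample n haplotypes per population and build the output matrix."""
    blocks = []
    pops = []
    used: dict[str, np.ndarray] = {}
    for label in POP_LABELS:
        src = _resolve_live(state, _lineage_pop(label, 0, model))
        # degenerate split times: several labels may share one live pool;
        # draw disjoint rows so sampled haplotypes are distinct individuals
        pool = state.pops[src]
        taken = used.setdefault(src, np.zeros(pool.shape[0], dtype=bool))
        avail = np.flatnonzero(~taken)
        if avail.size < n_haplotypes:
            raise ValueError(
                f"population {src} too small to sample {n_haplotypes} "
                "haplotypes per label"
            )
        rows = rng.choice(avail, size=n_haplotypes, replace=False)
        taken[rows] = True
        blocks.append(pool[np.sort(rows)])
        pops.extend([label] * n_haplotypes)
    alleles = np.concatenate(blocks, axis=0)

    order = np.argsort(state.positions, kind="stable")
    alleles = alleles[:, order]
    positions = state.positions[order]
    sel_flag = state.sel_flag[order]

    ac = alleles.sum(axis=0, dtype=np.int64)
    poly = (ac > 0) & (ac < alleles.shape[0])
    alleles = alleles[:, poly]
    positions = positions[poly]
    sel_flag = sel_flag[poly]

    # integer 1-based positions, strictly increasing
    pos_int = np.floor(positions).astype(np.int64) + 1
    for i in range(1, len(pos_int)):
        if pos_int[i] <= pos_int[i - 1]:
            pos_int[i] = pos_int[i - 1] + 1
    sel_pos = int(pos_int[np.flatnonzero(sel_flag)[0]]) if sel_flag.any() else None

    sample_ids = [
        f"{label}_{i // 2:04d}"
        for label in POP_LABELS
        for i in range(n_haplotypes)
    ]
    hm = HaplotypeMatrix(
        chrom=chrom,
        positions=pos_int,
        alleles=alleles,
        sample_ids=sample_ids,
        pop_of_haplotype=np.array(pops, dtype=object),
    )
    return hm, sel_pos


def simulate_three_pop(
    model: DemographyModel,
    n_haplotypes: int,
    length: float,
    sweep: Optional[SweepConfig] = None,
    seed: Optional[int] = None,
    chrom: str = "chrSim",
    max_retries: int = 200,
) -> HaplotypeMatrix:
    """Simulate three diverged populations; returns a pooled sample.

    ``n_haplotypes`` is the sample size per population (must be even so
    haplotypes pair into diploid samples).  Output is restricted to sites
    polymorphic in the pooled sample.  The returned matrix carries a
    ``provenance`` dict with the model, the sweep trajectory (frequency of
    the selected allele in the target lineage per generation) and the
    number of conditioning retries.

    Same seed, same arguments -> identical output.
    """
    if seed is None:
        raise ValueError("a seed is required; unseeded simulation is an error")
    if length < 1000:
        raise ValueError("sequence length must be >= 1 kb")
    if n_haplotypes % 2 or n_haplotypes < 4:
        raise ValueError("n_haplotypes per population must be even and >= 4")
    if sweep is not None and not (0 < sweep.position_bp < length):
        raise ValueError("sweep position must lie inside the sequence")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    t_start = model.total_burn_in + model.t_split_afr
    onset = sweep.onset if sweep is not None else -1
    if sweep is not None and onset >= t_start:
        raise ValueError("sweep onset predates the simulated timespan")

    state = _State()
    state.pops["ANC"] = np.zeros((2 * model.n_ancestral, 0), dtype=np.uint8)
    if model.seed_diversity:
        _seed_equilibrium_sfs(state, model, length, rng)

    def live_sizes(t: int) -> dict[str, int]:
        return {
            "ANC": model.n_ancestral, "OOA": model.n_ooa,
            "AFR": model.n_afr, "EUR": model.n_eur, "EAS": model.n_eas,
        }

    def advance(state: _State, t_from: int, t_to: int,
                rng: np.random.Generator, selecting: bool) -> None:
        """Evolve from t_from down to t_to generations before present."""
        sw = sweep if selecting else None
        reached = getattr(state, "_sweep_reached", False)
        for t in range(t_from, t_to, -1):
            if t == model.t_split_afr and "ANC" in state.pops:
                _split(state, "ANC", {"AFR": model.n_afr, "OOA": model.n_ooa},
                       length, model.r, rng)
                continue  # the split is this generation's reproduction
            if t == model.t_split_eurasn and "OOA" in state.pops:
                _split(state, "OOA", {"EUR": model.n_eur, "EAS": model.n_eas},
                       length, model.r, rng)
                continue
            sel_pop = None
            s_eff = 0.0
            if sw is not None and state.sel_col() >= 0:
                sel_pop = _resolve_live(state, _lineage_pop(sw.target_pop, t, model))
                s_eff = sw.s
                if not sw.complete:
                    freq = state.sel_freq(sel_pop)
                    if freq >= sw.target_frequency:
                        reached = True
                    if reached:
                        s_eff = 0.0
            _step(state, live_sizes(t), length, model.mu, model.r,
                  model.migration, rng, sel_pop, s_eff,
                  prune=(t % 8 == 0 or t <= 2))
            if sw is not None:
                pop = _resolve_live(
                    state, _lineage_pop(sw.target_pop, max(t - 1, 0), model)
                )
                freq = state.sel_freq(pop)
                state._trajectory.append((t - 1, freq))
                if freq == 0.0:
                    raise SweepLostError("selected allele lost")
        state._sweep_reached = reached

    def snapshot(state: _State) -> _State:
        s2 = _State()
        s2.positions = state.positions.copy()
        s2.sel_flag = state.sel_flag.copy()
        s2.pops = {k: v.copy() for k, v in state.pops.items()}
        s2._trajectory = list(state._trajectory)
        s2._sweep_reached = getattr(state, "_sweep_reached", False)
        return s2

    state._trajectory = []  # type: ignore[attr-defined]
    state._sweep_reached = False  # type: ignore[attr-defined]

    retries = 0
    if sweep is None:
        advance(state, t_start, 0, rng, selecting=False)
        final = state
    else:
        advance(state, t_start, onset, rng, selecting=False)
        base = state
        retry_streams = ss.spawn(max_retries + 1)[1:]
        final = None
        for attempt in range(max_retries):
            trial = snapshot(base)
            trial_rng = np.random.default_rng(retry_streams[attempt])
            pop = _resolve_live(trial, _lineage_pop(sweep.target_pop, onset, model))
            _inject_sweep(trial, sweep, pop, trial_rng)
            try:
                advance(trial, onset, 0, trial_rng, selecting=True)
            except SweepLostError:
                retries += 1
                continue
            end_pop = _resolve_live(
                trial, _lineage_pop(sweep.target_pop, 0, model)
            )
            freq = trial.sel_freq(end_pop)
            if sweep.complete and freq < 1.0:
                retries += 1
                continue
            if not sweep.complete and not trial._sweep_reached:
                retries += 1
                continue
            final = trial
            rng = trial_rng
            break
        if final is None:
            raise SweepLostError(
                f"sweep conditioning failed after {max_retries} retries"
            )

    hm, sel_pos = _finalize(final, model, n_haplotypes, length, chrom, rng)
    hm.provenance = {  # type: ignore[attr-defined]
        "seed": seed,
        "model": asdict(model),
        "sweep": asdict(sweep) if sweep is not None else None,
        "selected_position": sel_pos,
        "trajectory": list(final._trajectory),
        "retries": retries,
    }
    return hm


def simulate_one_pop(
    n_diploids: int,
    length: float,
    mu: float,
    r: float,
    generations: int,
    n_sample: int,
    seed: int,
    chrom: str = "chrSim",
) -> HaplotypeMatrix:
    """Single panmictic Wright-Fisher population (neutral), for calibration.

    Evolves ``generations`` generations from a monomorphic start, then
    samples ``n_sample`` haplotypes per population label (3 * n_sample in
    total) from the single pool; the labels are bookkeeping only since no
    split ever happens.
    """
    model = DemographyModel(
        n_ancestral=n_diploids, n_afr=n_diploids, n_eur=n_diploids,
        n_eas=n_diploids, n_ooa=n_diploids,
        t_split_afr=0, t_split_eurasn=0, mu=mu, r=r, burn_in=generations,
        seed_diversity=False,  # cold start: the caller controls equilibration
    )
    return simulate_three_pop(model, n_sample, length, seed=seed, chrom=chrom)


def thin_singletons(
    hm: HaplotypeMatrix, removed_fraction: float, seed: int
) -> HaplotypeMatrix:
    """Randomly delete a fraction of global singleton sites.

    A singleton is a site whose pooled minor-allele count is exactly 1.
    Exactly ``round(removed_fraction * n_singletons)`` singleton sites are
    removed, chosen uniformly by the seed; every other site is untouched.
    This mimics the deficit of rare variants in low-coverage sequencing.
    """
    if not (0.0 <= removed_fraction <= 1.0):
        raise ValueError("removed_fraction must be in [0, 1]")
    if seed is None:
        raise ValueError("a seed is required")
    ac = hm.derived_counts()
    minor = np.minimum(ac, hm.n_haplotypes - ac)
    singles = np.flatnonzero(minor == 1)
    n_remove = int(round(removed_fraction * len(singles)))
    rng = np.random.default_rng(seed)
    drop = rng.choice(singles, size=n_remove, replace=False)
    keep = np.ones(hm.n_sites, dtype=bool)
    keep[drop] = False
    return hm.restrict_sites(keep)


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

@dataclass
class ClusterSpec:
    """One simulated KRAB-ZNF-like cluster region."""

    name: str
    length: int = 50_000
    sweep: Optional[SweepConfig] = None
    n_genes: int = 4
    recomb_rate: float = 1.2  # cM/Mb in the genetic map
    h12_window: Optional[int] = None  # reserved for per-cluster overrides


@dataclass
class FixtureConfig:
    """Configuration for :func:`make_fixture_bundle`."""

    chrom: str = "chrS"
    clusters: list[ClusterSpec] = field(default_factory=lambda: [
        # AFR target: the sweep runs entirely inside one branch, so the
        # signal is population-exclusive; a completed hard sweep ending
        # near sampling time leaves the cleanest haplotype signature
        ClusterSpec("cluster_sweep", length=50_000, n_genes=3,
                    sweep=SweepConfig(position_bp=25_000.0, s=0.05,
                                      target_pop="AFR", onset=225,
                                      complete=True)),
        ClusterSpec("cluster_neutral_1", length=50_000),
        ClusterSpec("cluster_neutral_2", length=50_000),
    ])
    # bottleneck-shaped demography: a large, diverse ancestral population
    # (equilibrium-SFS seeded, burn-in builds linkage) and small derived
    # branches, mirroring the out-of-Africa size history; the same model
    # drives both the fixture data and the neutral null ensemble
    model: DemographyModel = field(default_factory=DemographyModel)
    n_haplotypes: int = 100  # per population
    n_background_blocks: int = 8  # neutral non-cluster blocks in the VCF
    block_length: int = 50_000
    block_genes: int = 14  # genes tiled inside each background block
    gap: int = 30_000  # between simulated blocks
    n_background_genes: int = 60
    gene_length: int = 6_000
    background_grf_fraction: float = 0.3
    score_boost: float = 6.0  # added to raw CLR/XP-CLR inside sweep intervals
    score_grid_step: int = 1_000
    base_map_rate: float = 1.2  # cM/Mb outside clusters
    n_znf_fingers: int = 7
    thin_fraction: float = 0.48

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureConfig":
        raw = json.loads(Path(path).read_text())
        clusters = [
            ClusterSpec(
                name=c["name"],
                length=c.get("length", 40_000),
                sweep=SweepConfig(**c["sweep"]) if c.get("sweep") else None,
                n_genes=c.get("n_genes", 4),
                recomb_rate=c.get("recomb_rate", 1.2),
            )
            for c in raw.pop("clusters", [])
        ]
        model = DemographyModel(**raw.pop("model", {}))
        cfg = cls(model=model, **raw)
        if clusters:
            cfg.clusters = clusters
        return cfg


# deterministic codon per amino acid; chosen so the classical examples hold:
# Cys=TGT (TGT->TAT gives C->Y), Thr=ACC (ACC->AAC gives T->N)
_CODON_OF_AA = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "AGC", "T": "ACC", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

_FINGER = "CPECGKAFSRSDHLTTHIRTH"  # C-x(2)-C-x(12)-H-x(3)-H
_LINKER = "TGEKP"
_KRAB = (
    "MDVAVYFSLEEWECLDTAQQNLYRNVMLENYRNLVSLGLAVSKPD"  # 45 aa KRAB-like box
)


def build_znf_protein(n_fingers: int) -> dict:
    """Synthetic KRAB-ZNF protein with known architecture.

    Layout: KRAB box, a 10-residue spacer, then ``n_fingers`` canonical
    C2H2 fingers joined by TGEKP linkers, then a 5-residue tail.  Returns
    the sequence, its reverse-translated CDS and the 1-based residue
    intervals of every feature (ground truth for the annotation tests).
    """
    seq = _KRAB + "GSGSGSGSGS"
    fingers = []
    linkers = []
    for i in range(n_fingers):
        start = len(seq) + 1
        seq += _FINGER
        fingers.append((start, len(seq)))
        if i < n_fingers - 1:
            lstart = len(seq) + 1
            seq += _LINKER
            linkers.append((lstart, len(seq)))
    seq += "GSSTV"
    cds = "".join(_CODON_OF_AA[a] for a in seq)
    return {
        "sequence": seq,
        "cds": cds,
        "krab": (1, len(_KRAB)),
        "fingers": fingers,
        "linkers": linkers,
    }


def _planted_znf_variants(arch: dict, n_hap: int) -> list[dict]:
    """Coding variants with constructed per-population frequencies.

    Frequencies echo the qualitative pattern of highly differentiated
    KRAB-ZNF variants (common in one population, rare elsewhere); their
    Weir-Cockerham F_ST is computed downstream, not stored here.
    """
    variants = []

    def codon_change(aa_pos: int, codon_offset: int, alt: str,
                     freqs: tuple, note: str) -> dict:
        cds_pos = 3 * (aa_pos - 1) + codon_offset  # 1-based cds position
        ref = arch["cds"][cds_pos - 1]
        return {
            "protein_id": "ZNFSYN1",
            "cds_pos": cds_pos,
            "ref": ref,
            "alt": alt,
            "freq_AFR": freqs[0], "freq_EUR": freqs[1], "freq_EAS": freqs[2],
            "n_AFR": n_hap, "n_EUR": n_hap, "n_EAS": n_hap,
            "note": note,
        }

    f_first = arch["fingers"][0]
    # first coordinating Cys of finger 1: TGT -> TAT (C->Y), high FST
    variants.append(codon_change(f_first[0], 2, "A", (0.55, 0.01, 0.01),
                                 "zinc_coordinating_high_fst"))
    # linker residue (first TGEKP, Gly ->  Asp GGT->GAT), high FST
    if arch["linkers"]:
        l0 = arch["linkers"][0]
        variants.append(codon_change(l0[0] + 1, 2, "A", (0.05, 0.70, 0.10),
                                     "linker_high_fst"))
    # KRAB residue change, high FST
    variants.append(codon_change(10, 1, "A", (0.02, 0.05, 0.60),
                                 "krab_high_fst"))
    # synonymous change with high FST (must be excluded from the report):
    # GCT -> GCA at a spacer Ala-like? spacer is GS repeat; use tail Ser AGC->AGT
    tail_ser = len(arch["sequence"]) - 2  # 'S' in the GSSTV tail
    variants.append(codon_change(tail_ser, 3, "T", (0.60, 0.02, 0.02),
                                 "synonymous_high_fst"))
    # nonsynonymous outside domains, low FST (excluded by threshold)
    variants.append(codon_change(len(_KRAB) + 1, 2, "A", (0.30, 0.28, 0.33),
                                 "outside_low_fst"))
    # nonsynonymous outside domains, high FST (kept, OUTSIDE_DOMAIN)
    variants.append(codon_change(len(_KRAB) + 3, 2, "A", (0.01, 0.65, 0.02),
                                 "outside_high_fst"))
    return variants


def make_fixture_bundle(
    config: FixtureConfig, seed: int, outdir: str | Path
) -> dict:
    """Write a coherent on-disk fixture bundle; returns the manifest.

    Files: haplotype VCF (clusters concatenated along one synthetic
    chromosome), gene and cluster BEDs, CLR and XP-CLR score-track TSVs per
    population (elevated inside planted sweep intervals), genetic map, GRF
    catalog TSV, ZNF protein FASTA + CDS FASTA, coding-variant TSV and a
    JSON manifest recording the ground truth.
    """
    if seed is None:
        raise ValueError("a seed is required")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # background blocks: neutral simulated segments outside any cluster,
    # giving the permutation tests a genome-like sampling universe
    blocks = list(config.clusters) + [
        ClusterSpec(f"background_{k}", length=config.block_length,
                    n_genes=config.block_genes)
        for k in range(config.n_background_blocks)
    ]
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(blocks) + 2)
    rng = np.random.default_rng(streams[-1])

    # --- lay simulated blocks along the chromosome, clusters first
    offset = config.gap
    cluster_ivs: list[GenomicInterval] = []
    block_ivs: list[GenomicInterval] = []
    sweep_truth = []
    mats = []
    for ci, cl in enumerate(blocks):
        iv = GenomicInterval(config.chrom, offset, offset + cl.length)
        block_ivs.append(iv)
        if ci < len(config.clusters):
            cluster_ivs.append(iv)
        if cl.sweep is not None:
            sw_abs = offset + cl.sweep.position_bp
            for prev in sweep_truth:
                if abs(prev["position"] - sw_abs) < cl.length:
                    raise ValueError("overlapping planted sweeps")
        hm = simulate_three_pop(
            config.model, config.n_haplotypes, cl.length, sweep=cl.sweep,
            seed=int(streams[ci].generate_state(1)[0] % (2 ** 31)),
            chrom=config.chrom,
        )
        hm = thin_singletons(
            hm, config.thin_fraction,
            seed=int(streams[ci].generate_state(2)[1] % (2 ** 31)),
        )
        shifted = HaplotypeMatrix(
            chrom=config.chrom,
            positions=hm.positions + offset,
            alleles=hm.alleles,
            sample_ids=hm.sample_ids,
            pop_of_haplotype=hm.pop_of_haplotype,
        )
        mats.append(shifted)
        if cl.sweep is not None:
            sel = hm.provenance["selected_position"]
            sweep_truth.append({
                "cluster": cl.name,
                "position": int(offset + (sel if sel else cl.sweep.position_bp)),
                "interval": [iv.start, iv.end],
                "target_pop": cl.sweep.target_pop,
                "s": cl.sweep.s,
            })
        offset += cl.length + config.gap

    chrom_len = offset + config.n_background_genes * (config.gene_length + 2_000) + config.gap

    # one matrix: same sampled individuals, unlinked blocks concatenated
    hm_all = HaplotypeMatrix(
        chrom=config.chrom,
        positions=np.concatenate([m.positions for m in mats]),
        alleles=np.concatenate([m.alleles for m in mats], axis=1),
        sample_ids=mats[0].sample_ids,
        pop_of_haplotype=mats[0].pop_of_haplotype,
    )

    # --- genes: tiled inside clusters, plus a background universe
    genes: list[tuple[GenomicInterval, str]] = []
    gene_rows = []
    gi = 0
    for bi, (iv, cl) in enumerate(zip(block_ivs, blocks)):
        in_cluster = bi < len(config.clusters)
        step = len(iv) // cl.n_genes
        for k in range(cl.n_genes):
            g_start = iv.start + k * step + step // 6
            g_end = min(g_start + max(step // 2, 1_000), iv.end)
            gid = f"G{gi:04d}"
            gi += 1
            is_grf = 1 if in_cluster else int(
                rng.random() < config.background_grf_fraction
            )
            genes.append((GenomicInterval(config.chrom, g_start, g_end), gid))
            gene_rows.append({
                "gene_id": gid,
                "symbol": (f"ZNFS{gi}" if in_cluster else f"BB{gi}"),
                "chrom": config.chrom,
                "start": g_start, "end": g_end, "is_grf": is_grf,
                "tf_class": ("KRAB-ZNF" if in_cluster
                             else ("Homeo domain" if is_grf else "unclassified")),
                "sources": ("synthetic_znf" if in_cluster
                            else ("synthetic_background" if is_grf else "")),
                "cluster": cl.name if in_cluster else "",
            })
    bg_start = offset
    for k in range(config.n_background_genes):
        g_start = bg_start + k * (config.gene_length + 2_000)
        g_end = g_start + config.gene_length
        gid = f"G{gi:04d}"
        gi += 1
        is_grf = int(rng.random() < config.background_grf_fraction)
        genes.append((GenomicInterval(config.chrom, g_start, g_end), gid))
        gene_rows.append({
            "gene_id": gid, "symbol": f"BG{gi}", "chrom": config.chrom,
            "start": g_start, "end": g_end, "is_grf": is_grf,
            "tf_class": "Homeo domain" if is_grf else "unclassified",
            "sources": "synthetic_background" if is_grf else "",
            "cluster": "",
        })

    planted_genes = [
        r["gene_id"] for r in gene_rows
        for sw in sweep_truth
        if r["cluster"] == sw["cluster"]
        and r["start"] < sw["interval"][1] and sw["interval"][0] < r["end"]
    ]

    # --- score tracks: exponential noise on a grid, boosted inside sweeps
    grid = np.arange(config.score_grid_step, chrom_len,
                     config.score_grid_step, dtype=np.int64)
    in_sweep = np.zeros(len(grid), dtype=bool)
    for sw in sweep_truth:
        a, b = sw["interval"]
        in_sweep |= (grid >= a) & (grid < b)
    track_paths = {}
    for stat, fname in (("CLR", "clr"), ("XP-CLR", "xpclr")):
        for pop in POP_LABELS:
            raw = rng.exponential(1.0, size=len(grid))
            boosted = [sw for sw in sweep_truth if sw["target_pop"] == pop]
            if boosted:
                mask = np.zeros(len(grid), dtype=bool)
                for sw in boosted:
                    a, b = sw["interval"]
                    mask |= (grid >= a) & (grid < b)
                raw[mask] += config.score_boost
            label = pop if stat == "CLR" else f"{pop}-REF"
            tr = ScoreTrack(stat, label, config.chrom, grid, raw)
            p = outdir / f"{fname}_{pop}.tsv"
            write_score_track(tr, p)
            track_paths[f"{stat}:{pop}"] = p.name  # relative: manifests are
            # byte-identical wherever the bundle is written

    # --- genetic map: per-cluster rates over a uniform background
    map_pos = [0]
    map_rate = [config.base_map_rate]
    for iv, cl in zip(cluster_ivs, config.clusters):
        map_pos.extend([iv.start, iv.end])
        map_rate.extend([cl.recomb_rate, config.base_map_rate])
    gmap = GeneticMap(config.chrom, np.array(map_pos), np.array(map_rate))

    # --- ZNF protein + planted coding variants
    arch = build_znf_protein(config.n_znf_fingers)
    variants = _planted_znf_variants(arch, config.n_haplotypes)

    # --- write everything
    paths = {
        "vcf": outdir / "haplotypes.vcf",
        "clusters_bed": outdir / "clusters.bed",
        "genes_bed": outdir / "genes.bed",
        "genetic_map": outdir / "genetic_map.tsv",
        "catalog": outdir / "grf_catalog.tsv",
        "protein_fasta": outdir / "znf_protein.fa",
        "cds_fasta": outdir / "znf_cds.fa",
        "variants": outdir / "znf_variants.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_haplotypes_vcf(hm_all, paths["vcf"])
    write_intervals_bed(
        [(iv, cl.name) for iv, cl in zip(cluster_ivs, config.clusters)],
        paths["clusters_bed"],
    )
    write_intervals_bed(genes, paths["genes_bed"])
    write_genetic_map(gmap, paths["genetic_map"])

    import pandas as pd
    pd.DataFrame(gene_rows).to_csv(paths["catalog"], sep="\t", index=False)
    with open(paths["protein_fasta"], "w") as fh:
        fh.write(">ZNFSYN1 synthetic KRAB-ZNF\n")
        fh.write(arch["sequence"] + "\n")
    with open(paths["cds_fasta"], "w") as fh:
        fh.write(">ZNFSYN1 synthetic KRAB-ZNF CDS\n")
        fh.write(arch["cds"] + "\n")
    pd.DataFrame(variants).to_csv(paths["variants"], sep="\t", index=False)

    manifest = {
        "seed": seed,
        "chrom": config.chrom,
        "chrom_length": int(chrom_len),
        "demography_note": (
            "synthetic stand-in demography at rescaled desk scale; "
            "not a fitted human model"
        ),
        "model": asdict(config.model),
        "n_haplotypes_per_pop": config.n_haplotypes,
        "clusters": [
            {"name": cl.name, "interval": [iv.start, iv.end],
             "sweep": asdict(cl.sweep) if cl.sweep else None}
            for iv, cl in zip(cluster_ivs, config.clusters)
        ],
        "blocks": [
            {"name": cl.name, "interval": [iv.start, iv.end],
             "is_cluster": k < len(config.clusters)}
            for k, (iv, cl) in enumerate(zip(block_ivs, blocks))
        ],
        "sweeps": sweep_truth,
        "planted_candidate_genes": sorted(set(planted_genes)),
        "znf_architecture": {
            "protein_id": "ZNFSYN1",
            "krab": list(arch["krab"]),
            "fingers": [list(f) for f in arch["fingers"]],
            "linkers": [list(l) for l in arch["linkers"]],
            "length": len(arch["sequence"]),
        },
        "planted_znf_variants": variants,
        "files": {k: v.name for k, v in paths.items()},
        "score_tracks": track_paths,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
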