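"""Cluster-level sweep evidence for KRAB-ZNF gene clusters.

Four lines of evidence are combined per cluster: (1) runs of consecutive
SNPs with significant XP-EHH rank scores, tested against same-length
regions sampled from the rest of the genome track; (2) a recombination
deficit test against same-length regions of the genetic map; (3) a
comparison against neutral coalescent-free simulations (the package's
forward Wright-Fisher generator with singleton thinning) of matched
length; and (4) an H12 scan delimiting regions with one or more
high-frequency haplotypes and extended haplotype homozygosity beyond a
minimum span.

All empirical p-values use the (1 + k) / (1 + N) convention: they are
never zero and their floor at N = 1000 permutations is just under 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .io_formats import GenomicInterval, GeneticMap, HaplotypeMatrix
from .popgen_stats import HStats, ehh_curve, h_statistics, xpehh_scan
from .rankscore_outliers import RankScoreTrack, rank_score_transform
from .synthetic_data import DemographyModel, simulate_three_pop, thin_singletons


@dataclass
class Run:
    """A maximal run of consecutive track points above threshold."""

    start_index: int
    end_index: int  # inclusive
    start_pos: int
    end_pos: int

    @property
    def count(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class CandidateRegion:
    """A delimited candidate interval with its evidence."""

    interval: GenomicInterval
    population: str
    run_length: int  # SNPs in the region
    ehh_span: float  # bp
    h_stats: HStats
    p_run_permutation: Optional[float] = None
    p_recombination: Optional[float] = None
    p_neutral_simulation: Optional[float] = None
    gene_ids: list[str] = field(default_factory=list)

    @property
    def softness(self) -> float:
        """H2/H1 at the peak window; larger values indicate softer sweeps."""
        return self.h_stats.ratio


def significant_runs(
    positions: np.ndarray | Sequence[int],
    scores: np.ndarray | Sequence[float],
    threshold: float,
    tolerance: int = 0,
) -> list[Run]:
    """Maximal runs of consecutive points with score > threshold.

    ``tolerance`` sub-threshold points may interrupt a run without breaking
    it (default 0: any sub-threshold SNP terminates the run, reading
    "uninterrupted" literally).
    """
    positions = np.asarray(positions)
    scores = np.asarray(scores, dtype=np.float64)
    runs: list[Run] = []
    start = None
    misses = 0
    last_hit = None
    for i, s in enumerate(scores):
        if s > threshold:
            if start is None:
                start = i
            last_hit = i
            misses = 0
        elif start is not None:
            misses += 1
            if misses > tolerance:
                runs.append(Run(start, last_hit,
                                int(positions[start]), int(positions[last_hit])))
                start = None
                misses = 0
    if start is not None:
        runs.append(Run(start, last_hit,
                        int(positions[start]), int(positions[last_hit])))
    return runs


def max_run_count(
    positions: np.ndarray, scores: np.ndarray, threshold: float
) -> int:
    runs = significant_runs(positions, scores, threshold)
    return max((r.count for r in runs), default=0)


def _sample_windows(
    intervals: Sequence[tuple[int, int]], length: int, n: int,
    exclude: Optional[GenomicInterval], rng: np.random.Generator,
) -> np.ndarray:
    """Uniform same-length window starts within a union of intervals,
    avoiding the focal region.  Intervals are chosen with probability
    proportional to the number of feasible starts they contain."""
    widths = np.array(
        [max(0, (b - a) - length + 1) for a, b in intervals], dtype=np.float64
    )
    if widths.sum() <= 0:
        raise ValueError("sampling universe shorter than the region")
    probs = widths / widths.sum()
    starts = np.empty(n, dtype=np.int64)
    got = 0
    guard = 0
    while got < n:
        guard += 1
        if guard > 1000:
            raise ValueError("focal region exclusion exhausted the universe")
        idx = rng.choice(len(intervals), size=n - got, p=probs)
        cand = np.array(
            [rng.integers(intervals[i][0],
                          intervals[i][1] - length + 1) for i in idx],
            dtype=np.int64,
        )
        if exclude is not None:
            ok = (cand + length <= exclude.start) | (cand >= exclude.end)
            cand = cand[ok]
        starts[got:got + len(cand)] = cand
        got += len(cand)
    return starts


def permutation_run_test(
    observed_run: int,
    track: RankScoreTrack,
    region_length: int,
    n_perm: int,
    seed: int,
    family_size: int = 1,
    threshold: float = 1.3,
    exclude: Optional[GenomicInterval] = None,
    universe: Optional[Sequence[tuple[int, int]]] = None,
) -> tuple[float, float]:
    """Empirical p for a run of significant rank scores.

    Samples ``n_perm`` same-length regions uniformly from the mappable
    universe (by default the track's whole extent; pass ``universe`` to
    restrict sampling to covered intervals), excluding the focal region,
    takes the maximum run count of points with rank score above
    ``threshold`` in each, and returns
    ``p = (1 + #samples >= observed) / (1 + n_perm)`` with its Bonferroni
    adjustment ``min(1, family_size * p)``.
    """
    if seed is None:
        raise ValueError("a seed is required")
    pos = track.positions
    if universe is None:
        universe = [(int(pos[0]), int(pos[-1]))]
    span = sum(b - a for a, b in universe)
    if span < 10 * region_length:
        raise ValueError("genome track must cover >= 10x the region length")
    rng = np.random.default_rng(seed)
    starts = _sample_windows(universe, region_length, n_perm, exclude, rng)
    k = 0
    for s in starts:
        a = np.searchsorted(pos, s, side="left")
        b = np.searchsorted(pos, s + region_length, side="right")
        if max_run_count(pos[a:b], track.rank_scores[a:b], threshold) >= observed_run:
            k += 1
    p = (1 + k) / (1 + n_perm)
    return p, min(1.0, family_size * p)


def recombination_deficit_test(
    region: GenomicInterval,
    gmap: GeneticMap,
    n_perm: int,
    seed: int,
    universe: Optional[tuple[int, int]] = None,
) -> float:
    """Is the region's mean recombination rate unusually low?

    Samples same-length regions from the map's extent and counts how often
    their length-weighted mean rate is <= the observed mean; small p means
    an unusually recombination-poor region.
    """
    if seed is None:
        raise ValueError("a seed is required")
    lo, hi = universe if universe is not None else (
        int(gmap.positions[0]), int(gmap.positions[-1]) + len(region)
    )
    length = len(region)
    observed = gmap.mean_rate(region.start, region.end)
    rng = np.random.default_rng(seed)
    starts = _sample_windows([(lo, hi)], length, n_perm, region, rng)
    k = sum(
        1 for s in starts
        if gmap.mean_rate(int(s), int(s) + length) <= observed
    )
    return (1 + k) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Neutral-simulation comparison
# ---------------------------------------------------------------------------

def region_statistics(
    hm: HaplotypeMatrix,
    pop: str,
    ref_pop: str = "AFR",
    window: tuple[int, int] = (40, 10),
    upper_quantile: float = 0.95,
    max_distance: float = 500_000.0,
) -> dict[str, float]:
    """Sweep-sensitive summary statistics of one region, one population.

    ``run``: longest run of consecutive XP-EHH scores above the region's
    own ``upper_quantile``; ``h12``: maximum H12 over sliding windows of
    ``window = (size, step)`` SNPs; ``score``: maximum XP-EHH score.
    Computed identically for observed regions and neutral replicates, so
    the three statistics are directly comparable.
    """
    size, step = window
    sub = hm.submatrix(pop)
    n_sites = hm.n_sites
    h12_max = 0.0
    if n_sites >= 1:
        wsize = min(size, n_sites)
        for start in range(0, max(1, n_sites - wsize + 1), step):
            h = h_statistics(hm, (start, start + wsize), pop)
            h12_max = max(h12_max, h.h12)
    out = {"h12": h12_max, "run": 0.0, "score": float("-inf")}
    try:
        tr = xpehh_scan(hm, pop, ref_pop, max_distance=max_distance,
                        standardize=True)
    except ValueError:
        return out
    if len(tr) == 0:
        return out
    thr = float(np.quantile(tr.scores, upper_quantile))
    out["run"] = float(max_run_count(tr.positions, tr.scores, thr))
    out["score"] = float(tr.scores.max())
    return out


def all_pop_region_statistics(
    hm: HaplotypeMatrix,
    pop_refs: Mapping[str, str],
    window: tuple[int, int] = (40, 10),
    upper_quantile: float = 0.95,
) -> dict[str, float]:
    """:func:`region_statistics` for several populations, flat-keyed as
    ``"<stat>:<pop>"`` so one simulated replicate serves every population's
    null at once.  Unstandardized XP-EHH is antisymmetric in the
    population pair, so reciprocal pairs are computed once and sign-flipped.
    """
    size, step = window
    raw_scans: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    out: dict[str, float] = {}
    for pop, ref in pop_refs.items():
        # H12 over sliding windows
        n_sites = hm.n_sites
        h12_max = 0.0
        if n_sites >= 1:
            wsize = min(size, n_sites)
            for start in range(0, max(1, n_sites - wsize + 1), step):
                h = h_statistics(hm, (start, start + wsize), pop)
                h12_max = max(h12_max, h.h12)
        out[f"h12:{pop}"] = h12_max
        out[f"run:{pop}"] = 0.0
        out[f"score:{pop}"] = float("-inf")
        pair, flip = ((pop, ref), False)
        if (ref, pop) in raw_scans:
            pair, flip = ((ref, pop), True)
        if pair not in raw_scans:
            try:
                tr = xpehh_scan(hm, pair[0], pair[1], standardize=False)
            except ValueError:
                continue
            raw_scans[pair] = (tr.positions, tr.scores)
        pos, raw = raw_scans[pair]
        if len(raw) == 0:
            continue
        scores = -raw if flip else raw.copy()
        if len(scores) > 1 and scores.std() > 0:
            scores = (scores - scores.mean()) / scores.std()
        thr = float(np.quantile(scores, upper_quantile))
        out[f"run:{pop}"] = float(max_run_count(pos, scores, thr))
        out[f"score:{pop}"] = float(scores.max())
    return out


def neutral_null_distribution(
    model: DemographyModel,
    region_length: int,
    n_sim: int,
    seed: int,
    n_haplotypes: int = 60,
    thinning_fraction: float = 0.48,
    stat_fn: Callable[[HaplotypeMatrix], Mapping[str, float]] | None = None,
    pop: str = "EUR",
    ref_pop: str = "AFR",
) -> list[dict[str, float]]:
    """Statistics of ``n_sim`` neutral matched-length replicates.

    Each replicate is a fresh three-population simulation with singleton
    thinning applied, summarized by ``stat_fn`` (default
    :func:`region_statistics` on ``pop`` vs ``ref_pop``).
    """
    if stat_fn is None:
        stat_fn = lambda m: region_statistics(m, pop, ref_pop)
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_sim):
        s1, s2 = (int(x % (2 ** 31)) for x in child.generate_state(2))
        hm = simulate_three_pop(model, n_haplotypes, region_length, seed=s1)
        hm = thin_singletons(hm, thinning_fraction, seed=s2)
        out.append(dict(stat_fn(hm)))
    return out


def neutral_region_test(
    observed: Mapping[str, float],
    region_length: int,
    model: DemographyModel,
    n_sim: int,
    thinning_fraction: float,
    seed: int,
    null_stats: Optional[Sequence[Mapping[str, float]]] = None,
    p_threshold: float = 0.01,
    **null_kwargs,
) -> dict:
    """Compare observed region statistics against a neutral null.

    One-sided upper-tail empirical p per statistic:
    ``p = (1 + #replicates >= observed) / (1 + n)``; a region is called
    non-neutral when any statistic's p falls below ``p_threshold``.
    ``null_stats`` reuses a precomputed ensemble (the replicates depend on
    the model and length, not on the observed region).
    """
    if null_stats is None:
        if n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        null_stats = neutral_null_distribution(
            model, region_length, n_sim, seed,
            thinning_fraction=thinning_fraction, **null_kwargs,
        )
    n = len(null_stats)
    ps = {}
    for key, obs in observed.items():
        if key not in null_stats[0]:  # null ensembles may carry fewer stats
            continue
        vals = np.array([d[key] for d in null_stats], dtype=np.float64)
        ps[key] = float((1 + (vals >= obs).sum()) / (1 + n))
    return {
        "p": ps,
        "non_neutral": any(v < p_threshold for v in ps.values()),
        "n_sim": n,
    }


# ---------------------------------------------------------------------------
# H12 region delimitation
# ---------------------------------------------------------------------------

def h12_scan_regions(
    hm: HaplotypeMatrix,
    pop: str,
    window: tuple[int, int] = (200, 25),
    h12_threshold: float = 0.1,
    min_ehh_span: float = 50_000.0,
    merge_gap: int = 10_000,
    max_distance: float = 500_000.0,
) -> list[CandidateRegion]:
    """Delimit regions with high-frequency haplotypes and long EHH.

    Sliding windows of ``window = (size, step)`` SNPs with H12 at or above
    ``h12_threshold`` are merged when closer than ``merge_gap`` bp; each
    merged region is kept only if the EHH span (level 0.5) at the centre of
    its maximum-H12 window reaches ``min_ehh_span``.  The span is measured
    among carriers of that window's most frequent haplotype — the extent
    of the predominant haplotype itself — so a sweep carried by two high-
    frequency haplotypes is not penalized for its softness.  The H2/H1
    ratio at that window annotates sweep softness.
    """
    size, step = window
    n_sites = hm.n_sites
    if n_sites == 0:
        return []
    wsize = min(size, n_sites)
    hits = []  # (start_idx, stop_idx, HStats)
    for start in range(0, max(1, n_sites - wsize + 1), step):
        stop = start + wsize
        h = h_statistics(hm, (start, stop), pop)
        if h.h12 >= h12_threshold:
            hits.append((start, stop, h))
    if not hits:
        return []

    # merge qualifying windows closer than merge_gap bp
    groups: list[list[tuple[int, int, HStats]]] = [[hits[0]]]
    for hit in hits[1:]:
        prev = groups[-1][-1]
        prev_end_pos = hm.positions[prev[1] - 1]
        start_pos = hm.positions[hit[0]]
        if start_pos - prev_end_pos <= merge_gap:
            groups[-1].append(hit)
        else:
            groups.append([hit])

    pop_rows = hm.pop_rows(pop)
    regions = []
    for grp in groups:
        first = grp[0][0]
        last = grp[-1][1] - 1
        best = max(grp, key=lambda t: t[2].h12)
        core = (best[0] + best[1] - 1) // 2
        window_alleles = hm.alleles[pop_rows][:, best[0]:best[1]]
        _, inverse, counts = np.unique(
            window_alleles, axis=0, return_inverse=True, return_counts=True
        )
        carriers = pop_rows[inverse == np.argmax(counts)]
        if len(carriers) >= 2:
            modal = HaplotypeMatrix(
                chrom=hm.chrom,
                positions=hm.positions,
                alleles=hm.alleles[carriers],
                sample_ids=[hm.sample_ids[i] for i in carriers],
                pop_of_haplotype=hm.pop_of_haplotype[carriers],
            )
            span = ehh_curve(modal, core, "all", max_distance).span()
        else:
            span = 0.0
        if span < min_ehh_span:
            continue
        iv = GenomicInterval(
            hm.chrom, int(hm.positions[first]) - 1, int(hm.positions[last])
        )
        regions.append(
            CandidateRegion(
                interval=iv,
                population=pop,
                run_length=last - first + 1,
                ehh_span=float(span),
                h_stats=best[2],
            )
        )
    return regions
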