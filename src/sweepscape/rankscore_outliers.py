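"""Empirical rank-score transform and outlier candidate calling.

Raw selection-scan scores are converted to rank scores,
``-log10(empirical upper-tail fraction)``, so a rank score above
1.3 corresponds to an empirical P below 0.05 regardless of the statistic's
native scale.  Candidate genes are those in the top fraction of the
gene-score distribution for every requested method (the three-method
intersection), and candidate sets are compared across populations with
exact Venn counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_formats import GenomicInterval, ScoreTrack

logger = logging.getLogger(__name__)


@dataclass
class RankScoreTrack:
    """A score track plus its empirical rank scores.

    ``rank_scores[i] = -log10(r_i / N)`` with ``r_i`` the number of raw
    scores >= the i-th value; ties share the larger r and hence the same
    rank score.  Values lie in ``(0, log10(N)]`` and are order-isomorphic
    to the raw scores.
    """

    statistic: str
    population: str
    chrom: str
    positions: np.ndarray
    raw_scores: np.ndarray
    rank_scores: np.ndarray


def rank_score_transform(track: ScoreTrack) -> RankScoreTrack:
    """Transform raw scores to -log10 empirical upper-tail rank scores."""
    scores = track.scores
    n = len(scores)
    if n < 10:
        raise ValueError("need >= 10 scores for an empirical rank transform")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    # r = number of values >= v, with ties sharing the larger count
    order = np.sort(scores)
    r = n - np.searchsorted(order, scores, side="left")
    rank_scores = -np.log10(r / n) + 0.0  # + 0.0 turns -0.0 into 0.0
    return RankScoreTrack(
        statistic=track.statistic,
        population=track.population,
        chrom=track.chrom,
        positions=track.positions.copy(),
        raw_scores=scores.copy(),
        rank_scores=rank_scores,
    )


def gene_level_scores(
    track: RankScoreTrack,
    genes: Sequence[tuple[GenomicInterval, str]],
    flank: int = 0,
) -> dict[str, float]:
    """Per-gene score: max rank score over points in gene body +/- flank.

    Genes with no overlapping track points map to NaN (undefined) and are
    excluded downstream, with a logged count — real score tracks do not
    cover every gene either.
    """
    out: dict[str, float] = {}
    n_unscored = 0
    pos = track.positions
    for iv, gid in genes:
        if iv.chrom != track.chrom:
            out[gid] = float("nan")
            n_unscored += 1
            continue
        lo = np.searchsorted(pos, iv.start - flank + 1, side="left")
        hi = np.searchsorted(pos, iv.end + flank, side="right")
        if hi > lo:
            out[gid] = float(track.rank_scores[lo:hi].max())
        else:
            out[gid] = float("nan")
            n_unscored += 1
    if n_unscored:
        logger.info(
            "%d/%d genes without track coverage (%s %s)",
            n_unscored, len(genes), track.statistic, track.population,
        )
    return out


@dataclass
class CandidateSet:
    """Candidate genes for one population: the per-method top sets intersected."""

    population: str
    methods: tuple[str, ...]
    genes: frozenset[str]
    best_scores: dict[str, float] = field(default_factory=dict)


def select_candidates(
    method_scores: Mapping[str, Mapping[str, float]],
    top_fraction: float = 0.05,
    methods: Optional[Sequence[str]] = None,
    population: str = "",
) -> CandidateSet:
    """Intersect per-method top-fraction gene sets.

    For each method, the candidate genes are those whose score sits in the
    top ``top_fraction`` of that method's gene-score distribution (genes
    tied with the boundary value are all included); the final set is the
    intersection across methods.  NaN-scored genes never qualify.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    if methods is None:
        methods = sorted(method_scores)
    if not methods:
        raise ValueError("need >= 1 method")
    for m in methods:
        if m not in method_scores or not method_scores[m]:
            raise ValueError(f"method {m!r} has no gene scores")
    top_sets = []
    for m in methods:
        scores = {
            g: s for g, s in method_scores[m].items() if not math.isnan(s)
        }
        vals = np.sort(np.array(list(scores.values())))[::-1]
        k = max(1, int(math.floor(top_fraction * len(vals))))
        cut = vals[k - 1]
        top_sets.append({g for g, s in scores.items() if s >= cut})
    genes = frozenset(set.intersection(*top_sets))
    best = {
        g: max(method_scores[m][g] for m in methods) for g in genes
    }
    return CandidateSet(
        population=population, methods=tuple(methods), genes=genes,
        best_scores=best,
    )


def population_overlap(
    candidate_sets: Mapping[str, CandidateSet | frozenset[str] | set[str]],
) -> dict:
    """Venn-partition counts and pairwise overlap percentages.

    Returns region counts keyed by sorted population combinations (e.g.
    ``"CEU&CHB"`` for genes in exactly those two sets), the set shared by
    all populations, and pairwise overlap percentages
    ``100 * |A ∩ B| / |A ∪ B|``.
    """
    if len(candidate_sets) < 2:
        raise ValueError("need >= 2 candidate sets")
    sets = {
        k: (v.genes if isinstance(v, CandidateSet) else frozenset(v))
        for k, v in candidate_sets.items()
    }
    pops = sorted(sets)
    universe = set().union(*sets.values())
    regions: dict[str, int] = {}
    for gene in universe:
        members = tuple(p for p in pops if gene in sets[p])
        key = "&".join(members)
        regions[key] = regions.get(key, 0) + 1
    shared = frozenset(set.intersection(*(set(s) for s in sets.values())))
    pairwise = {}
    for a, b in combinations(pops, 2):
        union = sets[a] | sets[b]
        pct = 100.0 * len(sets[a] & sets[b]) / len(union) if union else 0.0
        pairwise[f"{a}&{b}"] = pct
    return {
        "regions": regions,
        "shared_all": shared,
        "pairwise_pct": pairwise,
    }
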