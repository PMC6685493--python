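"""Core population-genetic statistics on phased haplotypes.

Weir-Cockerham F_ST (haploid allele-count variant), extended haplotype
homozygosity (EHH) with its integral iHH, the cross-population XP-EHH
log-ratio, Garud-style haplotype-homozygosity H statistics (H1, H2, H12,
H2/H1), and r^2 linkage-disequilibrium decay.

All estimators operate on a :class:`~sweepscape.io_formats.HaplotypeMatrix`
of complete phased 0/1 alleles.  Because the inputs are haplotypes, the
F_ST estimator is the haploid analysis-of-variance form: the genotype
heterozygosity term of the diploid Weir-Cockerham (1984) estimator is
absent.  Undefined values (monomorphic sites, too few carriers, vanishing
iHH denominators) are returned as NaN markers, never silently as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import HaplotypeMatrix, ScoreTrack

logger = logging.getLogger(__name__)

#: EHH value below which iHH integration is truncated
EHH_INTEGRATION_CUTOFF = 0.05
#: EHH level defining the reported span of extended homozygosity
EHH_SPAN_LEVEL = 0.5


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def fst_wc_from_counts(ns: Sequence[float], ps: Sequence[float]) -> float:
    """Haploid Weir-Cockerham ANOVA F_ST from per-population allele data.

    ``ns``: haplotype counts per population; ``ps``: allele frequencies.
    Monomorphic pooled input gives NaN (undefined, not zero); negative
    estimates are returned raw.
    """
    ns = np.asarray(ns, dtype=np.float64)
    ps = np.asarray(ps, dtype=np.float64)
    r = len(ns)
    if r < 2:
        raise ValueError("need >= 2 populations")
    n_tot = ns.sum()
    p_bar = float((ns * ps).sum() / n_tot)
    if p_bar <= 0.0 or p_bar >= 1.0:
        return float("nan")
    msp = float((ns * (ps - p_bar) ** 2).sum() / (r - 1))
    msg = float((ns * ps * (1.0 - ps)).sum() / (ns - 1.0).sum())
    n_c = float((n_tot - (ns ** 2).sum() / n_tot) / (r - 1))
    denom = msp + (n_c - 1.0) * msg
    if denom == 0.0:
        return float("nan")
    return (msp - msg) / denom


def site_fst_wc(hm: HaplotypeMatrix, pop_a: str, pop_b: str) -> np.ndarray:
    """Per-site Weir-Cockerham F_ST between two populations.

    Sites monomorphic in the pooled pair are NaN.
    """
    a = hm.submatrix(pop_a)
    b = hm.submatrix(pop_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("both populations need >= 2 haplotypes")
    na, nb = a.shape[0], b.shape[0]
    pa = a.sum(axis=0) / na
    pb = b.sum(axis=0) / nb
    out = np.empty(hm.n_sites, dtype=np.float64)
    for j in range(hm.n_sites):
        out[j] = fst_wc_from_counts([na, nb], [pa[j], pb[j]])
    return out


def global_fst_wc(hm: HaplotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir-Cockerham F_ST: ratio of summed variance components.

    The standard genome-scale estimator (sum the between- and total-
    variance components over sites, then divide once); more stable than
    averaging per-site ratios.
    """
    a = hm.submatrix(pop_a)
    b = hm.submatrix(pop_b)
    na, nb = a.shape[0], b.shape[0]
    ns = np.array([na, nb], dtype=np.float64)
    n_tot = ns.sum()
    n_c = n_tot - (ns ** 2).sum() / n_tot  # r - 1 = 1
    num = den = 0.0
    pa = a.mean(axis=0)
    pb = b.mean(axis=0)
    for j in range(hm.n_sites):
        ps = np.array([pa[j], pb[j]])
        p_bar = (ns * ps).sum() / n_tot
        if p_bar <= 0.0 or p_bar >= 1.0:
            continue
        msp = (ns * (ps - p_bar) ** 2).sum()
        msg = (ns * ps * (1.0 - ps)).sum() / (ns - 1.0).sum()
        num += msp - msg
        den += msp + (n_c - 1.0) * msg
    return num / den if den else float("nan")


def max_pairwise_fst(
    freqs: Sequence[float], ns: Sequence[float]
) -> float:
    """Maximum Weir-Cockerham F_ST over all population pairs at one site."""
    k = len(freqs)
    best = float("nan")
    for i in range(k):
        for j in range(i + 1, k):
            v = fst_wc_from_counts([ns[i], ns[j]], [freqs[i], freqs[j]])
            if np.isnan(best) or (not np.isnan(v) and v > best):
                best = v
    return best


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------

@dataclass
class EhhCurve:
    """EHH as a function of signed physical distance from a core site.

    Negative distances extend left (towards smaller positions), positive
    right.  Distance 0 always carries EHH = 1, and EHH is non-increasing
    in |distance| on each side.
    """

    core_position: int
    distances: np.ndarray  # signed bp, sorted ascending
    values: np.ndarray  # EHH in [0, 1]
    n_carriers: int

    def side(self, sign: int) -> tuple[np.ndarray, np.ndarray]:
        """(|distance|, value) arrays for one direction, origin included."""
        if sign > 0:
            m = self.distances >= 0
            d = self.distances[m]
            v = self.values[m]
        else:
            m = self.distances <= 0
            d = -self.distances[m][::-1]
            v = self.values[m][::-1]
        return d.astype(np.float64), v

    def ihh(self, cutoff: float = EHH_INTEGRATION_CUTOFF) -> float:
        """Trapezoidal integral of EHH over physical distance, both sides,
        truncated after the first segment that drops below ``cutoff``."""
        total = 0.0
        for sign in (-1, +1):
            d, v = self.side(sign)
            for i in range(1, len(d)):
                total += 0.5 * (v[i - 1] + v[i]) * (d[i] - d[i - 1])
                if v[i] < cutoff:
                    break
        return total

    def span(self, level: float = EHH_SPAN_LEVEL) -> float:
        """Total width (left + right extent) where EHH >= ``level``."""
        width = 0.0
        for sign in (-1, +1):
            d, v = self.side(sign)
            ext = 0.0
            for i in range(1, len(d)):
                if v[i] >= level:
                    ext = d[i]
                else:
                    break
            width += ext
        return width


def _ehh_walk(
    alleles: np.ndarray,
    start_groups: np.ndarray,
    site_order: Sequence[int],
    stop_below: float = 0.0,
) -> list[float]:
    """Homozygosity of extended haplotypes, refining groups site by site.

    Group labels are refined with a bincount relabelling (no sort).  EHH is
    non-increasing, so once it hits 0 the walk stops and pads with zeros;
    with ``stop_below`` > 0 it stops at the first value under that bound
    and pads with it (exact for any consumer that truncates at or above
    the bound)."""
    n = alleles.shape[0]
    pairs_total = n * (n - 1) / 2.0
    groups = start_groups.astype(np.int64, copy=True)
    n_groups = int(groups.max()) + 1 if n else 0
    out: list[float] = []
    for k, j in enumerate(site_order):
        key = groups * 2 + alleles[:, j]
        counts = np.bincount(key, minlength=2 * n_groups)
        live = np.flatnonzero(counts)
        relabel = np.zeros(2 * n_groups, dtype=np.int64)
        relabel[live] = np.arange(len(live))
        groups = relabel[key]
        n_groups = len(live)
        ehh = float((counts[live] * (counts[live] - 1) / 2.0).sum() / pairs_total)
        out.append(ehh)
        if ehh == 0.0 or ehh < stop_below:
            out.extend([ehh] * (len(site_order) - k - 1))
            break
    return out


def ehh_curve(
    hm: HaplotypeMatrix,
    core_index: int,
    core_allele: int | str = "all",
    max_distance: float = 500_000.0,
    pop: Optional[str] = None,
    stop_below: float = 0.0,
) -> EhhCurve:
    """EHH decay around a core site among carrier haplotypes.

    ``core_allele`` selects the carriers (0, 1, or "all" for every
    haplotype).  EHH(x) is the probability that two random carriers are
    identical at every site from the core out to distance x.  Fewer than 2
    carriers is undefined: the curve degenerates to NaN values.
    """
    alleles = hm.alleles if pop is None else hm.submatrix(pop)
    positions = hm.positions
    core_pos = int(positions[core_index])
    if core_allele == "all":
        rows = np.arange(alleles.shape[0])
    else:
        rows = np.flatnonzero(alleles[:, core_index] == core_allele)
    sub = alleles[rows]
    n = len(rows)

    right_idx = [
        j for j in range(core_index + 1, hm.n_sites)
        if positions[j] - core_pos <= max_distance
    ]
    left_idx = [
        j for j in range(core_index - 1, -1, -1)
        if core_pos - positions[j] <= max_distance
    ]
    dists = (
        [-(core_pos - int(positions[j])) for j in reversed(left_idx)]
        + [0]
        + [int(positions[j]) - core_pos for j in right_idx]
    )
    if n < 2:
        vals = np.full(len(dists), np.nan)
        vals[len(left_idx)] = np.nan
        return EhhCurve(core_pos, np.array(dists), vals, n)

    start = np.zeros(n, dtype=np.int64)
    right_vals = _ehh_walk(sub, start, right_idx, stop_below)
    left_vals = _ehh_walk(sub, start, left_idx, stop_below)
    values = np.array(left_vals[::-1] + [1.0] + right_vals)
    return EhhCurve(core_pos, np.array(dists), values, n)


def xpehh_scan(
    hm: HaplotypeMatrix,
    pop_a: str,
    pop_b: str,
    sites: Optional[Sequence[int]] = None,
    max_distance: float = 500_000.0,
    standardize: bool = True,
    cutoff: float = EHH_INTEGRATION_CUTOFF,
) -> ScoreTrack:
    """Cross-population EHH scan: per-site ln(iHH_A / iHH_B).

    Uses all-haplotype EHH per population, integrated bidirectionally.
    Sites where either iHH vanishes are undefined and dropped from the
    returned track (with a logged count).  With ``standardize`` the scores
    are centred and scaled over the supplied site set, the usual way XP-EHH
    is reported genome-wide.
    """
    if hm.submatrix(pop_a).shape[0] < 4 or hm.submatrix(pop_b).shape[0] < 4:
        raise ValueError("both populations need >= 4 haplotypes")
    if sites is None:
        sites = range(hm.n_sites)
    sites = list(sites)
    if not sites:
        raise ValueError("empty site set")
    raw = np.full(len(sites), np.nan)
    for k, j in enumerate(sites):
        # the walk may stop below the integration cutoff: iHH is unchanged
        ihh_a = ehh_curve(hm, j, "all", max_distance, pop=pop_a,
                          stop_below=cutoff).ihh(cutoff)
        ihh_b = ehh_curve(hm, j, "all", max_distance, pop=pop_b,
                          stop_below=cutoff).ihh(cutoff)
        if ihh_a > 0.0 and ihh_b > 0.0:
            raw[k] = np.log(ihh_a / ihh_b)
    defined = np.isfinite(raw)
    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("xpehh_scan: %d undefined sites dropped", n_undef)
    scores = raw[defined]
    if standardize and len(scores) > 1 and scores.std() > 0:
        scores = (scores - scores.mean()) / scores.std()
    return ScoreTrack(
        statistic="XP-EHH",
        population=f"{pop_a}-{pop_b}",
        chrom=hm.chrom,
        positions=hm.positions[np.array(sites)][defined],
        scores=scores,
    )


# ---------------------------------------------------------------------------
# H statistics
# ---------------------------------------------------------------------------

@dataclass
class HStats:
    """Haplotype-homozygosity statistics over a window.

    H1 is the homozygosity of the haplotype-frequency spectrum, H12 pools
    the two most frequent haplotypes, H2 drops the most frequent.  The
    ratio H2/H1 rises as a sweep becomes softer (more co-selected
    haplotypes sharing the high frequencies).
    """

    h1: float
    h2: float
    h12: float

    @property
    def ratio(self) -> float:
        return self.h2 / self.h1

    @classmethod
    def from_frequencies(cls, freqs: Sequence[float]) -> "HStats":
        p = np.sort(np.asarray(freqs, dtype=np.float64))[::-1]
        h1 = float((p ** 2).sum())
        h12 = h1 if len(p) < 2 else float((p[0] + p[1]) ** 2 + (p[2:] ** 2).sum())
        h2 = h1 - float(p[0] ** 2)
        return cls(h1=h1, h2=h2, h12=h12)


def h_statistics(
    hm: HaplotypeMatrix, window: tuple[int, int], pop: str
) -> HStats:
    """H1/H2/H12 over the site-index window ``[start, stop)`` in ``pop``.

    Haplotype classes are exact-identity classes over the window; ties in
    frequency do not affect H1, H12 or the H2/H1 ratio.
    """
    start, stop = window
    if stop <= start:
        raise ValueError("window must span >= 1 site")
    sub = hm.submatrix(pop)[:, start:stop]
    _, counts = np.unique(sub, axis=0, return_counts=True)
    return HStats.from_frequencies(counts / sub.shape[0])


# ---------------------------------------------------------------------------
# r^2 LD decay
# ---------------------------------------------------------------------------

def pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """r^2 between two 0/1 site vectors: (p_AB - p_A p_B)^2 / (p_A q_A p_B q_B)."""
    pa = x.mean()
    pb = y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    pab = float((x & y).mean())
    return (pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb))


def ld_r2_decay(
    hm: HaplotypeMatrix,
    pop: str,
    bin_edges: Sequence[float],
    threshold: float = 0.1,
) -> tuple[list[tuple[float, float, int]], float]:
    """Mean r^2 by physical-distance bin and the decay distance.

    Returns ``(rows, decay_distance)`` where each row is
    ``(bin_midpoint, mean_r2, n_pairs)`` and the decay distance is the
    midpoint of the first bin whose mean drops below ``threshold`` (NaN if
    none does).  Monomorphic pairs are skipped.
    """
    sub = hm.submatrix(pop).astype(np.int64)
    ac = sub.sum(axis=0)
    poly = np.flatnonzero((ac > 0) & (ac < sub.shape[0]))
    if len(poly) < 2:
        raise ValueError("need >= 2 polymorphic sites in the population")
    sub = sub[:, poly]
    pos = hm.positions[poly].astype(np.float64)

    # r^2 is the squared Pearson correlation of the 0/1 indicators
    c = np.corrcoef(sub.T)
    r2 = c ** 2
    iu = np.triu_indices(len(poly), k=1)
    d = np.abs(pos[iu[1]] - pos[iu[0]])
    v = r2[iu]

    edges = np.asarray(bin_edges, dtype=np.float64)
    rows = []
    decay = float("nan")
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (d >= lo) & (d < hi) & np.isfinite(v)
        mid = 0.5 * (lo + hi)
        mean = float(v[m].mean()) if m.any() else float("nan")
        rows.append((mid, mean, int(m.sum())))
        if np.isnan(decay) and np.isfinite(mean) and mean < threshold:
            decay = mid
    return rows, decay
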