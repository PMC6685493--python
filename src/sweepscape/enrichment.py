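"""Fisher-exact enrichment of GRF genes among outlier candidates.

For each selection statistic and population the candidate (top-fraction)
genes are crossed against the GRF / non-GRF partition of the gene universe
in a 2x2 table; the exact two-sided hypergeometric p-value is Bonferroni
corrected over the whole family of tests, and a verdict (Enrichment /
Depletion / No difference) is assigned from the adjusted p and the sample
odds ratio.  Raw p-values are floored at 2.2e-16 — the smallest value the
exact test is reported at — before adjustment.  Confounder checks
(recombination-rate KS test between GRF and non-GRF genes, Spearman
correlation of gene length with rank score) guard against the usual biases
of outlier scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .catalog import GRFCatalog, UNCLASSIFIED

logger = logging.getLogger(__name__)

#: floor applied to raw Fisher p-values before Bonferroni adjustment
P_FLOOR = 2.2e-16
#: default verdict threshold on the adjusted p-value
DEFAULT_ALPHA = 0.001
#: default Bonferroni family: 3 CLR + 6 XP-CLR + 6 XP-EHH + 3 FST tests
DEFAULT_FAMILY_SIZE = 18

ENRICHMENT = "Enrichment"
DEPLETION = "Depletion"
NO_DIFFERENCE = "No difference"


@dataclass
class EnrichmentRow:
    label: str
    table: tuple[int, int, int, int]  # a, b, c, d row-major
    odds_ratio: float  # ad/bc; inf when bc == 0
    p_raw: float
    p_adjusted: float
    verdict: str


def _verdict(p_adj: float, odds: float, alpha: float) -> str:
    if p_adj < alpha and odds > 1.0:
        return ENRICHMENT
    if p_adj < alpha and odds < 1.0:
        return DEPLETION
    return NO_DIFFERENCE


def fisher_enrichment(
    candidates: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
    grf_flags: Mapping[str, bool],
    family_size: int = DEFAULT_FAMILY_SIZE,
    alpha: float = DEFAULT_ALPHA,
    label: str = "",
) -> EnrichmentRow:
    """GRF-vs-non-GRF Fisher exact test for one candidate set.

    Table: (GRF in top, GRF not in top; non-GRF in top, non-GRF not in
    top).  Two-sided exact p (sum of tables at most as probable as the
    observed one), floored at ``P_FLOOR`` and Bonferroni-multiplied by
    ``family_size``.  The sample odds ratio is ad/bc (inf when bc = 0).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not set(candidates) <= set(universe):
        raise ValueError("candidates must be a subset of the universe")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    a = sum(1 for g in candidates if grf_flags.get(g, False))
    c = len(candidates) - a
    n_grf = sum(1 for g in universe if grf_flags.get(g, False))
    b = n_grf - a
    d = len(universe) - len(candidates) - b
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    p = max(float(p), P_FLOOR)
    odds = float("inf") if b * c == 0 else (a * d) / (b * c)
    p_adj = min(1.0, family_size * p)
    return EnrichmentRow(
        label=label,
        table=(a, b, c, d),
        odds_ratio=odds,
        p_raw=p,
        p_adjusted=p_adj,
        verdict=_verdict(p_adj, odds, alpha),
    )


def class_enrichment(
    catalog: GRFCatalog,
    candidates: set[str] | frozenset[str],
    classes: Optional[Sequence[str]] = None,
    family_size: Optional[int] = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentRow]:
    """Per-TF-class Fisher enrichment among the candidates.

    Each class is tested class-vs-rest against the catalog's gene
    universe; classes with no members in the universe are omitted with a
    log entry.  ``family_size`` defaults to the number of classes tested.
    """
    universe = set(catalog.records)
    cands = set(candidates) & universe
    if classes is None:
        classes = sorted({
            r.tf_class for r in catalog.records.values()
            if r.tf_class != UNCLASSIFIED
        })
    members = {
        cls: {g for g, r in catalog.records.items() if r.tf_class == cls}
        for cls in classes
    }
    tested = [cls for cls in classes if members[cls]]
    for cls in classes:
        if not members[cls]:
            logger.info("class %r has no members in the universe; omitted", cls)
    m = family_size if family_size is not None else max(1, len(tested))
    rows = []
    for cls in tested:
        in_cls = members[cls]
        flags = {g: (g in in_cls) for g in universe}
        rows.append(
            fisher_enrichment(cands, universe, flags, family_size=m,
                              alpha=alpha, label=cls)
        )
    return rows


def confounder_checks(
    gene_lengths: Mapping[str, float],
    rank_scores: Mapping[str, float],
    recomb_by_gene: Mapping[str, float],
    grf_flags: Mapping[str, bool],
) -> dict:
    """Bias checks for the outlier scan.

    Two-sample Kolmogorov-Smirnov test of per-gene recombination rates
    between GRF and non-GRF genes (D = sup |ECDF difference|), and
    Spearman rank correlation of gene length against gene rank score with
    average-rank tie handling; both with asymptotic p-values.  A constant
    input vector makes the correlation undefined (NaN).
    """
    genes = sorted(set(gene_lengths) & set(rank_scores))
    grf_rates = [recomb_by_gene[g] for g in recomb_by_gene
                 if grf_flags.get(g, False)]
    non_rates = [recomb_by_gene[g] for g in recomb_by_gene
                 if not grf_flags.get(g, False)]
    if len(grf_rates) < 8 or len(non_rates) < 8:
        raise ValueError("need >= 8 genes per group for the KS check")
    ks = stats.ks_2samp(grf_rates, non_rates, method="asymp")

    lengths = np.array([gene_lengths[g] for g in genes], dtype=np.float64)
    scores = np.array([rank_scores[g] for g in genes], dtype=np.float64)
    ok = np.isfinite(lengths) & np.isfinite(scores)
    lengths, scores = lengths[ok], scores[ok]
    if len(lengths) < 8 or np.ptp(lengths) == 0 or np.ptp(scores) == 0:
        rho, rho_p = float("nan"), float("nan")
    else:
        sp = stats.spearmanr(lengths, scores)
        rho, rho_p = float(sp.statistic), float(sp.pvalue)
    return {
        "ks_D": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "spearman_rho": rho,
        "spearman_p": rho_p,
        "n_genes": int(len(lengths)),
    }
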