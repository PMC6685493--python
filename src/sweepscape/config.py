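"""Analysis configuration: every tunable threshold in one place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional


@dataclass
class AnalysisConfig:
    """Defaults for the full sweep-scan pipeline.

    The thresholds are the conventional working values of outlier-based
    sweep scans: candidates come from the top 5% of each statistic's
    gene-score distribution; a rank score of 1.3 marks empirical P = 0.05;
    H12 regions are called at 0.1 with at least 50 kb of extended
    haplotype homozygosity; nonsynonymous variants are reported above
    F_ST 0.15 (0.25 marking the high tier); sites must clear a pooled
    minor-allele frequency of 0.001; permutation and simulation nulls use
    1,000 draws; and 48% of global singletons are thinned from simulated
    data to mimic low-coverage ascertainment.
    """

    top_fraction: float = 0.05
    rank_threshold: float = 1.3
    h12_threshold: float = 0.1
    min_ehh_span: float = 50_000.0
    fst_report_threshold: float = 0.15
    fst_high_threshold: float = 0.25
    maf_min: float = 0.001
    n_perm: int = 1_000
    n_sim: int = 1_000
    thinning_fraction: float = 0.48
    ehh_cutoff: float = 0.05
    ehh_span_level: float = 0.5
    h12_window: tuple[int, int] = (200, 25)
    merge_gap: int = 10_000
    neutral_p_threshold: float = 0.01
    enrichment_alpha: float = 0.001
    bonferroni_family: Optional[int] = None  # None: number of tests in the run
    xpehh_max_distance: float = 500_000.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if not (0 <= self.thinning_fraction <= 1):
            raise ValueError("thinning_fraction must be in [0, 1]")
        for name in ("rank_threshold", "h12_threshold", "min_ehh_span",
                     "fst_report_threshold", "maf_min", "n_perm", "n_sim"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("AnalysisConfig.seed is mandatory for a run")
        return self.seed

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
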