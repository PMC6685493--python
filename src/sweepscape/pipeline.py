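"""End-to-end orchestration: inputs -> statistics -> candidates ->
enrichment -> cluster scan -> ZNF variant report.

The pipeline consumes a fixture bundle (or identically laid-out real
inputs): a phased haplotype VCF, cluster and gene BEDs, precomputed CLR and
XP-CLR score tracks, a genetic map, a GRF catalog TSV, and a ZNF protein
with its CDS and coding variants.  XP-EHH and F_ST are computed from the
haplotypes; CLR and XP-CLR are consumed as tracks, the way genome-browser
scans distribute them.  Every stage is a pure function of its declared
inputs and the run seed, so identical config + seed reproduces every
output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .catalog import read_catalog_tsv
from .cluster_scan import (
    CandidateRegion,
    all_pop_region_statistics,
    h12_scan_regions,
    max_run_count,
    neutral_null_distribution,
    neutral_region_test,
    permutation_run_test,
    recombination_deficit_test,
    region_statistics,
)
from .config import AnalysisConfig
from .enrichment import fisher_enrichment
from .io_formats import (
    GenomicInterval,
    HaplotypeMatrix,
    ScoreTrack,
    read_genetic_map,
    read_haplotypes_vcf,
    read_intervals_bed,
    read_score_track,
)
from .popgen_stats import max_pairwise_fst, site_fst_wc, xpehh_scan
from .rankscore_outliers import (
    gene_level_scores,
    population_overlap,
    rank_score_transform,
    select_candidates,
)
from .synthetic_data import DemographyModel, POP_LABELS
from .znf_annotation import (
    annotate_variant,
    build_feature_map,
    detect_c2h2_fingers,
    high_fst_nonsyn_report,
)

logger = logging.getLogger(__name__)

#: reference population for the cross-population statistics, per target pop
XP_REFERENCE = {"EUR": "AFR", "EAS": "AFR", "AFR": "EUR"}


def load_bundle(bundle_dir: str | Path) -> dict:
    """Load a fixture bundle directory via its manifest."""
    bundle_dir = Path(bundle_dir)
    manifest = json.loads((bundle_dir / "manifest.json").read_text())

    def _p(key: str) -> Path:
        return bundle_dir / Path(manifest["files"][key]).name

    return {
        "manifest": manifest,
        "vcf": _p("vcf"),
        "clusters": read_intervals_bed(_p("clusters_bed")),
        "genes": read_intervals_bed(_p("genes_bed")),
        "gmap": read_genetic_map(_p("genetic_map")),
        "catalog": read_catalog_tsv(_p("catalog")),
        "protein_fasta": _p("protein_fasta"),
        "cds_fasta": _p("cds_fasta"),
        "variants": pd.read_csv(_p("variants"), sep="\t"),
        "score_paths": {
            k: bundle_dir / Path(v).name
            for k, v in manifest["score_tracks"].items()
        },
    }


def read_bundle_haplotypes(bundle: dict, maf_min: float) -> HaplotypeMatrix:
    vcf_path = bundle["vcf"]
    from cyvcf2 import VCF as _VCF

    samples = _VCF(str(vcf_path)).samples
    assignments = {s: s.split("_")[0] for s in samples}
    return read_haplotypes_vcf(vcf_path, assignments, maf_min=maf_min)


def _blocks(bundle: dict) -> list[tuple[str, GenomicInterval, bool]]:
    out = []
    for b in bundle["manifest"]["blocks"]:
        iv = GenomicInterval(bundle["manifest"]["chrom"], *b["interval"])
        out.append((b["name"], iv, bool(b["is_cluster"])))
    return out


def _restrict(hm: HaplotypeMatrix, iv: GenomicInterval) -> HaplotypeMatrix:
    mask = (hm.positions > iv.start) & (hm.positions <= iv.end)
    return hm.restrict_sites(mask)


def compute_xpehh_tracks(
    hm: HaplotypeMatrix,
    blocks: list[tuple[str, GenomicInterval, bool]],
    config: AnalysisConfig,
) -> dict[str, ScoreTrack]:
    """Per-population XP-EHH over each simulated block, concatenated.

    EHH is never extended across block boundaries (blocks are unlinked);
    standardization happens once over the concatenated per-population
    scores, mimicking genome-wide standardization.
    """
    tracks: dict[str, ScoreTrack] = {}
    for pop in POP_LABELS:
        ref = XP_REFERENCE[pop]
        pos_all, raw_all = [], []
        for _, iv, _ in blocks:
            sub = _restrict(hm, iv)
            if sub.n_sites < 2:
                continue
            tr = xpehh_scan(
                sub, pop, ref, max_distance=config.xpehh_max_distance,
                standardize=False, cutoff=config.ehh_cutoff,
            )
            pos_all.append(tr.positions)
            raw_all.append(tr.scores)
        pos = np.concatenate(pos_all)
        raw = np.concatenate(raw_all)
        if raw.std() > 0:
            raw = (raw - raw.mean()) / raw.std()
        tracks[pop] = ScoreTrack("XP-EHH", f"{pop}-{ref}", hm.chrom, pos, raw)
    return tracks


def compute_fst_tracks(hm: HaplotypeMatrix) -> dict[str, ScoreTrack]:
    """Per-site Weir-Cockerham F_ST for every population pair."""
    tracks = {}
    pairs = [("EUR", "AFR"), ("EAS", "AFR"), ("EUR", "EAS")]
    for a, b in pairs:
        vals = site_fst_wc(hm, a, b)
        ok = np.isfinite(vals)
        tracks[f"{a}-{b}"] = ScoreTrack(
            "FST", f"{a}-{b}", hm.chrom, hm.positions[ok], vals[ok]
        )
    return tracks


def call_candidates(
    method_tracks: Mapping[str, Mapping[str, ScoreTrack]],
    genes,
    config: AnalysisConfig,
) -> tuple[dict, dict]:
    """Rank-transform tracks, score genes, and intersect per-method tops.

    ``method_tracks[method][pop]`` holds the raw track; returns the
    per-population candidate sets and the per-method per-population gene
    score maps (NaN for uncovered genes).
    """
    gene_scores: dict[str, dict[str, dict[str, float]]] = {}
    for method, per_pop in method_tracks.items():
        gene_scores[method] = {}
        for pop, track in per_pop.items():
            rs = rank_score_transform(track)
            gene_scores[method][pop] = gene_level_scores(rs, genes)
    candidates = {}
    for pop in POP_LABELS:
        per_method = {m: gene_scores[m][pop] for m in method_tracks}
        candidates[pop] = select_candidates(
            per_method, top_fraction=config.top_fraction, population=pop
        )
    return candidates, gene_scores


def scan_clusters(
    hm: HaplotypeMatrix,
    bundle: dict,
    xpehh_tracks: Mapping[str, ScoreTrack],
    config: AnalysisConfig,
    seed: int,
    null_cache: Optional[dict] = None,
) -> list[CandidateRegion]:
    """Cluster-level sweep evidence: H12 regions with three empirical p's.

    The neutral null ensemble is simulated once per distinct region length
    (``null_cache`` can carry one across calls) at the bundle's demography.
    """
    blocks = _blocks(bundle)
    universe = [(iv.start, iv.end) for _, iv, _ in blocks]
    gmap = bundle["gmap"]
    model = DemographyModel(**bundle["manifest"]["model"])
    # null replicates sample the same number of haplotypes as the data, so
    # sample-size-dependent statistics (H12 especially) are comparable
    n_hap_null = bundle["manifest"]["n_haplotypes_per_pop"]
    if n_hap_null % 2:
        n_hap_null -= 1
    null_cache = null_cache if null_cache is not None else {}
    rng = np.random.default_rng(seed)
    regions: list[CandidateRegion] = []
    scan_window = config.h12_window
    for name, iv, is_cluster in blocks:
        if not is_cluster:
            continue
        sub = _restrict(hm, iv)
        if sub.n_sites < 5:
            continue
        for pop in POP_LABELS:
            found = h12_scan_regions(
                sub, pop, window=scan_window,
                h12_threshold=config.h12_threshold,
                min_ehh_span=config.min_ehh_span,
                merge_gap=config.merge_gap,
                max_distance=config.xpehh_max_distance,
            )
            if not found:
                continue
            track = xpehh_tracks[pop]
            a = np.searchsorted(track.positions, iv.start, side="left")
            b = np.searchsorted(track.positions, iv.end, side="right")
            rs = rank_score_transform(track)
            observed_run = max_run_count(
                rs.positions[a:b], rs.rank_scores[a:b], config.rank_threshold
            )
            p_run, _ = permutation_run_test(
                observed_run, rs, len(iv), config.n_perm,
                seed=int(rng.integers(2 ** 31)),
                threshold=config.rank_threshold,
                exclude=iv, universe=universe,
            )
            p_rec = recombination_deficit_test(
                iv, gmap, config.n_perm, seed=int(rng.integers(2 ** 31)),
                universe=(0, bundle["manifest"]["chrom_length"]),
            )
            key = len(iv)
            if key not in null_cache:
                null_cache[key] = neutral_null_distribution(
                    model, len(iv), config.n_sim,
                    seed=int(rng.integers(2 ** 31)),
                    n_haplotypes=n_hap_null,
                    thinning_fraction=config.thinning_fraction,
                    stat_fn=lambda m: all_pop_region_statistics(m, XP_REFERENCE),
                )
            obs_stats = {
                f"{k}:{pop}": v
                for k, v in region_statistics(sub, pop, XP_REFERENCE[pop]).items()
            }
            res = neutral_region_test(
                obs_stats, len(iv), model, config.n_sim,
                config.thinning_fraction, seed=0,
                null_stats=null_cache[key],
                p_threshold=config.neutral_p_threshold,
            )
            for reg in found:
                reg.p_run_permutation = p_run
                reg.p_recombination = p_rec
                reg.p_neutral_simulation = min(res["p"].values())
                reg.gene_ids = [
                    gid for giv, gid in bundle["genes"]
                    if giv.overlaps(reg.interval)
                ]
                regions.append(reg)
    return regions


def znf_variant_report(bundle: dict, config: AnalysisConfig) -> pd.DataFrame:
    """Annotate the bundle's coding variants and report high-F_ST ones."""
    seq = "".join(
        l.strip() for l in bundle["protein_fasta"].read_text().splitlines()
        if not l.startswith(">")
    )
    cds = "".join(
        l.strip() for l in bundle["cds_fasta"].read_text().splitlines()
        if not l.startswith(">")
    )
    arch = bundle["manifest"]["znf_architecture"]
    fingers = detect_c2h2_fingers(seq)
    fmap = build_feature_map(
        fingers, tuple(arch["krab"]), len(seq),
        protein_id=arch["protein_id"],
    )
    consequences = []
    for _, row in bundle["variants"].iterrows():
        freqs = [row[f"freq_{p}"] for p in POP_LABELS]
        ns = [row[f"n_{p}"] for p in POP_LABELS]
        fst = max_pairwise_fst(freqs, ns)
        consequences.append(
            annotate_variant(
                cds, int(row["cds_pos"]), str(row["ref"]), str(row["alt"]),
                fmap, gene_id=arch["protein_id"],
                pop_frequencies={p: row[f"freq_{p}"] for p in POP_LABELS},
                max_fst=fst,
            )
        )
    return high_fst_nonsyn_report(
        consequences, threshold=config.fst_report_threshold
    )


def run_full_pipeline(
    bundle_dir: str | Path,
    config: AnalysisConfig,
    outdir: str | Path,
    null_cache: Optional[dict] = None,
) -> dict:
    """Run every stage on a bundle; write the report files; return a summary.

    Outputs: ``candidates_<pop>.tsv``, ``venn_summary.json``,
    ``enrichment.tsv``, ``cluster_regions.tsv``, ``znf_report.tsv`` and
    ``run_manifest.json``.
    """
    seed = config.require_seed()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = load_bundle(bundle_dir)
    counts: dict[str, int] = {}

    hm = read_bundle_haplotypes(bundle, config.maf_min)
    counts["sites_after_maf"] = hm.n_sites
    blocks = _blocks(bundle)

    # score tracks: CLR / XP-CLR from disk, XP-EHH and F_ST from haplotypes
    clr = {
        pop: read_score_track(bundle["score_paths"][f"CLR:{pop}"], "CLR", pop)
        for pop in POP_LABELS
    }
    xpclr = {
        pop: read_score_track(
            bundle["score_paths"][f"XP-CLR:{pop}"], "XP-CLR", pop
        )
        for pop in POP_LABELS
    }
    xpehh = compute_xpehh_tracks(hm, blocks, config)
    fst_tracks = compute_fst_tracks(hm)

    genes = bundle["genes"]
    candidates, gene_scores = call_candidates(
        {"CLR": clr, "XP-CLR": xpclr, "XP-EHH": xpehh}, genes, config
    )
    overlap = population_overlap(candidates)

    # enrichment: GRF vs non-GRF per method x population (+ FST pairs)
    catalog = bundle["catalog"]
    grf_flags = {gid: (gid in catalog.grf_ids) for _, gid in genes}
    fst_gene_scores = {}
    for pair, track in fst_tracks.items():
        rs = rank_score_transform(track)
        fst_gene_scores[pair] = gene_level_scores(rs, genes)
    tests = []
    for method in ("CLR", "XP-CLR", "XP-EHH"):
        for pop in POP_LABELS:
            tests.append((f"{method} {pop}", gene_scores[method][pop]))
    for pair, scores in fst_gene_scores.items():
        tests.append((f"FST {pair}", scores))
    family = config.bonferroni_family or len(tests)
    rows = []
    for label, scores in tests:
        scored = {g for g, s in scores.items() if np.isfinite(s)}
        counts[f"unscored[{label}]"] = len(genes) - len(scored)
        vals = np.sort([scores[g] for g in scored])[::-1]
        k = max(1, int(np.floor(config.top_fraction * len(vals))))
        cut = vals[k - 1]
        top = {g for g in scored if scores[g] >= cut}
        row = fisher_enrichment(
            top, scored, grf_flags, family_size=family,
            alpha=config.enrichment_alpha, label=label,
        )
        rows.append(row)
    enrich_df = pd.DataFrame(
        {
            "test": r.label,
            "grf_top": r.table[0], "grf_rest": r.table[1],
            "nongrf_top": r.table[2], "nongrf_rest": r.table[3],
            "odds_ratio": r.odds_ratio,
            "p_bonferroni": r.p_adjusted,
            "feature": r.verdict,
        }
        for r in rows
    )

    regions = scan_clusters(hm, bundle, xpehh, config, seed,
                            null_cache=null_cache)
    counts["regions_tested"] = len(regions)
    region_df = pd.DataFrame(
        {
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "length_mb": round(len(r.interval) / 1e6, 3),
            "population": r.population,
            "grf_genes": ",".join(
                g for g in r.gene_ids if g in catalog.grf_ids
            ),
            "non_grf_genes": ",".join(
                g for g in r.gene_ids if g not in catalog.grf_ids
            ),
            "h12": r.h_stats.h12,
            "h2_h1": r.softness,
            "ehh_span": r.ehh_span,
            "p_run": r.p_run_permutation,
            "p_recomb": r.p_recombination,
            "p_neutral": r.p_neutral_simulation,
        }
        for r in regions
    )

    znf_df = znf_variant_report(bundle, config)

    # --- write outputs
    for pop in POP_LABELS:
        cs = candidates[pop]
        pd.DataFrame(
            sorted(
                ({"gene_id": g, "best_rank_score": cs.best_scores[g]}
                 for g in cs.genes),
                key=lambda d: -d["best_rank_score"],
            )
        ).to_csv(outdir / f"candidates_{pop}.tsv", sep="\t", index=False)
    with open(outdir / "venn_summary.json", "w") as fh:
        json.dump(
            {
                "regions": overlap["regions"],
                "shared_all": sorted(overlap["shared_all"]),
                "pairwise_pct": overlap["pairwise_pct"],
            },
            fh, indent=1, sort_keys=True,
        )
    enrich_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    region_df.to_csv(outdir / "cluster_regions.tsv", sep="\t", index=False)
    znf_df.to_csv(outdir / "znf_report.tsv", sep="\t", index=False)
    run_manifest = {
        "sweepscape_version": __version__,
        "config": {**asdict(config)},
        "config_digest": config.digest(),
        "seed": seed,
        "bonferroni_family": family,
        "stage_counts": counts,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=1, sort_keys=True, default=str)

    return {
        "candidates": candidates,
        "overlap": overlap,
        "enrichment": enrich_df,
        "regions": regions,
        "region_table": region_df,
        "znf_report": znf_df,
        "counts": counts,
    }
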