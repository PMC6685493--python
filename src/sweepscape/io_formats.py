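"""Shared genomic data types and on-disk format readers/writers.

Internal coordinates are 0-based half-open (:class:`GenomicInterval`).
VCF positions are 1-based, as on disk; :class:`HaplotypeMatrix` keeps them
that way because every haplotype statistic works on physical distances, for
which the origin convention is irrelevant.  Every cross-format conversion
happens at read/write time and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: statistics a ScoreTrack may carry
VALID_STATISTICS = ("CLR", "XP-CLR", "XP-EHH", "FST", "H12")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"end ({self.end}) must exceed start ({self.start}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_position(self, pos: int) -> bool:
        """True if 1-based position ``pos`` falls inside the interval."""
        return self.start < pos <= self.end

    def intersect_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class HaplotypeMatrix:
    """Phased biallelic haplotypes: H haplotypes x S sites of 0/1 alleles.

    ``positions`` are 1-based (VCF convention) and strictly increasing.
    ``pop_of_haplotype`` labels each row; every population must contribute
    at least two haplotypes, so that within-population statistics are
    defined everywhere.
    """

    chrom: str
    positions: np.ndarray  # (S,) int64, 1-based, strictly increasing
    alleles: np.ndarray  # (H, S) uint8 in {0,1}
    sample_ids: list[str]  # length H; one entry per haplotype
    pop_of_haplotype: np.ndarray  # (H,) object/str
    site_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.pop_of_haplotype = np.asarray(self.pop_of_haplotype, dtype=object)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        h, s = self.alleles.shape
        if len(self.positions) != s:
            raise ValueError("positions length does not match allele columns")
        if s > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if len(self.pop_of_haplotype) != h:
            raise ValueError("pop_of_haplotype length does not match haplotypes")
        if not self.site_ids:
            self.site_ids = [f"{self.chrom}:{p}" for p in self.positions]
        if len(self.site_ids) != s:
            raise ValueError("site_ids length does not match sites")
        vals = np.unique(self.alleles) if self.alleles.size else np.array([0])
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("alleles must be 0/1")
        for pop, cnt in zip(*np.unique(self.pop_of_haplotype, return_counts=True)):
            if cnt < 2:
                raise ValueError(f"population {pop!r} has fewer than 2 haplotypes")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.pop_of_haplotype.tolist()))

    def pop_rows(self, pop: str) -> np.ndarray:
        rows = np.flatnonzero(self.pop_of_haplotype == pop)
        if rows.size == 0:
            raise KeyError(f"population {pop!r} absent from haplotype matrix")
        return rows

    def submatrix(self, pop: str) -> np.ndarray:
        return self.alleles[self.pop_rows(pop)]

    def restrict_sites(self, mask: np.ndarray) -> "HaplotypeMatrix":
        mask = np.asarray(mask)
        out = HaplotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[mask],
            alleles=self.alleles[:, mask],
            sample_ids=list(self.sample_ids),
            pop_of_haplotype=self.pop_of_haplotype.copy(),
            site_ids=[s for s, m in zip(self.site_ids, mask) if m],
        )
        if hasattr(self, "provenance"):  # simulation metadata travels along
            out.provenance = self.provenance  # type: ignore[attr-defined]
        return out

    def derived_counts(self, pop: str | None = None) -> np.ndarray:
        """Per-site count of the 1 (ALT) allele, overall or in one population."""
        a = self.alleles if pop is None else self.submatrix(pop)
        return a.sum(axis=0, dtype=np.int64)


@dataclass
class ScoreTrack:
    """Per-position values of one selection/differentiation statistic."""

    statistic: str
    population: str  # population or "POP1-POP2" pair label
    chrom: str
    positions: np.ndarray  # (n,) int64, sorted ascending
    scores: np.ndarray  # (n,) float64, finite

    def __post_init__(self) -> None:
        if self.statistic not in VALID_STATISTICS:
            raise ValueError(
                f"unknown statistic {self.statistic!r}; allowed: {VALID_STATISTICS}"
            )
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.positions.shape != self.scores.shape:
            raise ValueError("positions and scores must have equal length")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        order = np.argsort(self.positions, kind="stable")
        self.positions = self.positions[order]
        self.scores = self.scores[order]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class GeneticMap:
    """Piecewise-constant recombination-rate map (cM/Mb).

    ``rates[i]`` applies on ``[positions[i], positions[i+1])``; the final
    rate extends to the right indefinitely and the first extends left.
    """

    chrom: str
    positions: np.ndarray  # (n,) int64, increasing
    rates: np.ndarray  # (n,) float64 cM/Mb, >= 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if len(self.positions) != len(self.rates) or len(self.rates) == 0:
            raise ValueError("positions and rates must be equal-length, non-empty")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("map positions must be increasing")
        if np.any(self.rates < 0):
            raise ValueError("recombination rates must be >= 0")

    def mean_rate(self, start: int, end: int) -> float:
        """Length-weighted mean rate over ``[start, end)`` in bp."""
        if end <= start:
            raise ValueError("end must exceed start")
        # breakpoints restricted to the query window
        cuts = [start] + [
            int(p) for p in self.positions if start < p < end
        ] + [end]
        total = 0.0
        for a, b in zip(cuts[:-1], cuts[1:]):
            idx = int(np.searchsorted(self.positions, a, side="right")) - 1
            idx = max(idx, 0)
            total += self.rates[idx] * (b - a)
        return total / (end - start)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_haplotypes_vcf(
    path: str | Path,
    pop_assignments: Mapping[str, str],
    maf_min: float = 0.001,
) -> HaplotypeMatrix:
    """Read phased biallelic SNPs from a VCF into a :class:`HaplotypeMatrix`.

    Sites whose pooled minor-allele frequency is <= ``maf_min`` are dropped.
    Multi-allelic and indel records are skipped (counted in the log), not
    split.  Unphased or missing genotypes, and samples without a population
    assignment, are hard errors: every downstream statistic assumes complete
    phased haplotypes.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in pop_assignments]
    if missing:
        raise ValueError(f"samples missing from pop_assignments: {missing}")

    chrom = None
    positions: list[int] = []
    site_ids: list[str] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gts = np.array(var.genotypes, dtype=object)  # rows: [a0, a1, phased]
        phased = all(g[2] for g in var.genotypes)
        if not phased:
            raise ValueError(
                f"unphased genotype at {var.CHROM}:{var.POS}; phased GT required"
            )
        hap = np.array(
            [[g[0], g[1]] for g in var.genotypes], dtype=np.int64
        ).reshape(-1)
        if np.any(hap < 0):
            raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError("multi-chromosome VCFs are not supported per matrix")
        positions.append(var.POS)
        site_ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        cols.append(hap.astype(np.uint8))
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records in %s", n_skipped, path)
    if not cols:
        raise ValueError(f"no usable biallelic SNP records in {path}")

    alleles = np.stack(cols, axis=1)  # (H, S)
    hap_samples = [s for s in samples for _ in (0, 1)]
    pops = np.array([pop_assignments[s] for s in hap_samples], dtype=object)

    # pooled MAF filter
    h = alleles.shape[0]
    ac = alleles.sum(axis=0)
    maf = np.minimum(ac, h - ac) / h
    keep = maf > maf_min
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d sites with pooled MAF <= %g", n_dropped, maf_min)
    hm = HaplotypeMatrix(
        chrom=chrom,
        positions=np.array(positions, dtype=np.int64),
        alleles=alleles,
        sample_ids=hap_samples,
        pop_of_haplotype=pops,
        site_ids=site_ids,
    )
    return hm.restrict_sites(keep)


def write_haplotypes_vcf(hm: HaplotypeMatrix, path: str | Path) -> Path:
    """Write a :class:`HaplotypeMatrix` as an uncompressed VCFv4.2 file.

    Alleles are written REF=A / ALT=G (allele identity is not part of the
    matrix); GT fields are phased.  Round-trips through
    :func:`read_haplotypes_vcf` losslessly for the fields the type carries.
    """
    path = Path(path)
    samples = hm.sample_ids[::2]
    if hm.sample_ids != [s for s in samples for _ in (0, 1)]:
        raise ValueError("sample_ids must pair consecutive haplotypes per sample")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hm.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j in range(hm.n_sites):
            col = hm.alleles[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(samples))
            )
            fh.write(
                f"{hm.chrom}\t{hm.positions[j]}\t{hm.site_ids[j]}\t"
                f"A\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return path


def read_intervals_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read a BED3/BED4 file; coordinates stay 0-based half-open."""
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            name = parts[3] if len(parts) > 3 else f"region_{lineno}"
            out.append((GenomicInterval(chrom, start, end), name))
    return out


def write_intervals_bed(
    intervals: Iterable[tuple[GenomicInterval, str]], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for iv, name in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
    return path


def read_score_track(
    path: str | Path, statistic: str, population: str
) -> ScoreTrack:
    """Read a TSV score track (chrom, position|start+end, score).

    Windowed tracks (start/end columns) are normalized to per-position
    points at window midpoints.  Rows with non-numeric scores are rejected
    with a logged count.
    """
    if statistic not in VALID_STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; allowed: {VALID_STATISTICS}"
        )
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    if "position" in cols:
        pos = df[cols["position"]]
    elif "pos" in cols:
        pos = df[cols["pos"]]
    elif "start" in cols and "end" in cols:
        pos = (df[cols["start"]] + df[cols["end"]]) // 2
    else:
        raise ValueError(f"{path}: need a position or start/end column")
    score = pd.to_numeric(df[cols["score"]], errors="coerce")
    bad = score.isna() | ~np.isfinite(score)
    if bad.any():
        logger.info("rejected %d non-numeric score rows in %s", int(bad.sum()), path)
    chrom_col = cols.get("chrom", cols.get("chromosome"))
    chroms = df[chrom_col][~bad].unique()
    if len(chroms) != 1:
        raise ValueError(f"{path}: expected a single chromosome, got {chroms}")
    return ScoreTrack(
        statistic=statistic,
        population=population,
        chrom=str(chroms[0]),
        positions=pos[~bad].to_numpy(dtype=np.int64),
        scores=score[~bad].to_numpy(dtype=np.float64),
    )


def write_score_track(track: ScoreTrack, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"chrom": track.chrom, "position": track.positions, "score": track.scores}
    ).to_csv(path, sep="\t", index=False)
    return path


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a TSV genetic map (chrom, position, rate cM/Mb)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    chrom = str(df[cols.get("chrom", cols.get("chromosome"))].iloc[0])
    rates = df[cols["rate"]].to_numpy(dtype=np.float64)
    if np.any(rates < 0):
        raise ValueError(f"{path}: negative recombination rate")
    return GeneticMap(
        chrom=chrom,
        positions=df[cols["position"]].to_numpy(dtype=np.int64),
        rates=rates,
    )


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"chrom": gmap.chrom, "position": gmap.positions, "rate": gmap.rates}
    ).to_csv(path, sep="\t", index=False)
    return path
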