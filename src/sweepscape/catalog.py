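"""Assembly and classification of the gene-regulatory-factor (GRF) catalog.

A GRF catalog is the union of several published gene inventories
(DNA-binding transcription factors, cofactors, chromatin modifiers), with
per-gene provenance recording which source lists contributed it, and an
optional functional classification into transcription-factor classes
(KRAB-ZNF, non-KRAB C2H2, Homeo domain, ...).  The class vocabulary ships
as data (a TSV), not code, and is freely extensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io_formats import GenomicInterval

UNCLASSIFIED = "unclassified"


def load_class_vocabulary(path: Optional[str | Path] = None) -> list[str]:
    """TF-class labels; the shipped default lists the large named classes."""
    if path is None:
        src = resources.files("sweepscape").joinpath("data/tf_classes.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    labels = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            labels.append(line.split("\t")[0])
    return labels


@dataclass
class GeneRecord:
    gene_id: str
    symbol: str
    interval: Optional[GenomicInterval] = None
    is_grf: bool = False
    tf_class: str = UNCLASSIFIED
    sources: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.is_grf and not self.sources:
            raise ValueError(
                f"{self.gene_id}: a GRF record requires >= 1 source list"
            )


@dataclass
class GRFCatalog:
    """Merged gene records plus source-list metadata."""

    records: dict[str, GeneRecord]
    source_sizes: dict[str, int] = field(default_factory=dict)
    inclusion_pct: dict[str, float] = field(default_factory=dict)
    class_vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vocab = set(self.class_vocabulary) | {UNCLASSIFIED}
        if self.class_vocabulary:
            bad = {
                r.tf_class for r in self.records.values()
                if r.tf_class not in vocab
            }
            if bad:
                raise ValueError(f"tf_class labels outside vocabulary: {bad}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def grf_ids(self) -> frozenset[str]:
        return frozenset(g for g, r in self.records.items() if r.is_grf)


def merge_gene_lists(
    lists: Mapping[str, Sequence[tuple[str, str]]],
    synonym_table: Optional[Mapping[str, str]] = None,
    class_vocabulary: Optional[list[str]] = None,
) -> GRFCatalog:
    """Union several named (gene_id, symbol) lists into one catalog.

    Identifiers are normalized through the caller-supplied synonym table
    before merging; each gene then records every source list that
    contributed it, and per-source inclusion percentages
    ``|source ∩ catalog| / |source|`` are reported (100% by construction
    for a pure union, less when the caller later filters the catalog).
    Two different symbols resolving to one id is an unresolvable collision
    and a hard error.
    """
    synonym_table = synonym_table or {}
    records: dict[str, GeneRecord] = {}
    source_sizes: dict[str, int] = {}
    symbol_of: dict[str, str] = {}
    for name, entries in lists.items():
        seen_ids = set()
        for gid, symbol in entries:
            gid = synonym_table.get(gid, gid)
            if gid in seen_ids:
                raise ValueError(
                    f"list {name!r}: duplicate id {gid!r} after synonym "
                    "normalization"
                )
            seen_ids.add(gid)
            if gid in symbol_of and symbol_of[gid] != symbol:
                raise ValueError(
                    f"id collision for {gid!r}: symbols "
                    f"{symbol_of[gid]!r} vs {symbol!r}"
                )
            symbol_of[gid] = symbol
            if gid in records:
                rec = records[gid]
                records[gid] = GeneRecord(
                    gene_id=gid, symbol=symbol, interval=rec.interval,
                    is_grf=True, tf_class=rec.tf_class,
                    sources=rec.sources | {name},
                )
            else:
                records[gid] = GeneRecord(
                    gene_id=gid, symbol=symbol, is_grf=True,
                    sources=frozenset({name}),
                )
        source_sizes[name] = len(seen_ids)
    inclusion = {
        name: 100.0 * sum(1 for r in records.values() if name in r.sources)
        / size
        for name, size in source_sizes.items() if size
    }
    return GRFCatalog(
        records=records,
        source_sizes=source_sizes,
        inclusion_pct=inclusion,
        class_vocabulary=class_vocabulary or [],
    )


def summarize_classes(catalog: GRFCatalog) -> pd.DataFrame:
    """Counts of classified genes per TF class, descending.

    Unclassified genes are not rows; the counts sum to the number of
    classified genes.
    """
    counts: dict[str, int] = {}
    for rec in catalog.records.values():
        if rec.tf_class != UNCLASSIFIED:
            counts[rec.tf_class] = counts.get(rec.tf_class, 0) + 1
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["tf_class", "n_genes"],
    )
    return df


def read_catalog_tsv(path: str | Path,
                     class_vocabulary: Optional[list[str]] = None) -> GRFCatalog:
    """Read a catalog TSV (gene_id, symbol, chrom, start, end, is_grf,
    tf_class, sources) such as the one the fixture bundle writes."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    records = {}
    for _, row in df.iterrows():
        sources = frozenset(
            s for s in str(row.get("sources", "")).split(",") if s
        )
        iv = None
        if {"chrom", "start", "end"} <= set(df.columns):
            iv = GenomicInterval(str(row["chrom"]), int(row["start"]),
                                 int(row["end"]))
        records[str(row["gene_id"])] = GeneRecord(
            gene_id=str(row["gene_id"]),
            symbol=str(row.get("symbol", row["gene_id"])),
            interval=iv,
            is_grf=bool(int(row.get("is_grf", 0))),
            tf_class=str(row.get("tf_class", UNCLASSIFIED)) or UNCLASSIFIED,
            sources=sources,
        )
    return GRFCatalog(records=records,
                      class_vocabulary=class_vocabulary or [])
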