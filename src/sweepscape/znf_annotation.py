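"""C2H2 zinc-finger architecture detection and coding-variant annotation.

A C2H2 finger is a ~21-28 residue module in which two cysteines and two
histidines tetrahedrally coordinate a zinc ion; DNA-binding specificity
resides at recognition-helix positions -1, 2, 3 and 6.  Fingers are
detected with the canonical pattern ``C-x(2,4)-C-x(12)-H-x(3,5)-H``; the
recognition-helix contact residues are anchored on the first coordinating
histidine at sequence index h as (h-7, h-5, h-4, h-1).  Linkers are the
gaps between consecutive fingers (canonically TGEKP); the KRAB repressor
domain, when present, comes from supplied annotation rather than
prediction.

Nonsynonymous variants are classified by the feature their residue falls
in: a change at a zinc-coordinating position very likely disrupts folding
of that finger; a change at a contact position can re-target the protein;
linker changes alter inter-finger spacing and the C-cap of the preceding
finger; KRAB changes can affect KAP1 recruitment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
DNA_ALPHABET = set("ACGT")

ZINC_COORDINATING = "ZINC_COORDINATING"
DNA_CONTACT = "DNA_CONTACT"
LINKER = "LINKER"
KRAB_DOMAIN = "KRAB_DOMAIN"
FINGER_OTHER = "FINGER_OTHER"
OUTSIDE_DOMAIN = "OUTSIDE_DOMAIN"

_FINGER_RE = re.compile(r"(C)(.{2,4}?)(C)(.{12})(H)(.{3,5}?)(H)")


@dataclass(frozen=True)
class FingerFeature:
    """One C2H2 finger: 1-based residue interval and its key positions."""

    index: int  # 1-based, N- to C-terminal
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    coordinating: tuple[int, int, int, int]  # C, C, H, H positions
    contacts: tuple[int, int, int, int]  # helix -1, 2, 3, 6 positions

    def __post_init__(self) -> None:
        if not all(self.start <= p <= self.end for p in self.contacts):
            raise ValueError("contact positions must lie inside the finger")


@dataclass
class ProteinFeatureMap:
    """Finger/linker/KRAB architecture of one ZNF protein."""

    protein_id: str
    length: int
    fingers: list[FingerFeature]
    linkers: list[tuple[int, int]]  # 1-based inclusive intervals
    krab: Optional[tuple[int, int]] = None

    def classify_residue(self, aa_pos: int) -> str:
        if not (1 <= aa_pos <= self.length):
            raise ValueError(f"residue {aa_pos} outside protein of length "
                             f"{self.length}")
        if self.krab and self.krab[0] <= aa_pos <= self.krab[1]:
            return KRAB_DOMAIN
        for f in self.fingers:
            if f.start <= aa_pos <= f.end:
                if aa_pos in f.coordinating:
                    return ZINC_COORDINATING
                if aa_pos in f.contacts:
                    return DNA_CONTACT
                return FINGER_OTHER
        for a, b in self.linkers:
            if a <= aa_pos <= b:
                return LINKER
        return OUTSIDE_DOMAIN


@dataclass
class VariantConsequence:
    """Classified impact of one single-base coding change."""

    gene_id: str
    cds_pos: int  # 1-based
    codon_ref: str
    codon_alt: str
    aa_ref: str
    aa_alt: str
    aa_pos: int
    impact: Optional[str]  # None for synonymous changes
    pop_frequencies: dict[str, float]
    max_fst: float

    @property
    def is_nonsynonymous(self) -> bool:
        return self.aa_ref != self.aa_alt

    @property
    def aa_change(self) -> str:
        return f"{self.aa_ref}{self.aa_pos}{self.aa_alt}"


def detect_c2h2_fingers(sequence: str) -> list[FingerFeature]:
    """Scan a protein sequence for C2H2 fingers, leftmost non-overlapping.

    The lazy spacer quantifiers make each match the most compact finger
    starting at its first cysteine; contact positions are His-anchored
    (offsets -7, -5, -4, -1 from the first coordinating histidine), which
    assumes the canonical twelve-residue C-H core.
    """
    bad = set(sequence) - AA_ALPHABET
    if bad:
        raise ValueError(f"non-amino-acid letters in sequence: {sorted(bad)}")
    fingers = []
    for i, m in enumerate(_FINGER_RE.finditer(sequence), start=1):
        c1 = m.start(1) + 1
        c2 = m.start(3) + 1
        h1 = m.start(5) + 1
        h2 = m.start(7) + 1
        fingers.append(
            FingerFeature(
                index=i,
                start=c1,
                end=h2,
                coordinating=(c1, c2, h1, h2),
                contacts=(h1 - 7, h1 - 5, h1 - 4, h1 - 1),
            )
        )
    return fingers


def build_feature_map(
    fingers: Sequence[FingerFeature],
    krab: Optional[tuple[int, int]],
    length: int,
    protein_id: str = "",
) -> ProteinFeatureMap:
    """Assemble the residue partition: fingers, inter-finger linkers, KRAB.

    Linkers are the maximal gaps strictly between consecutive fingers.
    Overlapping fingers, or a KRAB interval intersecting a finger, are hard
    errors.  Residues covered by none of the features classify as
    OUTSIDE_DOMAIN, so the map partitions [1, length] completely.
    """
    fingers = sorted(fingers, key=lambda f: f.start)
    for a, b in zip(fingers[:-1], fingers[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"fingers {a.index} and {b.index} overlap ({a.end} >= {b.start})"
            )
    if fingers and fingers[-1].end > length:
        raise ValueError("finger extends past the protein end")
    if krab is not None:
        for f in fingers:
            if krab[0] <= f.end and f.start <= krab[1]:
                raise ValueError("KRAB interval overlaps a finger")
    linkers = [
        (a.end + 1, b.start - 1)
        for a, b in zip(fingers[:-1], fingers[1:])
        if b.start - a.end > 1
    ]
    return ProteinFeatureMap(
        protein_id=protein_id, length=length, fingers=list(fingers),
        linkers=linkers, krab=krab,
    )


def annotate_variant(
    cds: str,
    cds_pos: int,
    ref: str,
    alt: str,
    feature_map: ProteinFeatureMap,
    gene_id: str = "",
    pop_frequencies: Optional[Mapping[str, float]] = None,
    max_fst: float = float("nan"),
) -> VariantConsequence:
    """Classify a single-base coding change by the feature it impacts.

    Translation uses the standard nuclear genetic code.  The reference
    base must match the CDS at ``cds_pos`` (1-based); ambiguous bases are
    hard errors.  Synonymous changes carry no impact class.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    if set(cds) - DNA_ALPHABET or ref not in DNA_ALPHABET or alt not in DNA_ALPHABET:
        raise ValueError("degenerate or non-ACGT bases are not supported")
    if not (1 <= cds_pos <= len(cds)):
        raise ValueError(f"cds position {cds_pos} outside CDS")
    if cds[cds_pos - 1] != ref:
        raise ValueError(
            f"reference mismatch at CDS position {cds_pos}: "
            f"expected {cds[cds_pos - 1]}, got {ref}"
        )
    aa_pos = (cds_pos + 2) // 3
    codon_start = 3 * (aa_pos - 1)
    codon_ref = cds[codon_start:codon_start + 3]
    offset = (cds_pos - 1) % 3
    codon_alt = codon_ref[:offset] + alt + codon_ref[offset + 1:]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    impact = None if aa_ref == aa_alt else feature_map.classify_residue(aa_pos)
    return VariantConsequence(
        gene_id=gene_id or feature_map.protein_id,
        cds_pos=cds_pos,
        codon_ref=codon_ref,
        codon_alt=codon_alt,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        aa_pos=aa_pos,
        impact=impact,
        pop_frequencies=dict(pop_frequencies or {}),
        max_fst=float(max_fst),
    )


def high_fst_nonsyn_report(
    consequences: Sequence[VariantConsequence],
    threshold: float = 0.15,
) -> pd.DataFrame:
    """Nonsynonymous variants with max pairwise F_ST strictly above threshold.

    Sorted by F_ST descending; columns mirror a supplementary-table layout
    (gene, CDS position, amino-acid change, impacted feature, per-population
    frequencies, max pairwise F_ST).
    """
    rows = []
    for v in consequences:
        if not v.is_nonsynonymous or not (v.max_fst > threshold):
            continue
        row = {
            "gene": v.gene_id,
            "cds_pos": v.cds_pos,
            "aa_change": v.aa_change,
            "feature": v.impact,
            "max_fst": v.max_fst,
        }
        for pop, f in sorted(v.pop_frequencies.items()):
            row[f"freq_{pop}"] = f
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("max_fst", ascending=False).reset_index(drop=True)
    return df
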