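"""Base composition and strand-skew statistics over mitogenome partitions.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), computed from
exact base counts.  Partitions follow the comparative-mitogenomics
convention: the whole genome on the H strand as deposited, every gene
partition oriented to its coding strand (so the L-strand ND6 shows its own
skew, not the mirror image), concatenated PCG/rRNA/tRNA sets, the three
codon positions of the protein-coding genes, and the control region.

Ambiguous bases (N etc.) are excluded from numerators and denominators; a
zero denominator yields an undefined (None) skew, never 0.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .codons import extract_codons
from .io import MitoGenome


@dataclass(frozen=True)
class CompositionStats:
    """Exact base counts with derived content and skew statistics."""

    a: int
    c: int
    g: int
    t: int

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def at_content(self) -> float:
        return (self.a + self.t) / self.total

    @property
    def gc_content(self) -> float:
        return (self.g + self.c) / self.total

    @property
    def at_skew(self) -> Optional[float]:
        d = self.a + self.t
        return (self.a - self.t) / d if d else None

    @property
    def gc_skew(self) -> Optional[float]:
        d = self.g + self.c
        return (self.g - self.c) / d if d else None


def base_composition(seq: str) -> CompositionStats:
    """Count A/C/G/T in a sequence, ignoring ambiguity codes."""
    cnt = Counter(seq.upper())
    stats = CompositionStats(cnt["A"], cnt["C"], cnt["G"], cnt["T"])
    if stats.total == 0:
        raise ValueError("composition undefined: no unambiguous bases")
    return stats


def skew(stats: CompositionStats) -> tuple[Optional[float], Optional[float]]:
    """(AT skew, GC skew); zero-denominator skews are None (undefined)."""
    return stats.at_skew, stats.gc_skew


@dataclass
class Partition:
    """A named concatenated subsequence of one genome, coding-strand oriented."""

    genome_id: str
    name: str
    sequence: str

    @property
    def stats(self) -> CompositionStats:
        return base_composition(self.sequence)


def codon_position_sequences(genome: MitoGenome) -> dict[int, str]:
    """Concatenate 1st/2nd/3rd codon-position sites over all PCGs.

    Only complete codons enter (the truncated terminal codon is skipped),
    read in frame from the annotated start on the coding strand; each
    position therefore holds the same number of sites.
    """
    out = {1: [], 2: [], 3: []}
    for feat in genome.features_of_kind("PCG"):
        if feat.length(genome.length) < 6:
            warnings.warn(f"{genome.id}/{feat.name}: PCG shorter than 6 nt excluded")
            continue
        codons, _ = extract_codons(genome, feat)
        for c in codons:
            out[1].append(c[0])
            out[2].append(c[1])
            out[3].append(c[2])
    return {k: "".join(v) for k, v in out.items()}


def build_partitions(genome: MitoGenome) -> list[Partition]:
    """The standard comparative partition set for one genome."""
    if not genome.has_sequence:
        raise ValueError(f"{genome.id}: partitions require a sequence")
    parts: list[Partition] = [
        Partition(genome.id, "whole", genome.sequence)
    ]
    pcg_seqs, rrna_seqs, trna_seqs = [], [], []
    for feat in genome.features:
        if feat.kind == "PCG":
            if feat.length(genome.length) < 6:
                warnings.warn(
                    f"{genome.id}/{feat.name}: PCG shorter than 6 nt excluded")
                continue
            s = genome.extract(feat)
            parts.append(Partition(genome.id, f"PCG:{feat.name}", s))
            pcg_seqs.append(s)
        elif feat.kind == "rRNA":
            rrna_seqs.append(genome.extract(feat))
        elif feat.kind == "tRNA":
            trna_seqs.append(genome.extract(feat))
    if pcg_seqs:
        parts.append(Partition(genome.id, "PCG:concat", "".join(pcg_seqs)))
        for pos, seq in codon_position_sequences(genome).items():
            parts.append(Partition(genome.id, f"codon_pos:{pos}", seq))
    if rrna_seqs:
        parts.append(Partition(genome.id, "rRNA:concat", "".join(rrna_seqs)))
    if trna_seqs:
        parts.append(Partition(genome.id, "tRNA:concat", "".join(trna_seqs)))
    cr = [f for f in genome.features if f.kind == "CR"]
    if cr:
        parts.append(Partition(genome.id, "CR", genome.extract(cr[0])))
    else:
        warnings.warn(f"{genome.id}: no control region annotated")
    return [p for p in parts if p.sequence]


def composition_table(genomes: Iterable[MitoGenome]) -> pd.DataFrame:
    """Tidy per-partition composition/skew table across genomes."""
    rows = []
    for g in genomes:
        for p in build_partitions(g):
            s = p.stats
            rows.append({
                "genome_id": g.id, "partition": p.name,
                "A": s.a, "C": s.c, "G": s.g, "T": s.t,
                "AT_content": s.at_content, "GC_content": s.gc_content,
                "AT_skew": s.at_skew, "GC_skew": s.gc_skew,
            })
    return pd.DataFrame(rows)
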