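"""Codon extraction, start/stop classification, amino-acid usage and RSCU.

All translation uses the vertebrate mitochondrial code (NCBI translation
table 2: ATA=Met, TGA=Trp, AGA/AGG=stop) via Biopython's code tables.
Leucine and serine are each split into their two synonymous families —
Leu(CUN)/Leu(UUR) and Ser(UCN)/Ser(AGY) — which is how mitogenome codon
usage is conventionally reported.

RSCU (relative synonymous codon usage) for a codon c in a synonymous
family F is ``count(c) * |F| / sum(count(F))``: 1 means the codon is used
exactly as often as expected under uniform use within its family.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio.Data import CodonTable

from .io import GeneFeature, MitoGenome

VERTEBRATE_MITO = CodonTable.unambiguous_dna_by_id[2]

BASES = "ACGT"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
STOP_CODONS = frozenset(VERTEBRATE_MITO.stop_codons)  # TAA TAG AGA AGG
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]

_AA_1TO3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


def translate(codon: str) -> Optional[str]:
    """One-letter amino acid under code 2, or None for a stop codon."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return None
    return VERTEBRATE_MITO.forward_table[codon]


def family_label(codon: str) -> Optional[str]:
    """Synonymous-family label; Leu and Ser split into their two families."""
    aa = translate(codon)
    if aa is None:
        return None
    name = _AA_1TO3[aa]
    if aa == "L":
        return "Leu(CUN)" if codon.startswith("CT") else "Leu(UUR)"
    if aa == "S":
        return "Ser(UCN)" if codon.startswith("TC") else "Ser(AGY)"
    return name


#: family label -> tuple of member codons (DNA alphabet)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    FAMILIES.setdefault(family_label(_c), ())
    FAMILIES[family_label(_c)] += (_c,)


# ---------------------------------------------------------------------------
# codon extraction


def extract_codons(genome: MitoGenome, gene: str | GeneFeature) -> tuple[list[str], str]:
    """Split a PCG into codons read 5'->3' on the coding strand.

    Returns ``(codons, remainder)`` where the remainder (0-2 nt) is the
    truncated terminal codon completed by polyadenylation in vivo.  An
    in-frame stop before the final codon triggers a misannotation warning
    but the codons are still returned.
    """
    feat = genome.feature(gene) if isinstance(gene, str) else gene
    if feat.kind != "PCG":
        raise ValueError(f"{feat.name} is not a protein-coding gene")
    seq = genome.extract(feat)
    if not seq:
        raise ValueError(f"{feat.name}: empty gene sequence")
    n_codons = len(seq) // 3
    codons = [seq[i * 3:(i + 1) * 3] for i in range(n_codons)]
    remainder = seq[n_codons * 3:]
    for i, c in enumerate(codons[:-1]):
        if c in STOP_CODONS:
            warnings.warn(
                f"{genome.id}/{feat.name}: internal stop codon {c} at codon "
                f"{i + 1} (possible misannotation)")
            break
    return codons, remainder


# ---------------------------------------------------------------------------
# start / stop classification

START_CLASSES = ("ATN", "GTG", "CTG", "other")
STOP_CLASSES = ("TAA", "TAG", "AGA/AGG", "T--", "TA-", "other")


def classify_start(codon: str) -> str:
    codon = codon.upper()
    if len(codon) == 3 and codon.startswith("AT"):
        return "ATN"
    if codon in ("GTG", "CTG"):
        return codon
    return "other"


def classify_stop(codons: list[str], remainder: str) -> str:
    """Classify the terminal codon, including truncated T--/TA- stops.

    Truncated classes apply only when the coordinate length leaves a 1- or
    2-nt remainder; AGA/AGG are valid vertebrate-mitochondrial stops but
    atypical for fish and are reported as their own class.
    """
    remainder = remainder.upper()
    if remainder:
        if remainder == "T":
            return "T--"
        if remainder == "TA":
            return "TA-"
        return "other"
    if not codons:
        return "other"
    last = codons[-1].upper()
    if last in ("TAA", "TAG"):
        return last
    if last in ("AGA", "AGG"):
        return "AGA/AGG"
    return "other"


@dataclass
class CodonCall:
    """Start/stop codon assignment for one gene."""

    gene: str
    start_codon: str
    start_class: str
    stop_codon: str
    stop_class: str


def call_gene(genome: MitoGenome, gene: str) -> CodonCall:
    feat = genome.feature(gene)
    if genome.has_sequence:
        codons, remainder = extract_codons(genome, feat)
        start = codons[0] if codons else ""
        stop_class = classify_stop(codons, remainder)
        stop = remainder if remainder else (codons[-1] if codons else "")
    else:
        # fall back on annotation when no sequence is attached
        start = feat.start_codon or ""
        stop = feat.stop_codon or ""
        if stop in ("TAA", "TAG", "AGA", "AGG"):
            stop_class = classify_stop([stop], "")
        else:
            stop_class = classify_stop([], stop)
    return CodonCall(feat.name, start, classify_start(start), stop, stop_class)


# ---------------------------------------------------------------------------
# usage statistics


def codon_usage_counts(
    genomes: Iterable[MitoGenome],
    exclude_terminal_stop: bool = True,
) -> tuple[dict[str, Counter], Counter]:
    """Sense-codon counts per genome and pooled across genomes.

    The annotated start codon is counted as given (GTG/CTG starts encode
    Met in vivo but are tallied by their nucleotide identity, matching how
    codon-usage tables are normally built); terminal stop codons and
    truncated remainders contribute nothing.
    """
    per_genome: dict[str, Counter] = {}
    pooled: Counter = Counter()
    for g in genomes:
        cnt: Counter = Counter()
        for feat in g.features_of_kind("PCG"):
            codons, _ = extract_codons(g, feat)
            if exclude_terminal_stop and codons and codons[-1] in STOP_CODONS:
                codons = codons[:-1]
            for c in codons:
                if c not in STOP_CODONS and set(c) <= set(BASES):
                    cnt[c] += 1
        per_genome[g.id] = cnt
        pooled.update(cnt)
    return per_genome, pooled


def amino_acid_frequencies(counts: Mapping[str, int]) -> pd.DataFrame:
    """Per-family amino-acid totals, frequencies and ranks (stops excluded)."""
    rows = []
    for fam, members in FAMILIES.items():
        total = sum(counts.get(c, 0) for c in members)
        rows.append({"amino_acid": fam, "count": total,
                     "family_size": len(members)})
    df = pd.DataFrame(rows)
    grand = df["count"].sum()
    df["frequency"] = df["count"] / grand if grand else 0.0
    df = df.sort_values(["count", "amino_acid"],
                        ascending=[False, True]).reset_index(drop=True)
    df["rank"] = df.index + 1
    return df


def rscu(counts: Mapping[str, int]) -> pd.DataFrame:
    """RSCU table over all 60 sense codons.

    Within each synonymous family with a nonzero total, RSCU values sum to
    the family size (mean 1); families never observed get NaN.
    """
    rows = []
    for fam, members in FAMILIES.items():
        total = sum(counts.get(c, 0) for c in members)
        for c in sorted(members):
            n = counts.get(c, 0)
            val = n * len(members) / total if total > 0 else float("nan")
            rows.append({"codon": c, "amino_acid": fam, "count": n,
                         "family_size": len(members), "rscu": val})
    return pd.DataFrame(rows).sort_values(
        ["amino_acid", "codon"]).reset_index(drop=True)


def codon_accounting(genome: MitoGenome) -> pd.DataFrame:
    """Per-gene codon counts and remainders (bookkeeping for audits)."""
    rows = []
    for feat in genome.features_of_kind("PCG"):
        codons, rem = extract_codons(genome, feat)
        rows.append({"genome_id": genome.id, "gene": feat.name,
                     "n_codons": len(codons), "remainder": len(rem),
                     "length": feat.length(genome.length)})
    return pd.DataFrame(rows)
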