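"""Gene order, rearrangement detection, overlaps, spacers and pseudogenes.

A circular gene order is a cyclic sequence of (gene, strand) pairs.  Two
orders are compared through their adjacency sets — the set of ordered
neighbour pairs around the circle — which is invariant under rotation, so
the linearization anchor (conventionally tRNA-Phe) never creates
artificial breakpoints.  The breakpoint distance is the number of
adjacencies of one order absent from the other; the displaced-gene search
finds the smallest set of genes whose removal makes the two circles
identical, which for the parrotfish-vs-canonical comparison isolates the
translocated tRNA-Met.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .io import GeneFeature, MitoGenome

OrderedGene = tuple[str, str]  # (name, strand)

#: canonical vertebrate mitogenome order (Ile-Gln-Met cluster between ND1 and ND2)
CANONICAL_VERTEBRATE_ORDER: tuple[OrderedGene, ...] = (
    ("tRNA-Phe", "H"), ("12S-rRNA", "H"), ("tRNA-Val", "H"), ("16S-rRNA", "H"),
    ("tRNA-Leu(UAA)", "H"), ("ND1", "H"), ("tRNA-Ile", "H"), ("tRNA-Gln", "L"),
    ("tRNA-Met", "H"), ("ND2", "H"), ("tRNA-Trp", "H"), ("tRNA-Ala", "L"),
    ("tRNA-Asn", "L"), ("tRNA-Cys", "L"), ("tRNA-Tyr", "L"), ("COI", "H"),
    ("tRNA-Ser(UGA)", "L"), ("tRNA-Asp", "H"), ("COII", "H"), ("tRNA-Lys", "H"),
    ("ATP8", "H"), ("ATP6", "H"), ("COIII", "H"), ("tRNA-Gly", "H"),
    ("ND3", "H"), ("tRNA-Arg", "H"), ("ND4L", "H"), ("ND4", "H"),
    ("tRNA-His", "H"), ("tRNA-Ser(GCU)", "H"), ("tRNA-Leu(UAG)", "H"),
    ("ND5", "H"), ("ND6", "L"), ("tRNA-Glu", "L"), ("Cytb", "H"),
    ("tRNA-Thr", "H"), ("tRNA-Pro", "L"), ("CR", "H"),
)

#: the parrotfish rearrangement: tRNA-Met translocated between tRNA-Ile and tRNA-Gln
PARROTFISH_ORDER: tuple[OrderedGene, ...] = tuple(
    [g for g in CANONICAL_VERTEBRATE_ORDER[:7]]  # ... ND1, tRNA-Ile
    + [("tRNA-Met", "H"), ("tRNA-Gln", "L")]
    + [g for g in CANONICAL_VERTEBRATE_ORDER[9:]]  # ND2 ...
)


@dataclass(frozen=True)
class GeneOrder:
    """Cyclic (gene, strand) order of one genome, anchored for display only."""

    genome_id: str
    genes: tuple[OrderedGene, ...]

    @classmethod
    def from_genome(cls, genome: MitoGenome, anchor: str = "tRNA-Phe") -> "GeneOrder":
        feats = sorted(genome.features, key=lambda f: f.start)
        order = [(f.name, f.strand) for f in feats]
        names = [n for n, _ in order]
        if anchor in names:
            i = names.index(anchor)
            order = order[i:] + order[:i]
        return cls(genome.id, tuple(order))

    def __str__(self) -> str:
        return "-".join(f"{n}({s})" for n, s in self.genes)

    def adjacencies(self) -> frozenset[tuple[OrderedGene, OrderedGene]]:
        n = len(self.genes)
        return frozenset(
            (self.genes[i], self.genes[(i + 1) % n]) for i in range(n)
        )


def _restrict(order: Sequence[OrderedGene], keep: set[str]) -> tuple[OrderedGene, ...]:
    return tuple(g for g in order if g[0] in keep)


def _rotation_equal(a: Sequence[OrderedGene], b: Sequence[OrderedGene]) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    la = list(a)
    for i in range(len(b)):
        if list(b[i:]) + list(b[:i]) == la:
            return True
    return False


def breakpoint_distance(a: GeneOrder | Sequence[OrderedGene],
                        b: GeneOrder | Sequence[OrderedGene]) -> int:
    """Number of strand-aware adjacencies of ``a`` absent from ``b``.

    Genes not shared by both orders are dropped with a warning; an empty
    intersection is an error.  The adjacency-set formulation is already
    rotation-invariant on the circle, so no further minimisation over
    rotations is needed (verified by the brute-force rotation oracle in the
    test suite).
    """
    ga = a.genes if isinstance(a, GeneOrder) else tuple(a)
    gb = b.genes if isinstance(b, GeneOrder) else tuple(b)
    common = {n for n, _ in ga} & {n for n, _ in gb}
    if not common:
        raise ValueError("gene orders share no genes")
    if len(common) < len(ga) or len(common) < len(gb):
        warnings.warn("unmatched genes dropped from breakpoint comparison")
    ra = GeneOrder("a", _restrict(ga, common))
    rb = GeneOrder("b", _restrict(gb, common))
    return len(ra.adjacencies() - rb.adjacencies())


def _first_disagreement(ga: Sequence[OrderedGene],
                        gb: Sequence[OrderedGene]) -> Optional[str]:
    """Gene of ``ga`` at the first slot (walking from a shared start gene)
    where the two linearized orders disagree."""
    names_a = [n for n, _ in ga]
    start = next((n for n, _ in gb if n in names_a), None)
    if start is None:
        return None
    ia = names_a.index(start)
    ib = [n for n, _ in gb].index(start)
    la = list(ga[ia:]) + list(ga[:ia])
    lb = list(gb[ib:]) + list(gb[:ib])
    for x, y in zip(la, lb):
        if x != y:
            return x[0]
    return None


def find_displaced_genes(a: GeneOrder | Sequence[OrderedGene],
                         b: GeneOrder | Sequence[OrderedGene],
                         max_set: int = 4) -> set[str]:
    """Smallest gene set whose removal makes the two circular orders equal.

    Candidates are limited to genes participating in broken adjacencies;
    subsets are tried in increasing size (exhaustive up to ``max_set``,
    greedy beyond), and each candidate removal is verified by cyclic
    equality of the reduced orders.

    An adjacent transposition admits two equally small explanations (either
    neighbour may have moved).  Ties are broken by a fixed convention:
    walking the circle from a shared start gene, the displaced gene is the
    one occupying the first slot where the query order ``a`` deviates from
    the reference ``b`` — which names the translocated gene the way such
    rearrangements are conventionally described.
    """
    ga = a.genes if isinstance(a, GeneOrder) else tuple(a)
    gb = b.genes if isinstance(b, GeneOrder) else tuple(b)
    common = {n for n, _ in ga} & {n for n, _ in gb}
    ga, gb = _restrict(ga, common), _restrict(gb, common)
    if _rotation_equal(ga, gb):
        return set()
    adj_a = GeneOrder("a", ga).adjacencies()
    adj_b = GeneOrder("b", gb).adjacencies()
    broken = adj_a ^ adj_b
    candidates = sorted({g[0] for pair in broken for g in pair})
    preferred = _first_disagreement(ga, gb)
    for k in range(1, min(max_set, len(candidates)) + 1):
        solutions = []
        for combo in combinations(candidates, k):
            keep = common - set(combo)
            if _rotation_equal(_restrict(ga, keep), _restrict(gb, keep)):
                solutions.append(set(combo))
        if solutions:
            for sol in solutions:
                if preferred in sol:
                    return sol
            return solutions[0]
    # greedy fallback: repeatedly remove the gene involved in most breaks
    keep = set(common)
    removed: set[str] = set()
    while not _rotation_equal(_restrict(ga, keep), _restrict(gb, keep)):
        counts: dict[str, int] = {}
        broken = (GeneOrder("a", _restrict(ga, keep)).adjacencies()
                  ^ GeneOrder("b", _restrict(gb, keep)).adjacencies())
        for pair in broken:
            for g in pair:
                counts[g[0]] = counts.get(g[0], 0) + 1
        worst = max(sorted(counts), key=lambda g: counts[g])
        keep.discard(worst)
        removed.add(worst)
    return removed


# ---------------------------------------------------------------------------
# adjacency / overlap / spacer accounting


@dataclass
class AdjacencyRecord:
    """Neighbouring feature pair with its spacer or overlap length."""

    genome_id: str
    upstream: str
    downstream: str
    gap: int           # positive spacer, negative overlap, 0 abutting
    sequence: str = ""  # spacer/overlap nucleotides on the H strand

    @property
    def spacer_bp(self) -> int:
        return max(self.gap, 0)

    @property
    def overlap_bp(self) -> int:
        return max(-self.gap, 0)


def adjacency_table(genome: MitoGenome) -> tuple[list[AdjacencyRecord], list[str]]:
    """Spacer/overlap record per consecutive feature pair on the circle.

    Returns ``(records, contained)`` where ``contained`` lists features fully
    nested inside another (excluded from the adjacency walk).  The circular
    last-to-first adjacency is included; sequences are attached when the
    genome carries one.
    """
    feats = sorted(genome.features, key=lambda f: (f.start, -f.end))
    if len(feats) < 2:
        raise ValueError(f"{genome.id}: need at least two features")
    n = genome.length
    contained: list[str] = []
    walk: list[GeneFeature] = []
    for f in feats:
        if walk and not f.wraps and not walk[-1].wraps and f.end <= walk[-1].end:
            contained.append(f.name)
            continue
        walk.append(f)
    records: list[AdjacencyRecord] = []
    for i, up in enumerate(walk):
        down = walk[(i + 1) % len(walk)]
        if i + 1 < len(walk):
            gap = down.start - up.end - 1
        else:
            gap = (down.start - up.end - 1) % n  # circular closure
            if gap > n / 2:  # a long way round means terminal overlap
                gap -= n
        seq = ""
        if genome.has_sequence and gap != 0:
            if gap > 0:
                s = up.end + 1
                e = down.start - 1
            else:
                s = down.start
                e = up.end
            s = (s - 1) % n + 1
            e = (e - 1) % n + 1
            seq = genome.region(s, e)
        records.append(AdjacencyRecord(genome.id, up.name, down.name, gap, seq))
    return records, contained


def adjacency_dataframe(genomes: Iterable[MitoGenome]) -> pd.DataFrame:
    rows = []
    for g in genomes:
        recs, contained = adjacency_table(g)
        for r in recs:
            rows.append({
                "genome_id": r.genome_id, "upstream": r.upstream,
                "downstream": r.downstream, "intergenic": r.gap,
                "spacer_bp": r.spacer_bp, "overlap_bp": r.overlap_bp,
                "sequence": r.sequence,
            })
        for name in contained:
            rows.append({"genome_id": g.id, "upstream": name,
                         "downstream": "", "intergenic": 0, "spacer_bp": 0,
                         "overlap_bp": 0, "sequence": "contained"})
    return pd.DataFrame(rows)


def circular_bookkeeping(genome: MitoGenome) -> dict:
    """Check sum(lengths) - sum(overlaps) + sum(spacers) == genome length."""
    recs, contained = adjacency_table(genome)
    walked = {r.upstream for r in recs}
    total_len = sum(f.length(genome.length) for f in genome.features
                    if f.name in walked)
    overlaps = sum(r.overlap_bp for r in recs)
    spacers = sum(r.spacer_bp for r in recs)
    return {
        "genome_id": genome.id,
        "sum_lengths": total_len, "sum_overlaps": overlaps,
        "sum_spacers": spacers, "genome_length": genome.length,
        "identity_holds": total_len - overlaps + spacers == genome.length,
        "contained_features": contained,
    }


def overlap_motifs(genomes: Iterable[MitoGenome],
                   pair: tuple[str, str]) -> pd.DataFrame:
    """Overlap subsequence (H strand) for a gene pair, grouped by identity."""
    rows = []
    for g in genomes:
        recs, _ = adjacency_table(g)
        for r in recs:
            if (r.upstream, r.downstream) == pair and r.overlap_bp > 0:
                rows.append({"genome_id": g.id, "motif": r.sequence,
                             "overlap_bp": r.overlap_bp})
    df = pd.DataFrame(rows, columns=["genome_id", "motif", "overlap_bp"])
    if not df.empty:
        df["group_size"] = df.groupby("motif")["motif"].transform("size")
    return df


# ---------------------------------------------------------------------------
# pseudogene candidates


def _global_identity(a: str, b: str) -> float:
    """Needleman-Wunsch identity (matches / aligned columns), unit scores."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return matches / len(s1)


def _shuffle_null(rng: np.random.Generator, spacer: str,
                  targets: Sequence[str], n_shuffles: int,
                  quantile: float) -> float:
    """Null distribution quantile for the BEST-of-all-tRNAs identity.

    Each shuffled copy of the spacer is scored against every target in
    both orientations and the maximum taken, mirroring the selection step
    applied to the real spacer; otherwise the max-over-targets bias would
    make the null too permissive.
    """
    chars = np.array(list(spacer))
    vals = []
    for _ in range(n_shuffles):
        rng.shuffle(chars)
        s = "".join(chars)
        rc = str(Seq(s).reverse_complement())
        vals.append(max(_global_identity(q, t)
                        for t in targets for q in (s, rc)))
    return float(np.quantile(vals, quantile))


def pseudogene_candidates(genome: MitoGenome, min_len: int = 30,
                          threshold: float = 0.5, n_shuffles: int = 30,
                          null_quantile: float = 1.0,
                          seed: int = 0) -> pd.DataFrame:
    """Flag long intergenic spacers resembling a tRNA of the same genome.

    Every spacer of at least ``min_len`` bp is globally aligned against
    each annotated tRNA (both orientations of the spacer).  A spacer is
    labelled a putative pseudogene of its best-matching tRNA when the
    identity reaches ``threshold`` AND exceeds the ``null_quantile`` of a
    seeded shuffle null (best-of-all-tRNAs identities of ``n_shuffles``
    shuffled copies of the spacer; the default takes their maximum) — global-alignment identity between
    unrelated short sequences sits near 0.5, so the null gate is what
    separates a degenerate gene copy from background.
    """
    if not genome.has_sequence:
        raise ValueError(f"{genome.id}: pseudogene scan requires a sequence")
    rng = np.random.default_rng(seed)
    recs, _ = adjacency_table(genome)
    trnas = {f.name: genome.extract(f) for f in genome.features_of_kind("tRNA")}
    rows = []
    for r in recs:
        if r.spacer_bp < min_len:
            continue
        spacer = r.sequence
        rc = str(Seq(spacer).reverse_complement())
        best_name, best_sim = "", 0.0
        for name, tseq in sorted(trnas.items()):
            for query in (spacer, rc):
                sim = _global_identity(query, tseq)
                if sim > best_sim:
                    best_name, best_sim = name, sim
        null_q = (_shuffle_null(rng, spacer, list(trnas.values()),
                                n_shuffles, null_quantile)
                  if best_name else 1.0)
        label = (f"psi-{best_name}"
                 if best_sim >= threshold and best_sim > null_q else "")
        rows.append({
            "genome_id": genome.id, "upstream": r.upstream,
            "downstream": r.downstream, "spacer_bp": r.spacer_bp,
            "best_trna": best_name, "similarity": best_sim,
            "null_q": null_q, "label": label,
        })
    return pd.DataFrame(rows, columns=["genome_id", "upstream", "downstream",
                                       "spacer_bp", "best_trna", "similarity",
                                       "null_q", "label"])
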