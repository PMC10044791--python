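"""Gene order comparison, adjacency accounting and pseudogene scan."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import pytest

from mitocomp.architecture import (CANONICAL_VERTEBRATE_ORDER, PARROTFISH_ORDER,
                                   GeneOrder, adjacency_table,
                                   breakpoint_distance, circular_bookkeeping,
                                   find_displaced_genes, overlap_motifs,
                                   pseudogene_candidates)
from mitocomp.simulate import GenomeSpec, make_genome


def brute_force_breakpoints(a, b):
    """Oracle: directed adjacencies of a missing from b, minimised over all
    rotations of b (independent list-walk implementation)."""
    def adj(order):
        n = len(order)
        return [(order[i], order[(i + 1) % n]) for i in range(n)]
    best = None
    for r in range(len(b)):
        rb = list(b[r:]) + list(b[:r])
        missing = sum(1 for pair in adj(list(a)) if pair not in adj(rb))
        best = missing if best is None else min(best, missing)
    return best


def test_identical_orders_have_zero_breakpoints():
    assert breakpoint_distance(PARROTFISH_ORDER, PARROTFISH_ORDER) == 0
    rotated = PARROTFISH_ORDER[5:] + PARROTFISH_ORDER[:5]
    assert breakpoint_distance(PARROTFISH_ORDER, rotated) == 0


def test_parrotfish_vs_canonical_matches_brute_force():
    d = breakpoint_distance(PARROTFISH_ORDER, CANONICAL_VERTEBRATE_ORDER)
    assert d == brute_force_breakpoints(PARROTFISH_ORDER,
                                        CANONICAL_VERTEBRATE_ORDER)
    assert d == 3


def test_breakpoint_distance_is_symmetric():
    pairs = [(PARROTFISH_ORDER, CANONICAL_VERTEBRATE_ORDER)]
    toy_a = (("a", "H"), ("b", "H"), ("c", "L"), ("d", "H"), ("e", "H"))
    toy_b = (("a", "H"), ("c", "L"), ("b", "H"), ("d", "H"), ("e", "H"))
    pairs.append((toy_a, toy_b))
    for x, y in pairs:
        assert breakpoint_distance(x, y) == breakpoint_distance(y, x)


def test_strand_flip_counts_as_disrupted_adjacency():
    toy = (("a", "H"), ("b", "H"), ("c", "H"), ("d", "H"), ("e", "H"))
    flipped = (("a", "H"), ("b", "H"), ("c", "L"), ("d", "H"), ("e", "H"))
    d = breakpoint_distance(toy, flipped)
    assert d == brute_force_breakpoints(toy, flipped) == 2


def test_displaced_gene_set_is_trna_met(table1):
    order = GeneOrder.from_genome(table1)
    assert find_displaced_genes(order, CANONICAL_VERTEBRATE_ORDER) == {"tRNA-Met"}
    assert find_displaced_genes(CANONICAL_VERTEBRATE_ORDER,
                                CANONICAL_VERTEBRATE_ORDER) == set()


def test_two_independent_moves_both_reported():
    base = tuple((c, "H") for c in "abcdefgh")
    # move b between e and f, and h between c and d
    moved = tuple((c, "H") for c in "acdhebfg")
    got = find_displaced_genes(moved, base)
    assert got == {"b", "h"}


def test_adjacency_reproduces_printed_intergenic_column(table1):
    """Entry-for-entry agreement with the packaged table's IGS column."""
    with resources.as_file(resources.files("mitocomp.data")
                           / "calotomus_carolinus_table.tsv") as p:
        printed = pd.read_csv(p, sep="\t")
    expected = dict(zip(printed["gene"], printed["intergenic"]))
    recs, contained = adjacency_table(table1)
    assert contained == []
    for r in recs:
        assert r.gap == expected[r.upstream], r.upstream
    gaps = {(r.upstream, r.downstream): r.gap for r in recs}
    assert gaps[("ATP8", "ATP6")] == -16
    assert gaps[("ND4L", "ND4")] == -7
    assert gaps[("ND5", "ND6")] == -4
    assert gaps[("tRNA-Gln", "ND2")] == 68


def test_circular_bookkeeping_identity(table1, synthetic_genome, family):
    """Sum of lengths - overlaps + spacers equals the genome length."""
    for g in [table1, synthetic_genome] + family[0]:
        assert circular_bookkeeping(g)["identity_holds"], g.id


def test_nested_feature_reported_as_containment(synthetic_genome):
    import dataclasses
    from mitocomp.io import GeneFeature, MitoGenome
    g = MitoGenome(id="nest", sequence="A" * 1000, features=[
        GeneFeature("ND1", "PCG", 1, 600, "H"),
        GeneFeature("tRNA-Met", "tRNA", 100, 169, "H"),
        GeneFeature("ND2", "PCG", 601, 1000, "H"),
    ])
    recs, contained = adjacency_table(g)
    assert contained == ["tRNA-Met"]
    assert {r.upstream for r in recs} == {"ND1", "ND2"}


def test_overlap_motifs_recovered_and_grouped(synthetic_genome, truth):
    df = overlap_motifs([synthetic_genome], ("ATP8", "ATP6"))
    assert df["motif"].tolist() == [truth["overlaps"]["ATP8-ATP6"]["motif"]]
    assert df["motif"].iloc[0] == "CTGACCTTGGCACTAG"
    # same planted motif in two genomes -> one conservation group of size 2
    g2, _ = make_genome(GenomeSpec(seed=99, genome_id="other"))
    df2 = overlap_motifs([synthetic_genome, g2], ("ND4L", "ND4"))
    assert df2["group_size"].tolist() == [2, 2]
    # a non-overlapping pair yields no entry
    assert overlap_motifs([synthetic_genome], ("COI", "COII")).empty


def test_planted_pseudo_trna_met_is_labelled(synthetic_genome):
    df = pseudogene_candidates(synthetic_genome)
    row = df[df["upstream"] == "tRNA-Gln"].iloc[0]
    assert row["label"] == "psi-tRNA-Met"
    assert row["best_trna"] == "tRNA-Met"
    assert row["similarity"] > 0.7
    # short spacers are not evaluated at all
    assert (df["spacer_bp"] >= 30).all()


def test_random_spacer_stays_unlabelled(synthetic_genome):
    """Overwriting the pseudogene spacer with random bases removes the label."""
    rng = np.random.default_rng(123)
    g = synthetic_genome
    gln = g.feature("tRNA-Gln")
    nd2 = g.feature("ND2")
    rand = "".join("ACGT"[i] for i in rng.choice(4, nd2.start - gln.end - 1))
    seq = g.sequence[:gln.end] + rand + g.sequence[nd2.start - 1:]
    from mitocomp.io import MitoGenome
    g2 = MitoGenome(id="rand", sequence=seq, features=list(g.features))
    df = pseudogene_candidates(g2)
    row = df[df["upstream"] == "tRNA-Gln"].iloc[0]
    assert row["label"] == ""
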