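"""Nei-Gojobori counting, JC/K2P corrections and distance matrices."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest

from mitocomp.codons import SENSE_CODONS, STOP_CODONS, translate
from mitocomp.selection import (distances, gene_omega, jukes_cantor,
                                k2p_from_pq, ng_pairwise, ng_site_counts)
from mitocomp.simulate import EvolSpec, evolve_codons, random_coding_sequence

BASES = "ACGT"


def oracle_site_counts(codon):
    """Independent brute force: enumerate all nine single-base mutants."""
    syn_sites = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            m = codon[:pos] + b + codon[pos + 1:]
            if m in STOP_CODONS:
                continue
            valid += 1
            syn += translate(m) == translate(codon)
        if valid:
            syn_sites += syn / valid
    return 3.0 - syn_sites, syn_sites


def oracle_pair_differences(a, b):
    """Independent path enumeration with stop-paths excluded."""
    diff = [i for i in range(3) if a[i] != b[i]]
    res = []
    for order in permutations(diff):
        cur, nd, sd, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate(nxt) == translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            res.append((nd, sd))
    if not res:
        return None
    return tuple(np.mean(res, axis=0))


def test_site_counts_match_enumeration_for_all_sense_codons():
    for codon in SENSE_CODONS:
        n, s = ng_site_counts(codon)
        n_o, s_o = oracle_site_counts(codon)
        assert n == pytest.approx(n_o) and s == pytest.approx(s_o), codon
        assert n + s == pytest.approx(3.0)


def test_site_counts_known_values():
    # Phe TTT: only the third position has a synonymous mutant (TTC)
    assert ng_site_counts("TTT")[1] == pytest.approx(1 / 3)
    # Met ATG in code 2: ATA is also Met -> one of three third-position
    # mutants synonymous
    assert ng_site_counts("ATG")[1] == pytest.approx(1 / 3)
    # four-fold third position contributes one full synonymous site
    assert ng_site_counts("GGA")[1] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="stop"):
        ng_site_counts("TAA")


def test_pairwise_identical_and_single_change():
    rp = ng_pairwise("ATGGCA", "ATGGCA")
    assert (rp.Nd, rp.Sd, rp.dN, rp.dS) == (0, 0, -0.0, -0.0)
    # one synonymous third-position change in 100 codons: closed form
    a = random_coding_sequence(100, seed=3)
    b = a[:5] + {"A": "G", "G": "A", "C": "T", "T": "C"}[a[5]] + a[6:]
    rp = ng_pairwise(a, b)
    if rp.Sd == 1.0:  # transition at pos 3 is synonymous for most codons
        assert rp.dN == pytest.approx(0.0)
        assert rp.dS == pytest.approx(jukes_cantor(1.0 / rp.S))


def test_multihit_codons_average_over_stop_free_paths():
    for x, y in [("CCT", "CAA"), ("GGA", "AAA"), ("TTT", "GCT"),
                 ("CGA", "CTT"), ("ATG", "TGA")]:
        seq_a, seq_b = "ATG" + x, "ATG" + y
        rp = ng_pairwise(seq_a, seq_b)
        oracle = oracle_pair_differences(x, y)
        if oracle is None:
            assert rp.n_codons == 1  # only the shared ATG was comparable
        else:
            assert (rp.Nd, rp.Sd) == (pytest.approx(oracle[0]),
                                      pytest.approx(oracle[1]))


def test_pairwise_is_symmetric():
    a = random_coding_sequence(150, seed=10)
    b = evolve_codons(a, EvolSpec(seed=11, n_taxa=1, d=0.5, kappa=1.0,
                                  omega=0.5))["t1"]
    r1, r2 = ng_pairwise(a, b), ng_pairwise(b, a)
    assert r1.Nd == pytest.approx(r2.Nd)
    assert r1.Sd == pytest.approx(r2.Sd)
    assert r1.N == pytest.approx(r2.N)


def test_ambiguous_codons_dropped_pairwise():
    rp = ng_pairwise("ATGNNNGCA", "ATGGGAGCA")
    assert rp.n_codons == 2
    assert rp.N + rp.S == pytest.approx(6.0)


def test_site_count_invariant_n_plus_s():
    a = random_coding_sequence(80, seed=21)
    b = random_coding_sequence(80, seed=22)
    rp = ng_pairwise(a, b)
    comparable = rp.n_codons
    assert rp.N + rp.S == pytest.approx(3.0 * comparable)


def test_jukes_cantor_domain():
    assert jukes_cantor(0.0) == 0.0
    assert jukes_cantor(0.75) is None
    assert jukes_cantor(0.1) == pytest.approx(-0.75 * np.log(1 - 0.4 / 3))


def test_omega_recovery_seeded_example():
    """True omega 0.1 (500 codons, 10 taxa) is recovered in [0.07, 0.13]."""
    root = random_coding_sequence(500, seed=17)
    aln = evolve_codons(root, EvolSpec(seed=23, n_taxa=10, d=0.15,
                                       kappa=1.0, omega=0.1))
    res = gene_omega(aln)
    assert 0.07 <= res["omega"] <= 0.13
    assert res["selection"] == "purifying"


def test_duplicate_taxon_barely_moves_omega():
    root = random_coding_sequence(300, seed=31)
    aln = evolve_codons(root, EvolSpec(seed=37, n_taxa=6, d=0.2,
                                       kappa=1.0, omega=0.3))
    base = gene_omega(aln)["omega"]
    aln["t7"] = aln["t1"]
    dup = gene_omega(aln)
    assert dup["n_pairs"] == 21
    assert dup["omega"] == pytest.approx(base, rel=0.15)


def test_biopython_ng86_agrees_on_moderate_divergence():
    """Cross-check against an independent NG86 implementation; tolerances
    reflect that the reference does not exclude stop mutants from site
    denominators."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
    from Bio.Data import CodonTable
    a = random_coding_sequence(200, seed=9)
    b = evolve_codons(a, EvolSpec(seed=31, n_taxa=1, d=0.4, kappa=1.0,
                                  omega=0.3))["t1"]
    dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86",
                       codon_table=CodonTable.unambiguous_dna_by_id[2])
    rp = ng_pairwise(a, b)
    assert rp.dN == pytest.approx(dn, rel=0.15, abs=0.01)
    assert rp.dS == pytest.approx(ds, rel=0.15, abs=0.01)


def test_distance_closed_forms():
    # 1 transition per 100 sites
    a = "A" * 100
    b = "G" + "A" * 99
    dm = distances({"x": a, "y": b, "z": a, "w": a})
    assert dm.p[0, 1] == pytest.approx(0.01)
    assert dm.k2p[0, 1] == pytest.approx(-0.5 * np.log(0.98), abs=1e-9)
    assert dm.p[0, 2] == 0.0
    # P = Q = 0.1 closed form
    k = k2p_from_pq(0.1, 0.1)
    assert k == pytest.approx(-0.5 * np.log(0.7) - 0.25 * np.log(0.8))
    assert np.isnan(k2p_from_pq(0.5, 0.4))


def test_distances_pairwise_deletion_and_symmetry():
    dm = distances({"x": "ACGTN", "y": "ACGAN", "z": "ACGTA", "w": "ACGTA"})
    assert dm.p[0, 1] == pytest.approx(0.25)  # N column dropped pairwise
    assert np.allclose(dm.p, dm.p.T)
    assert np.all(np.diag(dm.p) == 0)
    phylip = dm.to_phylip("p")
    assert phylip.splitlines()[0] == "4"
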