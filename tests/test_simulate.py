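"""The synthetic-data generator: determinism, planted truth, evolution."""

from __future__ import annotations

import numpy as np
import pytest

from mitocomp.codons import STOP_CODONS, extract_codons, translate
from mitocomp.composition import base_composition
from mitocomp.simulate import (DEFAULT_OVERLAP_MOTIFS, EvolSpec, GenomeSpec,
                               base_probs, codon_joint, evolve_codons,
                               evolve_sequences, expected_p_distance,
                               make_genome, make_genome_family,
                               random_coding_sequence, saturated_alignment)


def test_same_seed_reproduces_identical_genome(synthetic_genome):
    g2, _ = make_genome(GenomeSpec(seed=7))
    assert g2.sequence == synthetic_genome.sequence
    assert [f.name for f in g2.features] == [f.name for f in
                                             synthetic_genome.features]


def test_truth_record_matches_genome(synthetic_genome, truth):
    """Everything the truth record claims is verifiable in the genome."""
    order = [(f.name, f.strand) for f in synthetic_genome.features]
    assert order == [tuple(x) for x in truth["gene_order"]]
    assert truth["genome_length"] == synthetic_genome.length
    # stop codons sit at the annotated gene ends
    for gene, stop in truth["stops"].items():
        codons, rem = extract_codons(synthetic_genome, gene)
        planted = stop or "TAA"
        tail = (codons[-1] if not rem else rem)
        coding = synthetic_genome.extract(gene)
        assert coding.endswith(planted), gene
    # CSB plants are where the truth record says
    cr = synthetic_genome.extract("CR")
    for block, info in truth["csb"].items():
        assert cr[info["start_in_cr"] - 1:info["end_in_cr"]] == info["sequence"]
    # psi spacer coordinates match the tRNA-Gln..ND2 gap
    psi = truth["psi_spacer"]
    assert psi["start"] == synthetic_genome.feature("tRNA-Gln").end + 1
    assert psi["end"] == synthetic_genome.feature("ND2").start - 1


def test_parrotfish_template_gene_order(synthetic_genome):
    names = [f.name for f in synthetic_genome.features]
    i = names.index("tRNA-Ile")
    assert names[i:i + 3] == ["tRNA-Ile", "tRNA-Met", "tRNA-Gln"]


def test_vertebrate_template_gene_order():
    g, _ = make_genome(GenomeSpec(seed=3, template="vertebrate"))
    names = [f.name for f in g.features]
    i = names.index("tRNA-Ile")
    assert names[i:i + 3] == ["tRNA-Ile", "tRNA-Gln", "tRNA-Met"]
    assert g.completeness_report()["complete_37"]


def test_no_internal_stops_in_generated_pcgs(synthetic_genome):
    for feat in synthetic_genome.features_of_kind("PCG"):
        codons, _ = extract_codons(synthetic_genome, feat)
        assert all(c not in STOP_CODONS for c in codons[:-1]), feat.name


def test_codon_joint_matches_targets_exactly():
    """The solved 60-codon distribution reproduces the position-averaged
    base marginals to numerical precision (deterministic, no sampling)."""
    p = base_probs(0.55, 0.05, -0.25)
    joint, marg = codon_joint(p, {"A": 1.7, "T": 1.2, "C": 0.9, "G": 0.45})
    assert joint.sum() == pytest.approx(1.0)
    np.testing.assert_allclose(marg.mean(axis=0), p, atol=5e-4)
    at3 = marg[2][0] + marg[2][3]
    assert at3 > marg[2][1] + marg[2][2]  # wobble AT bias


def test_infeasible_plans_raise():
    with pytest.raises(ValueError, match="motif length"):
        make_genome(GenomeSpec(seed=1, overlap_motifs={
            **DEFAULT_OVERLAP_MOTIFS, ("ATP8", "ATP6"): "ACGT"}))
    with pytest.raises(ValueError, match="non-positive"):
        base_probs(0.5, -1.0, 0.0)  # AT skew of -1 leaves no A at all


def test_evolution_at_zero_distance_is_identity():
    root = "ACGT" * 250
    aln = evolve_sequences(root, EvolSpec(seed=1, n_taxa=5, d=0.0))
    assert all(s == root for s in aln.values())


def test_star_tree_pairwise_divergence_matches_closed_form():
    rng = np.random.default_rng(4)
    root = "".join("ACGT"[i] for i in rng.choice(4, 60000))
    aln = evolve_sequences(root, EvolSpec(seed=8, n_taxa=4, d=0.05, kappa=2.0))
    seqs = list(aln.values())
    ps = []
    for i in range(4):
        for j in range(i + 1, 4):
            a = np.frombuffer(seqs[i].encode(), np.uint8)
            b = np.frombuffer(seqs[j].encode(), np.uint8)
            ps.append((a != b).mean())
    assert np.mean(ps) == pytest.approx(expected_p_distance(0.1, 2.0), abs=0.005)


def test_symmetric_tree_requires_power_of_two():
    with pytest.raises(ValueError, match="power of two"):
        evolve_sequences("ACGT" * 10, EvolSpec(seed=1, n_taxa=6,
                                               tree="symmetric", d=0.1))
    aln = evolve_sequences("ACGT" * 10, EvolSpec(seed=1, n_taxa=8,
                                                 tree="symmetric", d=0.1))
    assert len(aln) == 8


def test_gamma_heterogeneity_spreads_site_entropy():
    from mitocomp.saturation import site_entropy_profile
    root = "ACGT" * 1000
    hom = evolve_sequences(root, EvolSpec(seed=6, n_taxa=8, d=1.0))
    het = evolve_sequences(root, EvolSpec(seed=6, n_taxa=8, d=1.0,
                                          gamma_alpha=0.2))
    v_hom = np.var(site_entropy_profile(list(hom.values())))
    v_het = np.var(site_entropy_profile(list(het.values())))
    assert v_het > v_hom


def test_codon_model_omega_zero_is_purely_synonymous():
    root = random_coding_sequence(200, seed=2)
    aln = evolve_codons(root, EvolSpec(seed=3, n_taxa=4, d=1.0, kappa=1.0,
                                       omega=0.0))
    prot = [translate(root[i:i + 3]) for i in range(0, len(root), 3)]
    for seq in aln.values():
        assert [translate(seq[i:i + 3])
                for i in range(0, len(seq), 3)] == prot


def test_codon_model_never_emits_stops():
    root = random_coding_sequence(300, seed=5)
    aln = evolve_codons(root, EvolSpec(seed=6, n_taxa=6, d=5.0, kappa=2.0,
                                       omega=1.0))
    for seq in aln.values():
        assert all(seq[i:i + 3] not in STOP_CODONS
                   for i in range(0, len(seq), 3))


def test_codon_model_requires_omega_and_clean_root():
    with pytest.raises(ValueError, match="omega"):
        evolve_codons("ATG", EvolSpec(seed=1, n_taxa=2, d=0.1))
    with pytest.raises(ValueError, match="stop"):
        evolve_codons("ATGTAA", EvolSpec(seed=1, n_taxa=2, d=0.1, omega=0.5))


def test_neutral_codon_model_recovers_omega_one():
    from mitocomp.selection import gene_omega
    root = random_coding_sequence(600, seed=12)
    aln = evolve_codons(root, EvolSpec(seed=13, n_taxa=8, d=0.2, kappa=1.0,
                                       omega=1.0))
    assert gene_omega(aln)["omega"] == pytest.approx(1.0, rel=0.15)


def test_saturated_alignment_is_seed_deterministic():
    a = saturated_alignment(6, 100, seed=9)
    b = saturated_alignment(6, 100, seed=9)
    assert a == b


def test_family_shares_annotations_and_diverges(family):
    genomes, truth = family
    assert len(genomes) == truth["n_taxa"]
    lengths = {g.length for g in genomes}
    assert lengths == {truth["genome_length"]}
    a, b = genomes[0].sequence, genomes[1].sequence
    frac_diff = np.mean([x != y for x, y in zip(a, b)])
    assert 0.0 < frac_diff < 0.5
    # CR diverges much faster than the rest
    cr = genomes[0].feature("CR")
    cr_diff = np.mean([x != y for x, y in
                       zip(a[cr.start - 1:cr.end], b[cr.start - 1:cr.end])])
    assert cr_diff > 3 * frac_diff
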