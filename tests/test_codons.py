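"""Codon extraction, start/stop classes, amino-acid usage and RSCU."""

from __future__ import annotations

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp.codons import (FAMILIES, SENSE_CODONS, STOP_CODONS,
                             amino_acid_frequencies, classify_start,
                             classify_stop, codon_usage_counts, extract_codons,
                             rscu, translate)
from mitocomp.io import GeneFeature, MitoGenome


def test_code_two_oddities():
    """Vertebrate-mito specifics: ATA=Met, TGA=Trp, AGA/AGG are stops."""
    assert translate("ATA") == "M"
    assert translate("TGA") == "W"
    assert STOP_CODONS == {"TAA", "TAG", "AGA", "AGG"}
    assert len(SENSE_CODONS) == 60


def test_leu_and_ser_are_split_families():
    assert set(FAMILIES["Leu(CUN)"]) == {"CTA", "CTC", "CTG", "CTT"}
    assert set(FAMILIES["Leu(UUR)"]) == {"TTA", "TTG"}
    assert set(FAMILIES["Ser(AGY)"]) == {"AGC", "AGT"}
    assert len(FAMILIES["Ser(UCN)"]) == 4


def test_extract_codons_counts_on_table1_geometry(synthetic_genome):
    codons, rem = extract_codons(synthetic_genome, "ND5")
    assert (len(codons), rem) == (614, "")
    codons, rem = extract_codons(synthetic_genome, "ATP6")
    assert len(codons) == 229 and rem == "TA"
    codons, rem = extract_codons(synthetic_genome, "COII")
    assert rem == "T"


def test_extract_codons_rejects_non_pcg(synthetic_genome):
    with pytest.raises(ValueError, match="not a protein-coding"):
        extract_codons(synthetic_genome, "tRNA-Met")


def test_internal_stop_triggers_misannotation_warning():
    g = MitoGenome(id="x", sequence="ATGTAAAAATAG",
                   features=[GeneFeature("ND1", "PCG", 1, 12, "H")])
    with pytest.warns(UserWarning, match="internal stop"):
        extract_codons(g, "ND1")


@pytest.mark.parametrize("codon, cls", [
    ("ATG", "ATN"), ("ATA", "ATN"), ("ATT", "ATN"),
    ("GTG", "GTG"), ("CTG", "CTG"), ("TTG", "other"),
])
def test_start_classification(codon, cls):
    assert classify_start(codon) == cls


@pytest.mark.parametrize("codons, rem, cls", [
    (["ATG", "TAA"], "", "TAA"),
    (["ATG", "TAG"], "", "TAG"),
    (["ATG", "AGA"], "", "AGA/AGG"),
    (["ATG"], "T", "T--"),
    (["ATG"], "TA", "TA-"),
    (["ATG"], "G", "other"),
    (["ATG", "AAA"], "", "other"),
])
def test_stop_classification(codons, rem, cls):
    assert classify_stop(codons, rem) == cls


def test_amino_acid_frequencies_toy_counts():
    counts = Counter({"CTA": 1, "CTG": 1, "GCC": 1})  # Leu(CUN) x2, Ala x1
    df = amino_acid_frequencies(counts).set_index("amino_acid")
    assert df.loc["Leu(CUN)", "count"] == 2
    assert df.loc["Ala", "count"] == 1
    assert df.loc["Leu(CUN)", "rank"] == 1


def test_uniform_codon_usage_gives_family_size_proportional_frequencies():
    counts = Counter({c: 1 for c in SENSE_CODONS})
    df = amino_acid_frequencies(counts).set_index("amino_acid")
    for fam, members in FAMILIES.items():
        assert df.loc[fam, "count"] == len(members)
        assert df.loc[fam, "frequency"] == pytest.approx(len(members) / 60)


def test_rscu_closed_forms():
    equal = Counter({c: 5 for c in FAMILIES["Gly"]})  # 4-fold, equal use
    df = rscu(equal).set_index("codon")
    for c in FAMILIES["Gly"]:
        assert df.loc[c, "rscu"] == pytest.approx(1.0)
    skewed = Counter({"AGC": 10, "AGT": 0})  # 2-fold used 10:0
    df = rscu(skewed).set_index("codon")
    assert df.loc["AGC", "rscu"] == pytest.approx(2.0)
    assert df.loc["AGT", "rscu"] == pytest.approx(0.0)


@settings(max_examples=50, deadline=None)
@given(st.dictionaries(st.sampled_from(SENSE_CODONS),
                       st.integers(min_value=0, max_value=50), max_size=40))
def test_rscu_family_sums_equal_family_size(counts):
    """Within every observed family, RSCU sums to the family size."""
    df = rscu(counts)
    for fam, sub in df.groupby("amino_acid"):
        if sub["count"].sum() > 0:
            assert sub["rscu"].sum() == pytest.approx(sub["family_size"].iloc[0],
                                                      abs=1e-9)
        else:
            assert sub["rscu"].isna().all()


def test_codon_accounting_identity(synthetic_genome):
    """3 x codons + remainders add up to the summed PCG lengths."""
    total = 0
    for feat in synthetic_genome.features_of_kind("PCG"):
        codons, rem = extract_codons(synthetic_genome, feat)
        total += 3 * len(codons) + len(rem)
    expected = sum(f.length(synthetic_genome.length)
                   for f in synthetic_genome.features_of_kind("PCG"))
    assert total == expected


def test_wobble_bias_shows_in_usage(synthetic_genome):
    """The generator's AT-biased wobble yields AT-rich third positions and
    makes CGA the top arginine codon, as in fish mitogenomes."""
    _, pooled = codon_usage_counts([synthetic_genome])
    third = Counter()
    for codon, n in pooled.items():
        third[codon[2]] += n
    assert third["A"] + third["T"] > third["G"] + third["C"]
    arg = {c: pooled.get(c, 0) for c in FAMILIES["Arg"]}
    assert max(arg, key=arg.get) == "CGA"
    df = rscu(pooled).set_index("codon")
    assert df.loc["CGA", "rscu"] == df.loc[list(FAMILIES["Arg"]), "rscu"].max()


def test_gene_calls_from_annotation_without_sequence(table1):
    from mitocomp.codons import call_gene
    coi = call_gene(table1, "COI")
    assert coi.start_class == "GTG"
    atp6 = call_gene(table1, "ATP6")
    assert atp6.start_class == "CTG"
    assert atp6.stop_class == "TA-"
    coii = call_gene(table1, "COII")
    assert coii.stop_class == "T--"
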