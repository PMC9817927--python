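"""GenBank reading, strand labelling, PCG extraction and gene-order calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mitocub as mc
from mitocub.genome_io import (GeneFeature, MitogenomeRecord, gt_fraction,
                               map_gene_name, revcomp)


# --- synonym mapping -------------------------------------------------------

@pytest.mark.parametrize("alias,symbol", [
    ("COI", "MT-CO1"),
    ("COX1", "MT-CO1"),
    ("ND6", "MT-ND6"),
    ("cytb", "MT-CYB"),
    ("D-loop", "CR"),
    ("12S ribosomal RNA", "MT-RNR1"),
    ("tRNA-Leu(UUR)", "MT-TL1"),
])
def test_gene_name_synonyms(alias, symbol):
    assert map_gene_name(alias) == symbol


def test_unknown_name_maps_to_none():
    assert map_gene_name("totally-novel-orf") is None


# --- strand assignment -----------------------------------------------------

def _record_from(seq):
    return MitogenomeRecord(accession="X", sequence=seq,
                            features=[GeneFeature("MT-ND1", "PCG", 1, len(seq))])


def test_assign_strands_extremes():
    sa = mc.assign_strands(_record_from("GGTT"))
    assert sa.gt_submitted == 1.0 and sa.label_submitted == "H"
    sa = mc.assign_strands(_record_from("AACC"))
    assert sa.gt_submitted == 0.0 and sa.label_submitted == "L"


def test_assign_strands_all_n_errors():
    with pytest.raises(ValueError):
        mc.assign_strands(_record_from("NNNN"))


@settings(derandomize=True, max_examples=60)
@given(st.text(alphabet="ACGT", min_size=1, max_size=200))
def test_strand_gt_complementarity(seq):
    """G+T of a strand and of its reverse complement sum to exactly 1."""
    assert gt_fraction(seq) + gt_fraction(revcomp(seq)) == pytest.approx(1.0, abs=1e-12)


# --- PCG extraction --------------------------------------------------------

def test_extract_pcgs_reverse_complements_opposite_features():
    # submitted strand holds CAT; the opposite-orientation gene reads ATG
    seq = "CCCCAT" + "G" * 6
    rec = MitogenomeRecord(accession="X", sequence=seq, features=[
        GeneFeature("MT-ND6", "PCG", 4, 6, orientation="opposite"),
    ])
    genes = mc.extract_pcgs(rec)
    assert genes[0].cds == "ATG"


def test_extract_recovers_planted_cds(genome_and_truth):
    record, truth = genome_and_truth
    genes = mc.extract_pcgs(record)
    assert [g.gene for g in genes] == list(mc.PCG_SYMBOLS)
    for g in genes:
        assert g.cds == truth["cds"][g.gene]
        assert g.strand_label == truth["strand_labels"][g.gene]


def test_nd6_is_the_only_heavy_strand_gene(genome_and_truth):
    record, _ = genome_and_truth
    genes = mc.extract_pcgs(record)
    heavy = [g.gene for g in genes if g.strand_label == "H"]
    assert heavy == ["MT-ND6"]


def test_out_of_bounds_feature_errors(genome_and_truth):
    record, _ = genome_and_truth
    bad = MitogenomeRecord(accession="X", sequence=record.sequence, features=[
        GeneFeature("MT-ND1", "PCG", 1, record.length + 10),
    ])
    with pytest.raises(ValueError):
        mc.extract_pcgs(bad)


# --- GenBank round trip ----------------------------------------------------

def test_genbank_round_trip(genome_and_truth, tmp_path):
    record, truth = genome_and_truth
    path = tmp_path / "g.gb"
    mc.write_genbank(record, path)
    back = mc.read_genbank(path)
    assert back.length == record.length
    assert back.sequence == record.sequence
    assert len(back.pcg_features()) == 13
    assert len(back.features) == 38  # 37 genes + control region
    genes = mc.extract_pcgs(back)
    for g in genes:
        assert g.cds == truth["cds"][g.gene]


def test_read_genbank_rejects_no_cds(tmp_path):
    gb = tmp_path / "empty.gb"
    gb.write_text(
        "LOCUS       X 8 bp DNA circular 01-JAN-2000\n"
        "FEATURES             Location/Qualifiers\n"
        "ORIGIN\n        1 acgtacgt\n//\n")
    with pytest.raises(ValueError, match="no PCGs"):
        mc.read_genbank(gb)


# --- gene order ------------------------------------------------------------

def test_default_genome_is_ancestral_avian(genome_and_truth):
    record, _ = genome_and_truth
    label, mismatch = mc.classify_gene_order(record)
    assert label == "ancestral_avian" and mismatch is None


def test_swapped_trnas_classify_other(genome_and_truth):
    record, _ = genome_and_truth
    feats = [GeneFeature(f.name, f.kind, f.start, f.end, f.orientation)
             for f in record.features]
    # swap the names of two adjacent tRNAs (coordinates stay put)
    i = next(k for k, f in enumerate(feats) if f.name == "MT-TW")
    j = next(k for k, f in enumerate(feats) if f.name == "MT-TA")
    feats[i].name, feats[j].name = feats[j].name, feats[i].name
    feats[i].orientation, feats[j].orientation = (feats[j].orientation,
                                                  feats[i].orientation)
    rec2 = MitogenomeRecord(record.accession, record.sequence, feats)
    label, mismatch = mc.classify_gene_order(rec2)
    assert label == "other"
    assert "MT-T" in mismatch


def test_gene_order_rotation_invariance(genome_and_truth):
    """Rotating the circular genome does not change the order call."""
    record, _ = genome_and_truth
    anchor = next(f for f in record.features if f.name == "MT-CO2")
    shift = anchor.start - 1
    L = record.length
    seq = record.sequence[shift:] + record.sequence[:shift]
    feats = []
    for f in record.features:
        start = (f.start - 1 - shift) % L + 1
        end = start + (f.end - f.start)
        if end <= L:  # wrapped features dropped; generator layout avoids them
            feats.append(GeneFeature(f.name, f.kind, start, end, f.orientation))
    rec2 = MitogenomeRecord(record.accession, seq, feats)
    if len(feats) == len(record.features):
        assert mc.classify_gene_order(rec2)[0] == "ancestral_avian"


def test_duplicate_symbol_is_other_not_exception(genome_and_truth):
    record, _ = genome_and_truth
    feats = list(record.features) + [GeneFeature("MT-TF", "tRNA", 1, 10)]
    rec2 = MitogenomeRecord(record.accession, record.sequence, feats)
    label, mismatch = mc.classify_gene_order(rec2)
    assert label == "other" and "duplicated" in mismatch


# --- start/stop survey -----------------------------------------------------

def test_survey_start_stop_flags_and_incomplete_stops():
    genes = [
        mc.GeneSequence("MT-CO1", "t", "GTG" + "AAA" * 4 + "TAA", "L"),
        mc.GeneSequence("MT-ND2", "t", "ATG" + "AAA" * 4 + "T", "L"),
        mc.GeneSequence("MT-ND3", "t", "ATG" + "AAA" * 4 + "TA", "L"),
        mc.GeneSequence("MT-ND4", "t", "ATGAAATAG", "L"),
    ]
    rows = mc.survey_start_stop(genes)
    assert rows[0]["start_codon"] == "GTG" and rows[0]["non_atg_start"]
    assert rows[0]["stop_codon"] == "TAA"
    assert rows[1]["stop_codon"] == "T--"
    assert rows[2]["stop_codon"] == "TA-"
    assert rows[3]["start_codon"] == "ATG" and rows[3]["stop_codon"] == "TAG"
    assert not rows[3]["non_atg_start"]
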