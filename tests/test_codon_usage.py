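"""Codon counting, RSCU, ENC and GC-site indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mitocub as mc
from mitocub.codon_usage import (CodonCounts, codon_homozygosity, enc,
                                 extract_codons, gc3s, gc_site_contents,
                                 mean_rscu_and_classify, profile, rscu)
from mitocub.genetic_code import VERTEBRATE_MITO

CODE = VERTEBRATE_MITO


# --- codon extraction ------------------------------------------------------

def test_extract_drops_terminal_stop():
    assert extract_codons("ATGAAATAA").counts == {"ATG": 1, "AAA": 1}


def test_extract_drops_incomplete_stop_remnant():
    assert extract_codons("ATGAAAT").counts == {"ATG": 1, "AAA": 1}


def test_extract_drops_internal_stop_with_warning(caplog):
    with caplog.at_level("WARNING"):
        counts = extract_codons("ATGAGAAAA")
    assert counts.counts == {"ATG": 1, "AAA": 1}
    assert any("internal stop" in r.message for r in caplog.records)


def test_extract_skips_n_codons():
    assert extract_codons("ATGANAAAA").counts == {"ATG": 1, "AAA": 1}


def test_extract_too_short_errors():
    with pytest.raises(ValueError):
        extract_codons("ATG")


# --- RSCU ------------------------------------------------------------------

def test_rscu_two_fold_family():
    counts = CodonCounts(counts={"AAA": 3, "AAG": 1})
    r = rscu(counts)
    assert r["AAA"] == pytest.approx(1.5)
    assert r["AAG"] == pytest.approx(0.5)


def test_rscu_six_fold_leucine():
    # CTA dominates the 6-fold Leu family
    counts = CodonCounts(counts={"CTA": 6, "CTC": 2, "CTG": 2, "CTT": 2})
    assert rscu(counts)["CTA"] == pytest.approx(3.0)


def test_rscu_unobserved_family_is_nan():
    counts = CodonCounts(counts={"AAA": 3})
    assert np.isnan(rscu(counts)["GGG"])


@settings(derandomize=True, max_examples=40)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_rscu_family_sums_equal_family_size(seed):
    """Sum of RSCU over each observed family equals the family size."""
    rng = np.random.default_rng(seed)
    raw = rng.integers(0, 30, size=60)
    counts = CodonCounts(counts={c: int(n) for c, n in
                                 zip(CODE.sense_codons, raw) if n})
    r = rscu(counts)
    for fam in CODE.families:
        total = sum(counts.counts.get(c, 0) for c in fam)
        if total:
            assert sum(r[c] for c in fam) == pytest.approx(len(fam), abs=1e-9)


def test_rscu_invariant_under_codon_order():
    cds = "ATG" + "AAAGAATTC" * 5 + "TAA"
    shuffled = "ATG" + "GAATTCAAA" * 5 + "TAA"
    r1, r2 = rscu(extract_codons(cds)), rscu(extract_codons(shuffled))
    assert r1.keys() == r2.keys()
    np.testing.assert_array_equal(  # NaN compares equal to NaN here
        np.array([r1[c] for c in sorted(r1)]),
        np.array([r2[c] for c in sorted(r2)]))


# --- ENC -------------------------------------------------------------------

def test_enc_uniform_usage_is_maximal():
    counts = CodonCounts(counts={c: 100 for c in CODE.sense_codons})
    assert enc(counts) == 60.0


def test_enc_single_codon_per_family_is_20():
    counts = CodonCounts(counts={fam[0]: 50 for fam in CODE.families})
    assert enc(counts) == pytest.approx(20.0)


def test_homozygosity_two_fold_3_1():
    assert codon_homozygosity(4, [3, 1]) == pytest.approx(0.5)


def test_enc_matches_independent_reimplementation():
    """Clean-room Wright/CodonW oracle on random 500-codon genes."""

    def oracle(counts_map):
        by_class = {}
        for fam in CODE.families:
            ns = [counts_map.get(c, 0) for c in fam]
            n = sum(ns)
            if n < 2:
                continue
            f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
            if f > 0:
                by_class.setdefault(len(fam), []).append(f)
        means = {k: sum(v) / len(v) for k, v in by_class.items()}
        fallback = sum(means.values()) / len(means)
        total = sum(nf / means.get(k, fallback)
                    for k, nf in CODE.family_size_counts().items())
        return min(total, 60.0)

    rng = np.random.default_rng(2024)
    for _ in range(5):
        p = rng.dirichlet(np.ones(60) * 0.5)
        draw = rng.multinomial(500, p)
        counts = CodonCounts(counts={c: int(n) for c, n in
                                     zip(CODE.sense_codons, draw) if n})
        assert enc(counts) == pytest.approx(oracle(counts.counts), abs=1e-9)


def test_enc_bounds_and_count_doubling_drift():
    """ENC stays in [20, 60]; doubling all counts moves the finite-sample
    homozygosity monotonically toward its infinite-n value (ENC drifts
    down when the capped maximum is not in play)."""
    rng = np.random.default_rng(5)
    p = rng.dirichlet(np.ones(60) * 0.3)
    draw = rng.multinomial(400, p)
    counts = {c: int(n) for c, n in zip(CODE.sense_codons, draw) if n}
    e1 = enc(CodonCounts(counts=counts))
    e2 = enc(CodonCounts(counts={c: 2 * n for c, n in counts.items()}))
    assert 20.0 <= e2 <= e1 <= 60.0


def test_enc_no_family_with_data_is_nan():
    counts = CodonCounts(counts={"AAA": 1})
    assert np.isnan(enc(counts))


# --- GC contents -----------------------------------------------------------

def test_gc_sites_extremes():
    counts = CodonCounts(counts={"GGG": 1, "CCC": 1})
    gc1, gc2, gc3, gc12 = gc_site_contents(counts)
    assert gc1 == gc2 == gc3 == gc12 == 1.0
    counts = CodonCounts(counts={"ATA": 5})
    assert gc_site_contents(counts) == (0.0, 0.0, 0.0, 0.0)


def test_gc12_is_mean_of_gc1_gc2():
    counts = CodonCounts(counts={"GAA": 3, "AGT": 1})
    gc1, gc2, _, gc12 = gc_site_contents(counts)
    assert gc12 == pytest.approx((gc1 + gc2) / 2)
    assert min(gc1, gc2) <= gc12 <= max(gc1, gc2)


def test_gc3s_third_position_fraction():
    counts = CodonCounts(counts={"AAA": 1, "GGC": 1, "TGA": 1})
    assert gc3s(counts) == pytest.approx(1 / 3)


def test_gc3s_equals_gc3_under_table2():
    cds = "ATG" + "GAATTCAAACTGCAT" * 6 + "TAA"
    counts = extract_codons(cds)
    _, _, gc3, _ = gc_site_contents(counts)
    assert gc3s(counts) == pytest.approx(gc3)


# --- mean RSCU classification ----------------------------------------------

def _profile_with_rscu(rscu_map, strand="L", taxon="t"):
    p = profile(CodonCounts(gene="g", taxon=taxon,
                            counts={"AAA": 2, "AAG": 2}), strand_label=strand)
    p.rscu = rscu_map
    return p


def test_classification_thresholds():
    cls, _, _ = mean_rscu_and_classify([_profile_with_rscu({"CTA": 1.7})])
    assert cls["CTA"] == "over_represented"
    cls, _, _ = mean_rscu_and_classify([_profile_with_rscu({"CTA": 1.6})])
    assert cls["CTA"] == "preferred"  # boundary closed on the preferred side
    cls, _, _ = mean_rscu_and_classify([_profile_with_rscu({"CTA": 0.9})])
    assert cls["CTA"] == "under_or_normal"


def test_planted_ac_bias_is_recovered():
    """Genes generated with A/C-ending preference yield mostly A/C-ending
    over-represented codons."""
    profiles = []
    for seed in range(6):
        counts, _ = mc.generate_codon_counts(4000, seed=seed, ac_tilt=3.0)
        counts.taxon = f"t{seed}"
        profiles.append(profile(counts, strand_label="L"))
    cls, _, tallies = mean_rscu_and_classify(profiles)
    over = [c for c, lab in cls.items() if lab == "over_represented"]
    assert over, "tilt 3.0 should over-represent some codons"
    ac_ending = sum(1 for c in over if c[2] in "AC")
    assert ac_ending / len(over) > 0.5
    tally = tallies["L"]
    assert tally["A"] + tally["C"] > tally["G"] + tally["T"]
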