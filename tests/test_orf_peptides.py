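"""ORF scanning, translation, digestion and peptide chemistry."""

import math

import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pyteomics_mass
from pyteomics import parser as pyteomics_parser

from venomics.orf_peptides import (
    Transcript,
    digest,
    find_orfs,
    in_mass_window,
    isoelectric_point,
    mascot_ion_score,
    monoisotopic_mass,
    net_charge,
    reverse_complement,
    translate,
)

from _oracles import brute_force_orfs


# ---------------------------------------------------------------------------
# translation


@pytest.mark.parametrize("nt,aa", [
    ("ATGTGA", "M"),
    ("ATGAAACGTTGA", "MKR"),
    ("ATGAAACGT", "MKR"),          # no trailing stop is fine
    ("ATGANATGA", "MX"),           # codon with N -> X
])
def test_translate_standard_code(nt, aa):
    assert translate(nt) == aa


def test_translate_internal_stop_is_an_error_with_position():
    with pytest.raises(ValueError, match="codon 1"):
        translate("ATGTAAAAATGA")


def test_translate_rejects_bad_length_and_alphabet():
    with pytest.raises(ValueError, match="multiple of 3"):
        translate("ATGA")
    with pytest.raises(ValueError):
        translate("ATGUUU")


def test_printed_pla2_cds_translates_to_codon_count(toxin_cds):
    nt = toxin_cds["PLA2_Gu"]
    protein = translate(nt)
    assert len(protein) == len(nt) // 3 - 1
    assert protein.startswith("M") and "*" not in protein


# ---------------------------------------------------------------------------
# ORF scanning


def test_no_atg_means_no_orfs():
    t = Transcript("t", "CCCCCCTAACCCCCC")
    assert find_orfs(t, min_len_aa=1) == []


def test_printed_svmp1_cds_is_one_full_length_orf(toxin_cds):
    nt = toxin_cds["SVMP1_Gb"]
    t = Transcript("svmp1", nt)
    orfs = find_orfs(t, min_len_aa=50)
    full = [o for o in orfs if o.strand == "+" and o.start == 0
            and o.end == len(nt)]
    assert len(full) == 1
    assert full[0].nt_seq == nt
    longest = find_orfs(t, min_len_aa=50, longest_only=True)
    assert longest[0].start == 0 and longest[0].end == len(nt)


def test_longest_only_tie_breaks_to_plus_strand():
    # ATG AAA TAA reads as an ORF on both strands of its own revcomp pair
    fwd = "ATGAAATAA"
    seq = fwd + "NN" + reverse_complement(fwd)
    t = Transcript("t", seq)
    best = find_orfs(t, min_len_aa=1, longest_only=True)
    assert best[0].strand == "+"


@settings(max_examples=120, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGTN", min_size=3, max_size=300),
       st.integers(min_value=1, max_value=20))
def test_find_orfs_matches_exhaustive_triple_enumeration(seq, min_aa):
    t = Transcript("t", seq)
    got = {(o.strand, o.frame, o.start, o.end)
           for o in find_orfs(t, min_len_aa=min_aa)}
    assert got == brute_force_orfs(seq, min_aa)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGT", min_size=30, max_size=200))
def test_minus_strand_orfs_translate_like_their_own_cds(seq):
    t = Transcript("t", seq)
    for orf in find_orfs(t, min_len_aa=3):
        if orf.strand == "-":
            rc = reverse_complement(seq)
            assert orf.nt_seq == rc[orf.start:orf.end]
        assert translate(orf.nt_seq)  # complete ORFs always translate


# ---------------------------------------------------------------------------
# tryptic digestion


@pytest.mark.parametrize("protein,expected", [
    ("AAAA", ["AAAA"]),
    ("MKRA", ["MK", "R", "A"]),
    ("AKPRA", ["AKPR", "A"]),      # K before P is not cleaved
])
def test_digest_zero_missed_follows_the_trypsin_rule(protein, expected):
    peps = [p.aa_seq for p in digest(protein, max_missed=0)]
    assert peps == expected


@pytest.mark.parametrize("protein", [
    "MKRAPEPTIDEKRAKPLLRSTK", "KRKRKR", "MAGICPRKTEIN", "PKPKPK",
])
def test_digest_agrees_with_pyteomics_cleavage(protein):
    ours = {p.aa_seq for p in digest(protein, max_missed=2)}
    ref = pyteomics_parser.cleave(protein, pyteomics_parser.expasy_rules["trypsin"],
                                  missed_cleavages=2)
    assert ours == set(ref)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
def test_digest_reconstruction_and_missed_cleavage_structure(protein):
    peps = digest(protein, max_missed=2)
    base = [p.aa_seq for p in peps if p.missed_cleavages == 0]
    assert "".join(base) == protein
    for m in (1, 2):
        got = [p.aa_seq for p in peps if p.missed_cleavages == m]
        want = ["".join(base[i:i + m + 1]) for i in range(len(base) - m)]
        assert got == want


# ---------------------------------------------------------------------------
# masses and the MALDI window


def test_monoisotopic_mass_reference_values():
    assert monoisotopic_mass("G") == pytest.approx(75.03203, abs=1e-4)
    assert monoisotopic_mass("GG") == pytest.approx(132.05349, abs=1e-4)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
       st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
def test_mass_additivity_and_pyteomics_agreement(a, b):
    assert monoisotopic_mass(a + b) == pytest.approx(
        monoisotopic_mass(a) + monoisotopic_mass(b) - 18.010565, abs=1e-6)
    assert monoisotopic_mass(a) == pytest.approx(
        pyteomics_mass.fast_mass(a), abs=1e-3)


def test_mass_rejects_nonstandard_residues():
    with pytest.raises(ValueError, match="nonstandard"):
        monoisotopic_mass("AXA")


def test_mass_window_boundaries_and_monotonicity():
    assert not in_mass_window(monoisotopic_mass("G"))            # 75 Da
    assert in_mass_window(800.0) and in_mass_window(4000.0)      # inclusive
    assert not in_mass_window(799.999) and not in_mass_window(4000.001)
    assert in_mass_window(1500.0, 800, 4000)
    assert in_mass_window(1500.0, 700, 5000)                     # widening keeps True
    with pytest.raises(ValueError):
        in_mass_window(1000.0, 4000, 800)


# ---------------------------------------------------------------------------
# Mascot score and isoelectric point


def test_mascot_score_reference_points():
    assert mascot_ion_score(1.0) == 0.0
    assert mascot_ion_score(0.001) == 30.0
    assert mascot_ion_score(0.05) == pytest.approx(13.0103, abs=1e-4)
    with pytest.raises(ValueError):
        mascot_ion_score(0.0)
    with pytest.raises(ValueError):
        mascot_ion_score(1.5)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.floats(min_value=1e-10, max_value=0.999), st.floats(min_value=1.001, max_value=10.0))
def test_mascot_score_strictly_decreasing(p, factor):
    q = min(p * factor, 1.0)
    assert mascot_ion_score(p) > mascot_ion_score(q)


def test_isoelectric_point_basic_chemistry():
    assert net_charge("PEPTIDE", isoelectric_point("PEPTIDE")) == pytest.approx(0, abs=1e-3)
    assert isoelectric_point("KKKKK") > isoelectric_point("DDDDD")


def test_isoelectric_point_matches_fine_grid_scan():
    seq = "ACDEFGHIKLMNPQRSTVWY"
    # independent route: scan a 1e-4 pH grid for the sign change
    grid = None
    ph = 0.0
    while ph < 14.0:
        if net_charge(seq, ph) <= 0.0:
            grid = ph
            break
        ph += 1e-4
    assert isoelectric_point(seq) == pytest.approx(grid, abs=1e-3)
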