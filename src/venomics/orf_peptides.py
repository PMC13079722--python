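"""Sequence chemistry for venom proteotranscriptomics.

ORF prediction on assembled transcripts, translation, tryptic digestion,
monoisotopic peptide masses with MALDI-window filtering, Mascot score
conversion, and isoelectric-point estimation.

Conventions
-----------
* ORF coordinates are 0-based half-open and strand-local: for a minus-strand
  ORF, ``start``/``end`` index into the reverse complement of the transcript.
* An ORF runs from an ATG to the first in-frame stop codon (stop included in
  ``nt_seq``); every ATG defines its own ORF, so nested ORFs sharing a stop
  are all reported.
* Codons containing ``N`` translate to ``X``; only exact TAA/TAG/TGA codons
  terminate an ORF.
* The MALDI mass window compares the *neutral* monoisotopic mass against the
  instrument's m/z limits; the ~1 Da proton mass is negligible against a
  3200 Da window and is ignored.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "Transcript",
    "OpenReadingFrame",
    "ProteinSeq",
    "TrypticPeptide",
    "find_orfs",
    "translate",
    "reverse_complement",
    "digest",
    "monoisotopic_mass",
    "in_mass_window",
    "mascot_ion_score",
    "isoelectric_point",
    "net_charge",
    "WATER_MONO",
    "RESIDUE_MONO",
]

NT_ALPHABET = set("ACGTN")
STOP_CODONS = ("TAA", "TAG", "TGA")

# Standard genetic code (DNA codons).  Stops are handled separately.
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Monoisotopic residue masses (Da) for the 20 standard amino acids, and the
# mass of water added once per peptide (free N/C termini).
WATER_MONO = 18.010565
RESIDUE_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

# Side-chain and terminal pKa values (EMBOSS set).  pI here only positions
# simulated spots on the 2-DE pH axis, so a single fixed table suffices.
PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


@dataclass(frozen=True)
class Transcript:
    """An assembled transcript (gene-level OTU) from one tissue library."""

    id: str
    seq: str
    species: str = ""
    tissue: str = "unspecified"

    def __post_init__(self):
        if not self.id:
            raise ValueError("transcript id must be nonempty")
        bad = set(self.seq) - NT_ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id}: invalid nucleotide(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class OpenReadingFrame:
    transcript_id: str
    strand: str            # '+' or '-'
    frame: int             # 0-2, on the reported strand
    start: int             # 0-based, strand-local
    end: int               # half-open; includes the stop codon
    nt_seq: str

    @property
    def aa_length(self) -> int:
        """Protein length in residues, excluding the stop codon."""
        return (self.end - self.start) // 3 - 1


@dataclass(frozen=True)
class ProteinSeq:
    id: str
    aa_seq: str
    source: OpenReadingFrame | None = None
    species: str = ""


@dataclass(frozen=True)
class TrypticPeptide:
    aa_seq: str
    missed_cleavages: int
    mono_mass: float


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate a CDS with the standard code.

    A trailing stop codon is stripped; an internal stop raises (surfacing
    frame mistakes rather than silently truncating); any codon containing
    N yields X.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} is not a multiple of 3")
    bad = set(nt) - NT_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)}")
    aa = []
    n_codons = len(nt) // 3
    for i in range(n_codons):
        codon = nt[3 * i: 3 * i + 3]
        if codon in STOP_CODONS:
            if i != n_codons - 1:
                raise ValueError(f"internal stop codon {codon} at codon {i}")
            break  # trailing stop: drop
        aa.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(aa)


def _frame_orfs(seq: str, strand: str, tid: str, min_len_aa: int,
                include_partial: bool) -> list[OpenReadingFrame]:
    n = len(seq)
    orfs = []
    for frame in range(3):
        codon_starts = range(frame, n - 2, 3)
        stops = [i for i in codon_starts if seq[i:i + 3] in STOP_CODONS]
        for i in codon_starts:
            if seq[i:i + 3] != "ATG":
                continue
            j = bisect_left(stops, i)
            if j < len(stops):
                stop = stops[j]
                aa_len = (stop - i) // 3
                if aa_len >= min_len_aa:
                    orfs.append(OpenReadingFrame(
                        tid, strand, frame, i, stop + 3, seq[i:stop + 3]))
            elif include_partial:
                end = i + 3 * ((n - i) // 3)
                if (end - i) // 3 >= min_len_aa:
                    orfs.append(OpenReadingFrame(
                        tid, strand, frame, i, end, seq[i:end]))
    return orfs


def find_orfs(t: Transcript, min_len_aa: int = 50, longest_only: bool = False,
              include_partial: bool = False) -> list[OpenReadingFrame]:
    """Six-frame ATG→stop ORF scan.

    Returns ORFs of at least ``min_len_aa`` residues (stop excluded), sorted
    (+ strand first, then start, then end).  ``longest_only`` returns a
    single-element list with the longest ORF; ties break to the + strand,
    then the smallest start.  ``include_partial`` also reports 3'-partial
    ORFs that run off the sequence end without a stop.
    """
    if len(t.seq) < 3:
        raise ValueError("sequence shorter than one codon")
    orfs = _frame_orfs(t.seq, "+", t.id, min_len_aa, include_partial)
    orfs += _frame_orfs(reverse_complement(t.seq), "-", t.id, min_len_aa,
                        include_partial)
    orfs.sort(key=lambda o: (o.strand != "+", o.start, o.end))
    if longest_only:
        if not orfs:
            return []
        best = max(orfs, key=lambda o: (o.end - o.start,
                                        o.strand == "+", -o.start))
        return [best]
    return orfs


def digest(p: ProteinSeq | str, max_missed: int = 2) -> list[TrypticPeptide]:
    """In-silico tryptic digestion: cleave after K/R unless followed by P.

    Returns every peptide carrying 0..``max_missed`` missed cleavages, in
    N→C order (grouped by missed-cleavage count).  Peptides containing
    nonstandard residues get ``mono_mass = nan`` so the mass window drops
    them rather than raising mid-digest.
    """
    aa = p.aa_seq if isinstance(p, ProteinSeq) else p
    if not aa:
        raise ValueError("empty protein sequence")
    cuts = [i + 1 for i in range(len(aa) - 1)
            if aa[i] in "KR" and aa[i + 1] != "P"]
    bounds = [0] + cuts + [len(aa)]
    segments = [aa[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]
    peptides = []
    for m in range(max_missed + 1):
        for i in range(len(segments) - m):
            pep = "".join(segments[i:i + m + 1])
            try:
                mass = monoisotopic_mass(pep)
            except ValueError:
                mass = math.nan
            peptides.append(TrypticPeptide(pep, m, mass))
    return peptides


def monoisotopic_mass(aa_seq: str) -> float:
    """Neutral monoisotopic peptide mass: residue masses plus one water."""
    if not aa_seq:
        raise ValueError("empty peptide")
    try:
        return sum(RESIDUE_MONO[a] for a in aa_seq) + WATER_MONO
    except KeyError as exc:
        raise ValueError(f"nonstandard residue {exc.args[0]!r}") from exc


def in_mass_window(pep: TrypticPeptide | float, lo: float = 800.0,
                   hi: float = 4000.0) -> bool:
    """Inclusive MALDI window test on the neutral monoisotopic mass."""
    if lo > hi:
        raise ValueError(f"mass window lo {lo} exceeds hi {hi}")
    mass = pep.mono_mass if isinstance(pep, TrypticPeptide) else pep
    return lo <= mass <= hi


def mascot_ion_score(P: float) -> float:
    """Mascot ion score −10·log10(P) for random-match probability P."""
    if not 0.0 < P <= 1.0:
        raise ValueError(f"P must be in (0, 1], got {P}")
    return -10.0 * math.log10(P)


def net_charge(aa_seq: str, pH: float) -> float:
    """Henderson–Hasselbalch net charge over termini and ionizable side chains."""
    pos = 1.0 / (1.0 + 10.0 ** (pH - PKA_POSITIVE["Nterm"]))
    neg = -1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE["Cterm"] - pH))
    for a in aa_seq:
        if a in PKA_POSITIVE:
            pos += 1.0 / (1.0 + 10.0 ** (pH - PKA_POSITIVE[a]))
        elif a in PKA_NEGATIVE:
            neg -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE[a] - pH))
    return pos + neg


def isoelectric_point(aa_seq: str, tol: float = 1e-6) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so the root is unique.
    """
    if not aa_seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(aa_seq, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
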