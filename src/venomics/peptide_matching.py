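"""Proteome-transcriptome cross-evidence: peptide library building and matching.

MS-identified peptides are searched against the space of proteins translated
from venom-gland transcripts, either as free substrings (default — no
assumption about the library side of the search) or restricted to in-window
tryptic peptides.  MALDI peptide mass fingerprinting cannot distinguish
isoleucine from leucine, so an ``il_mode`` collapses I and L to a common
symbol on both sides; it is off by default but recommended for PMF data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .orf_peptides import ProteinSeq, digest, in_mass_window

__all__ = [
    "ObservedPeptide",
    "PeptideLibrary",
    "MatchResult",
    "MatchSummary",
    "build_library",
    "match_peptides",
    "summarize_matches",
    "read_peptides_tsv",
]

_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
_AMBIGUOUS = set("XBZ")


@dataclass(frozen=True)
class ObservedPeptide:
    species: str
    spot_id: str
    aa_seq: str
    ion_score: float | None = None
    annotation: str | None = None

    def __post_init__(self):
        if not self.aa_seq:
            raise ValueError("observed peptide sequence is empty")


@dataclass
class PeptideLibrary:
    mode: str                       # 'substring' | 'tryptic'
    il_mode: bool
    proteins: dict = field(default_factory=dict)   # id -> (collapsed) aa_seq
    entries: dict = field(default_factory=dict)    # peptide -> sorted source ids


@dataclass(frozen=True)
class MatchResult:
    peptide: ObservedPeptide
    matched: bool
    matched_ids: tuple[str, ...]


@dataclass(frozen=True)
class MatchSummary:
    species: str
    n_matched: int
    n_total: int


def _collapse_il(seq: str) -> str:
    # J is the standard one-letter placeholder for "I or L"
    return seq.replace("I", "J").replace("L", "J")


def build_library(proteins, mode: str = "substring", il_mode: bool = False,
                  max_missed: int = 2,
                  mass_window: tuple[float, float] = (800.0, 4000.0)) -> PeptideLibrary:
    """Build the search space from translated proteins.

    ``proteins`` is a list of :class:`ProteinSeq` (or (id, seq) pairs).
    Substring mode stores the id→sequence map for scanning; tryptic mode
    enumerates every digest peptide inside the mass window and maps it to
    all of its source proteins.
    """
    items = []
    for p in proteins:
        if isinstance(p, ProteinSeq):
            items.append((p.id, p.aa_seq))
        else:
            items.append((p[0], p[1]))
    if not items:
        raise ValueError("empty protein list")
    if mode not in ("substring", "tryptic"):
        raise ValueError(f"unknown library mode {mode!r}")
    lib = PeptideLibrary(mode=mode, il_mode=il_mode)
    for pid, seq in items:
        stored = _collapse_il(seq) if il_mode else seq
        lib.proteins[pid] = stored
        if mode == "tryptic":
            lo, hi = mass_window
            for pep in digest(seq, max_missed):
                if not in_mass_window(pep, lo, hi):
                    continue
                key = _collapse_il(pep.aa_seq) if il_mode else pep.aa_seq
                sources = lib.entries.setdefault(key, [])
                if pid not in sources:
                    sources.append(pid)
    for key in lib.entries:
        lib.entries[key].sort()
    return lib


def match_peptides(observed, lib: PeptideLibrary,
                   allow_wildcards: bool = False) -> list[MatchResult]:
    """Match observed peptides against the library, in input order.

    Ambiguity codes B/Z/X never match unless ``allow_wildcards`` is set (in
    which case they match any residue at that position, substring mode
    only).  Peptides with characters outside the residue alphabet raise a
    warning and come back unmatched.
    """
    results = []
    for obs in observed:
        seq = obs.aa_seq.upper()
        bad = set(seq) - _RESIDUES - _AMBIGUOUS
        if bad:
            warnings.warn(
                f"peptide {obs.aa_seq!r} ({obs.species}/{obs.spot_id}) has "
                f"invalid characters {sorted(bad)}; returned unmatched")
            results.append(MatchResult(obs, False, ()))
            continue
        ambiguous = set(seq) & _AMBIGUOUS
        if ambiguous and not allow_wildcards:
            results.append(MatchResult(obs, False, ()))
            continue
        query = _collapse_il(seq) if lib.il_mode else seq
        if lib.mode == "tryptic":
            ids = tuple(lib.entries.get(query, ()))
        elif ambiguous:
            import re
            pattern = re.compile("".join(
                "." if c in _AMBIGUOUS else re.escape(c) for c in query))
            ids = tuple(sorted(pid for pid, pseq in lib.proteins.items()
                               if pattern.search(pseq)))
        else:
            ids = tuple(sorted(pid for pid, pseq in lib.proteins.items()
                               if query in pseq))
        results.append(MatchResult(obs, bool(ids), ids))
    return results


def summarize_matches(results) -> list[MatchSummary]:
    """Per-species matched/total counts (each observed occurrence counts once)."""
    tally: dict[str, list[int]] = {}
    order = []
    for r in results:
        sp = r.peptide.species
        if sp not in tally:
            tally[sp] = [0, 0]
            order.append(sp)
        tally[sp][1] += 1
        if r.matched:
            tally[sp][0] += 1
    return [MatchSummary(sp, tally[sp][0], tally[sp][1]) for sp in order]


def read_peptides_tsv(path) -> list[ObservedPeptide]:
    """Read an observed-peptide table (species, spot_id, peptide, ion_score)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        score = getattr(row, "ion_score", None)
        out.append(ObservedPeptide(str(row.species), str(row.spot_id),
                                   str(row.peptide), score))
    return out
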