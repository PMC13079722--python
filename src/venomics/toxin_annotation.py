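"""Toxin-family assignment by local alignment against a labeled reference panel.

Each translated query protein is aligned (Smith-Waterman, affine gaps,
BLOSUM62 by default) against every panel entry; the best-scoring entry
determines the family and toxin status.  Scores are normalized by the
query's self-alignment score, giving a length-robust value in [0, 1] that
needs no database statistics: queries below the ``min_norm_score`` threshold
are "unidentified", and "non-toxin" status requires explicit NONTOXIN panel
entries, yielding the three-way toxin / non-toxin / unidentified split.

The alignment engine is Biopython's PairwiseAligner (local mode); a gap of
length k costs ``gap_open + (k-1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .orf_peptides import ProteinSeq

__all__ = [
    "FAMILY_VOCABULARY",
    "ReferenceEntry",
    "ScoringParams",
    "FamilyAssignment",
    "smith_waterman",
    "assign_family",
    "annotate_all",
    "read_panel_fasta",
    "write_panel_fasta",
]

FAMILY_VOCABULARY = {
    "SVMP", "SVSP", "PLA2", "M-LAO", "CTL", "CRISP", "VEGF", "NGF",
    "5NUC", "PDE", "DPPIV", "AP", "PA-precursor",
}


@dataclass(frozen=True)
class ReferenceEntry:
    id: str
    family: str
    aa_seq: str
    is_toxin: bool

    def __post_init__(self):
        if self.family not in FAMILY_VOCABULARY and \
                not self.family.startswith("NONTOXIN-"):
            raise ValueError(f"family {self.family!r} outside the controlled vocabulary")


@dataclass
class ScoringParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_norm_score: float = 0.4

    def validate(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if not 0.0 <= self.min_norm_score <= 1.0:
            raise ValueError("min_norm_score outside [0, 1]")


@dataclass(frozen=True)
class FamilyAssignment:
    query_id: str
    family: str | None
    raw_score: float
    norm_score: float
    status: str               # 'toxin' | 'non-toxin' | 'unidentified'
    best_ref: str | None = None


def _aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def smith_waterman(a: str, b: str, params: ScoringParams | None = None) -> float:
    """Optimal local alignment score under affine gaps (>= 0)."""
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    params = params or ScoringParams()
    params.validate()
    return max(0.0, float(_aligner(params).score(a, b)))


def assign_family(query: ProteinSeq | str, panel, params: ScoringParams | None = None,
                  query_id: str = "query") -> FamilyAssignment:
    """Best-panel-hit family assignment with self-score normalization.

    Equal raw scores resolve to the lexicographically smallest reference id.
    """
    if isinstance(query, ProteinSeq):
        seq, qid = query.aa_seq, query.id
    else:
        seq, qid = query, query_id
    panel = list(panel)
    if not panel:
        raise ValueError("reference panel is empty")
    params = params or ScoringParams()
    params.validate()
    aligner = _aligner(params)
    self_score = max(float(aligner.score(seq, seq)), 1e-9)
    best_score, best_entry = -1.0, None
    for entry in sorted(panel, key=lambda e: e.id):
        score = max(0.0, float(aligner.score(seq, entry.aa_seq)))
        if score > best_score:
            best_score, best_entry = score, entry
    norm = min(best_score / self_score, 1.0)
    if norm < params.min_norm_score:
        return FamilyAssignment(qid, None, best_score, norm, "unidentified")
    status = "toxin" if best_entry.is_toxin else "non-toxin"
    return FamilyAssignment(qid, best_entry.family, best_score, norm, status,
                            best_entry.id)


def annotate_all(proteins, panel, params: ScoringParams | None = None) -> list[FamilyAssignment]:
    """One assignment per input protein, input order preserved."""
    return [assign_family(p, panel, params) for p in proteins]


def read_panel_fasta(path) -> list[ReferenceEntry]:
    """Panel FASTA with headers ``id|family|toxin_flag``."""
    entries = []
    header, chunks = None, []
    def flush():
        if header is None:
            return
        pid, family, flag = header.split("|")
        entries.append(ReferenceEntry(pid, family, "".join(chunks),
                                      flag.lower() == "toxin"))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                flush()
                header, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    flush()
    return entries


def write_panel_fasta(entries, path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            flag = "toxin" if e.is_toxin else "nontoxin"
            fh.write(f">{e.id}|{e.family}|{flag}\n")
            for i in range(0, len(e.aa_seq), 70):
                fh.write(e.aa_seq[i:i + 70] + "\n")
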