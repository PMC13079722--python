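"""Composition profiles at the proteome (2-DE spot) and transcriptome (RPKM) level.

Two deliberately different denominators, kept exactly as the field reports
them: protein-level family percentages are fractions of the TOTAL gel spot
volume (so unidentified spots dilute them and the family percentages sum to
the identified coverage), while transcript-level family percentages are
fractions of the toxin-only RPKM sum (and therefore sum to 100).  Both
profiles can be renormalized to a toxin-only denominator for harmonized
comparison in the concordance report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CompositionProfile",
    "ToxinFractionResult",
    "normalize_spots",
    "spot_family_composition",
    "compute_rpkm",
    "add_rpkm",
    "toxin_fraction",
    "transcript_family_composition",
    "log_fpkm",
]


@dataclass
class CompositionProfile:
    species: str
    level: str                      # 'protein' | 'transcript'
    percents: dict                  # family -> percent
    denominator: str                # 'total' | 'toxin-only'
    identified_percent: float | None = None

    def toxin_only(self) -> "CompositionProfile":
        """Renormalize the family percentages to sum to 100."""
        total = sum(self.percents.values())
        if total <= 0:
            raise ValueError(f"profile for {self.species} has no labeled signal")
        return CompositionProfile(
            self.species, self.level,
            {k: 100.0 * v / total for k, v in self.percents.items()},
            "toxin-only", self.identified_percent)


@dataclass(frozen=True)
class ToxinFractionResult:
    species: str
    tissue: str
    percent_toxin: float


def normalize_spots(spots: pd.DataFrame) -> pd.DataFrame:
    """Add ``norm_intensity`` = intensity / total intensity, for one gel."""
    if (spots["intensity"] < 0).any():
        raise ValueError("negative spot intensity")
    total = spots["intensity"].sum()
    if total <= 0:
        raise ValueError("all spot intensities are zero")
    out = spots.copy()
    out["norm_intensity"] = out["intensity"] / total
    return out


def spot_family_composition(spots: pd.DataFrame,
                            species: str | None = None) -> CompositionProfile:
    """Family percentages of TOTAL gel volume from normalized spots.

    Spots with an empty/missing family label count only in the denominator;
    ``identified_percent`` is the labeled share of the gel.
    """
    if "norm_intensity" not in spots.columns:
        spots = normalize_spots(spots)
    if species is None:
        uniq = spots["species"].unique()
        if len(uniq) != 1:
            raise ValueError("spots span multiple species; pass one gel")
        species = str(uniq[0])
    fam = spots["family"].fillna("")
    labeled = spots[fam != ""]
    percents = (labeled.groupby(labeled["family"])["norm_intensity"]
                .sum().mul(100.0).to_dict())
    identified = float(labeled["norm_intensity"].sum() * 100.0)
    return CompositionProfile(species, "protein", percents, "total", identified)


def compute_rpkm(count: float, length_nt: float, library_total: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if length_nt <= 0:
        raise ValueError("transcript length must be positive")
    if library_total <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("negative count")
    return count * 1.0e9 / (length_nt * library_total)


def add_rpkm(counts: pd.DataFrame) -> pd.DataFrame:
    """Vectorized RPKM per (species, tissue) library on a counts table."""
    out = counts.copy()
    totals = out.groupby(["species", "tissue"])["count"].transform("sum")
    if (totals <= 0).any():
        raise ValueError("a library has zero total counts")
    out["rpkm"] = out["count"] * 1.0e9 / (out["length"] * totals)
    return out


def toxin_fraction(records: pd.DataFrame, statuses: dict,
                   species: str | None = None,
                   tissue: str | None = None) -> ToxinFractionResult:
    """Percent of a library's total RPKM carried by toxin-status OTUs.

    ``statuses`` maps otu_id to a status string ('toxin' counts) or boolean.
    """
    if species is None:
        species = str(records["species"].iloc[0])
    if tissue is None:
        tissue = str(records["tissue"].iloc[0])
    missing = [o for o in records["otu_id"] if o not in statuses]
    if missing:
        raise ValueError(f"missing status for OTUs: {missing[:5]}")
    total = records["rpkm"].sum()
    if total <= 0:
        raise ValueError("zero total RPKM")
    def is_toxin(otu):
        s = statuses[otu]
        return s is True or s == "toxin"
    toxin = records.loc[[is_toxin(o) for o in records["otu_id"]], "rpkm"].sum()
    return ToxinFractionResult(species, tissue, 100.0 * toxin / total)


def transcript_family_composition(records: pd.DataFrame, families: dict,
                                  species: str | None = None,
                                  denominator: str = "toxin-only") -> CompositionProfile:
    """Family percentages of toxin RPKM for one (species, tissue) library.

    ``families`` maps otu_id to a toxin family label; OTUs absent from the
    map (or mapped to '' / None) are non-toxin and excluded from the
    toxin-only denominator.
    """
    if species is None:
        species = str(records["species"].iloc[0])
    fam_col = [families.get(o) or "" for o in records["otu_id"]]
    df = records.assign(_family=fam_col)
    toxin = df[df["_family"] != ""]
    if toxin.empty:
        raise ValueError("no toxin OTUs in the library")
    sums = toxin.groupby("_family")["rpkm"].sum()
    if denominator == "toxin-only":
        denom = sums.sum()
    elif denominator == "total":
        denom = df["rpkm"].sum()
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise ValueError("zero RPKM denominator")
    percents = (sums * 100.0 / denom).to_dict()
    return CompositionProfile(species, "transcript", percents, denominator)


def log_fpkm(value: float) -> float:
    """log10(FPKM + 0.1), the transform used for expression boxplots."""
    if value < 0:
        raise ValueError("negative expression value")
    return math.log10(value + 0.1)
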