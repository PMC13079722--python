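"""Proteome-transcriptome concordance and the end-to-end pipeline.

The two composition profiles use different denominators (protein level:
fraction of total gel volume; transcript level: fraction of toxin RPKM), so
before comparison the protein profile is renormalized to a toxin-only
denominator.  Per family, the log2 ratio of (protein + eps) / (transcript +
eps) percent is computed with a pseudo-percent eps, and families outside a
+/-1 log2 band are flagged protein- or transcript-biased — the quantitative
form of the "transcript abundant but protein scarce" discrepancy calls.

:func:`run_pipeline` chains the whole analysis on a simulated dataset:
ORF calling -> translation -> peptide matching -> panel annotation ->
spot/RPKM composition -> gland enrichment -> cross-species Venn ->
concordance, and writes a consolidated JSON report that echoes every
threshold used.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from . import enrichment_markers as em
from . import quantification as qt
from .orf_peptides import ProteinSeq, Transcript, find_orfs, translate
from .peptide_matching import (ObservedPeptide, build_library, match_peptides,
                               summarize_matches)
from .synthetic_data import SimulationConfig, default_config, generate_dataset
from .toxin_annotation import (FamilyAssignment, ReferenceEntry, ScoringParams,
                               annotate_all)

__all__ = [
    "ConcordanceRow",
    "PipelineSettings",
    "build_concordance",
    "family_ratio",
    "cross_species_fold",
    "spearman_concordance",
    "run_pipeline",
]


@dataclass(frozen=True)
class ConcordanceRow:
    species: str
    family: str
    protein_percent: float
    transcript_percent: float
    log2_ratio: float
    flag: str                      # concordant | protein-biased | transcript-biased


@dataclass
class PipelineSettings:
    """Every tunable the pipeline uses, echoed verbatim into the report."""

    tau: float = 0.4               # annotation norm-score threshold
    theta: float = 0.95            # clustering identity threshold
    min_coverage: float = 0.8      # clustering length-ratio floor
    alpha: float = 0.05            # enrichment significance level
    min_lfc: float = 1.0           # volcano fold-change floor
    epsilon: float = 0.1           # concordance pseudo-percent
    band: float = 1.0              # concordance |log2 ratio| band
    mass_window: tuple = (800.0, 4000.0)
    min_orf_aa: int = 50
    il_mode: bool = False


def build_concordance(protein_profile: qt.CompositionProfile,
                      transcript_profile: qt.CompositionProfile,
                      epsilon: float = 0.1,
                      band: float = 1.0) -> list[ConcordanceRow]:
    """Family-by-family comparison of harmonized composition profiles."""
    if protein_profile.species != transcript_profile.species:
        raise ValueError(
            f"species mismatch: {protein_profile.species} vs "
            f"{transcript_profile.species}")
    prot = protein_profile.toxin_only()
    tx = (transcript_profile if transcript_profile.denominator == "toxin-only"
          else transcript_profile.toxin_only())
    rows = []
    for fam in sorted(set(prot.percents) | set(tx.percents)):
        p = prot.percents.get(fam, 0.0)
        t = tx.percents.get(fam, 0.0)
        ratio = math.log2((p + epsilon) / (t + epsilon))
        if abs(ratio) <= band:
            flag = "concordant"
        elif ratio > 0:
            flag = "protein-biased"
        else:
            flag = "transcript-biased"
        rows.append(ConcordanceRow(prot.species, fam, p, t, ratio, flag))
    return rows


def family_ratio(profile: qt.CompositionProfile, fam_a: str, fam_b: str) -> float:
    """percent(fam_a) / percent(fam_b) within one profile."""
    b = profile.percents.get(fam_b, 0.0)
    if b <= 0:
        raise ValueError(f"family {fam_b} has zero percent; ratio undefined")
    return profile.percents.get(fam_a, 0.0) / b


def cross_species_fold(profile_a: qt.CompositionProfile,
                       profile_b: qt.CompositionProfile,
                       fam_x: str, fam_y: str) -> float:
    """How much larger the fam_x:fam_y ratio is in species A than B."""
    return family_ratio(profile_a, fam_x, fam_y) / family_ratio(profile_b, fam_x, fam_y)


def spearman_concordance(protein_percents, transcript_percents) -> float:
    """Spearman rank correlation between paired family percentages."""
    p = list(protein_percents)
    t = list(transcript_percents)
    if len(p) != len(t) or len(p) < 3:
        raise ValueError("need at least 3 paired families")
    return float(stats.spearmanr(p, t).statistic)


# ---------------------------------------------------------------------------
# pipeline


def _longest_orf_proteins(dataset) -> list[ProteinSeq]:
    proteins = []
    for sp in sorted(dataset.transcripts):
        for tid, seq in dataset.transcripts[sp]:
            orfs = find_orfs(Transcript(tid, seq, species=sp),
                             min_len_aa=50, longest_only=True)
            if not orfs:
                continue
            orf = orfs[0]
            proteins.append(ProteinSeq(tid, translate(orf.nt_seq), orf, sp))
    return proteins


def run_pipeline(config: SimulationConfig | None = None,
                 outdir: str | Path | None = None,
                 seed: int = 0,
                 settings: PipelineSettings | None = None) -> dict:
    """Simulate, analyze, and report.  Deterministic given config and seed."""
    settings = settings or PipelineSettings()
    if config is None:
        config = default_config(seed=seed)
    if not config.species:
        raise ValueError("configuration error: species list is empty")
    dataset, truth = generate_dataset(config)

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        dataset.write(out / "inputs", truth)

    # ORF calling + translation
    proteins = _longest_orf_proteins(dataset)
    by_species: dict[str, list[ProteinSeq]] = {}
    for p in proteins:
        by_species.setdefault(p.species, []).append(p)

    # panel annotation
    panel = [ReferenceEntry(pid, fam, aa, tox)
             for pid, fam, tox, aa in dataset.panel]
    params = ScoringParams(min_norm_score=settings.tau)
    assignments = annotate_all(proteins, panel, params)
    status = {a.query_id: a.status for a in assignments}
    family = {a.query_id: a.family for a in assignments
              if a.status == "toxin" and a.family}

    # transcript-level quantification
    rpkm = qt.add_rpkm(dataset.counts)
    report: dict = {"species": {}, "settings": {
        "tau": settings.tau, "theta": settings.theta,
        "min_coverage": settings.min_coverage, "alpha": settings.alpha,
        "min_lfc": settings.min_lfc, "epsilon": settings.epsilon,
        "band": settings.band, "mass_window": list(settings.mass_window),
        "min_orf_aa": settings.min_orf_aa, "il_mode": settings.il_mode,
        "seed": config.seed,
    }}

    enriched_by_species: dict[str, set] = {}
    seqs_by_id = {tid: seq for sp in dataset.transcripts
                  for tid, seq in dataset.transcripts[sp]}

    for sp in config.species:
        gland = rpkm[(rpkm.species == sp) & (rpkm.tissue == "gland")]
        muscle = rpkm[(rpkm.species == sp) & (rpkm.tissue == "muscle")]
        statuses = {o: status.get(o, "unidentified") for o in gland.otu_id}

        tox_gland = qt.toxin_fraction(gland, statuses, sp, "gland")
        tox_muscle = qt.toxin_fraction(muscle, statuses, sp, "muscle")
        tx_profile = qt.transcript_family_composition(gland, family, sp)

        spots = dataset.spots[dataset.spots.species == sp]
        prot_profile = qt.spot_family_composition(qt.normalize_spots(spots), sp)

        # peptide cross-matching
        lib = build_library(by_species.get(sp, []), mode="substring",
                            il_mode=settings.il_mode)
        observed = [ObservedPeptide(r.species, r.spot_id, r.peptide, r.ion_score)
                    for r in dataset.peptides.itertuples(index=False)
                    if r.species == sp]
        matches = match_peptides(observed, lib)
        summary = summarize_matches(matches)

        # gland enrichment
        n_g, n_m = int(gland["count"].sum()), int(muscle["count"].sum())
        muscle_map = dict(zip(muscle["otu_id"],
                              zip(muscle["count"], muscle["rpkm"])))
        results = []
        for otu, c_g, r_g in zip(gland["otu_id"], gland["count"], gland["rpkm"]):
            c_m, r_m = muscle_map[otu]
            pair = em.TissueCountPair(otu, int(c_g), int(c_m), n_g, n_m,
                                      float(r_g), float(r_m))
            results.append(em.gland_enrichment(pair, settings.alpha))
        em.adjust_enrichment(results)
        enriched = {r.otu_id for r in results if r.enriched}
        enriched_by_species[sp] = enriched

        concordance = build_concordance(prot_profile, tx_profile,
                                        settings.epsilon, settings.band)
        fams = sorted(set(prot_profile.toxin_only().percents)
                      & set(tx_profile.percents))
        rho = (spearman_concordance(
                   [prot_profile.toxin_only().percents[f] for f in fams],
                   [tx_profile.percents[f] for f in fams])
               if len(fams) >= 3 else None)

        report["species"][sp] = {
            "toxin_fraction_gland_percent": round(tox_gland.percent_toxin, 3),
            "toxin_fraction_muscle_percent": round(tox_muscle.percent_toxin, 4),
            "transcript_composition_percent": {
                k: round(v, 3) for k, v in sorted(tx_profile.percents.items())},
            "protein_composition_percent": {
                k: round(v, 3) for k, v in sorted(prot_profile.percents.items())},
            "identified_spot_percent": round(prot_profile.identified_percent, 2),
            "match_summary": {s.species: [s.n_matched, s.n_total] for s in summary},
            "n_gland_enriched": len(enriched),
            "concordance": [
                {"family": r.family,
                 "protein_percent": round(r.protein_percent, 3),
                 "transcript_percent": round(r.transcript_percent, 3),
                 "log2_ratio": round(r.log2_ratio, 4),
                 "flag": r.flag}
                for r in concordance],
            "spearman_rho": None if rho is None else round(rho, 4),
        }

    # cross-species Venn over gland-enriched toxin OTUs
    venn = None
    if len(config.species) == 3:
        labeled = [(sp, tid, seqs_by_id[tid])
                   for sp in config.species
                   for tid in sorted(enriched_by_species[sp])
                   if status.get(tid) == "toxin"]
        clusters = em.cluster_across_species(
            labeled, theta=settings.theta, min_coverage=settings.min_coverage)
        venn = em.venn_counts(clusters, config.species).summary()
        report["venn_toxin_otus"] = venn
        report["clusters"] = {
            cl.cluster_id: ["|".join(m) for m in cl.members] for cl in clusters}

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1))
        conc_rows = [
            {"species": sp, **row}
            for sp in report["species"]
            for row in report["species"][sp]["concordance"]]
        pd.DataFrame(conc_rows).to_csv(out / "concordance.tsv", sep="\t",
                                       index=False)
    return report
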