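"""Seeded synthetic venomics datasets with planted ground truth.

Emulates the study design of a three-pit-viper venomics experiment: venom
gland and muscle RNA-seq count tables over shared (orthologous) and
species-specific toxin gene clusters, 2-DE spot tables whose MW/pI derive
from the encoded proteins, and MALDI-identified tryptic peptides with a
controlled fraction of unmatched (decoy) observations.

Every quantity a recovery test needs is recorded in :class:`GroundTruth`.

Model summary
-------------
* Each toxin family has one ancestral protein carrying a conserved
  family-identifying 12-mer motif.  Ortholog clusters are nucleotide-mutated
  copies of the family ancestor (``family_divergence``), and each species'
  copy of a cluster is mutated a further ``divergence``/2 from the cluster
  ancestor, so ``divergence`` is the expected pairwise substitution rate
  BETWEEN two species' copies, while clusters of the same family stay well
  separated.
* Read counts are multinomial with category probability proportional to
  expression weight × transcript length, which makes RPKM an unbiased
  estimator of the planted expression weights.
* Muscle toxin expression is ``muscle_leak`` × gland expression (default
  1e-4), reproducing the near-absence of toxin transcripts in muscle.
* Spot intensities are planted protein-level family fractions times
  lognormal noise (sigma 0.2 by default), keeping intensities positive.
* Observed peptides are abundance-weighted tryptic peptides inside the
  800-4000 Da window; a ``decoy_fraction`` of them receive one residue
  substitution, rejection-sampled to be absent from every translated
  protein, so the planted matched fraction is exactly 1 - decoy_fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .orf_peptides import (
    _CODON_TABLE,
    STOP_CODONS,
    digest,
    in_mass_window,
    isoelectric_point,
    monoisotopic_mass,
    translate,
)

__all__ = [
    "FamilySpec",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "ConfigError",
    "generate_dataset",
    "generate_toxin_gene",
    "mutate_sequence",
    "sample_counts",
    "project_spot",
    "sample_observed_peptides",
    "default_config",
    "DEFAULT_SPECIES",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_FOR = {}
for _codon, _aa in _CODON_TABLE.items():
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()

_BASES = "ACGT"

DEFAULT_SPECIES = ("Gb", "Gi", "Gu")

# Family-identifying 12-mers.  The enzymatic families use their canonical
# catalytic/signature motifs (zinc-binding HExxHxxGxxHD for SVMP, the serine
# protease GDSGGP box, the Ca-binding loop CCFVHDCC of PLA2, the flavoenzyme
# GxGxxG dinucleotide-binding region of M-LAO, the VEGF cystine-knot CxCxC
# spacing); the remaining families carry fixed invented 12-mers.
DEFAULT_MOTIFS = {
    "SVMP": "HELGHNLGMNHD",
    "SVSP": "GDSGGPLICNGQ",
    "PLA2": "DRCCFVHDCCYG",
    "M-LAO": "VGAGMSGLSAAY",
    "CTL": "WNDQSCDSKHPF",
    "CRISP": "HNTWRSEVQKAW",
    "VEGF": "CSGCCSDESLAC",
}

# Mean protein lengths loosely matching the real families (SVMP ~470 aa
# P-III precursor, PLA2 ~140 aa precursor, ...).
_DEFAULT_FAMILY_SHAPES = {
    "SVMP": (470, 40), "SVSP": (260, 20), "PLA2": (140, 10),
    "M-LAO": (500, 40), "CTL": (150, 12), "CRISP": (220, 18),
    "VEGF": (145, 12),
}

# Planted transcript-level family composition (fraction of toxin RPKM) per
# species, mirroring the dominance structure of the real venom gland
# transcriptomes: SVMP-dominated Gb and Gu, SVSP-dominated Gi.
DEFAULT_TRANSCRIPT_COMPOSITION = {
    "Gb": {"SVMP": 0.827, "PLA2": 0.076, "SVSP": 0.065, "CRISP": 0.026,
           "M-LAO": 0.002, "CTL": 0.002, "VEGF": 0.002},
    "Gi": {"SVSP": 0.570, "PLA2": 0.307, "VEGF": 0.085, "SVMP": 0.010,
           "M-LAO": 0.010, "CTL": 0.0096, "CRISP": 0.0084},
    "Gu": {"SVMP": 0.677, "PLA2": 0.222, "SVSP": 0.048, "CRISP": 0.046,
           "M-LAO": 0.003, "CTL": 0.002, "VEGF": 0.002},
}

# Planted protein-level composition (fraction of TOTAL spot volume; the rest
# of the gel is unidentified spots), mirroring the 2-DE quantification:
# identified spots cover ~55.7/55.6/40.0% of the three gels.
DEFAULT_PROTEIN_COMPOSITION = {
    "Gb": {"SVMP": 0.3515, "M-LAO": 0.0562, "SVSP": 0.0400, "PLA2": 0.0354,
           "CTL": 0.0300, "CRISP": 0.0289, "VEGF": 0.0150},
    "Gi": {"SVSP": 0.2647, "PLA2": 0.1631, "VEGF": 0.0581, "SVMP": 0.0300,
           "CTL": 0.0150, "CRISP": 0.0131, "M-LAO": 0.0120},
    "Gu": {"SVMP": 0.1676, "PLA2": 0.1615, "M-LAO": 0.0221, "SVSP": 0.0200,
           "CRISP": 0.0150, "CTL": 0.0100, "VEGF": 0.0038},
}

# Planted fraction of gland expression coming from toxin genes per species
# (muscle gets ~leak x these, i.e. < 0.01%).
DEFAULT_GLAND_TOXIN_FRACTION = {"Gb": 0.373, "Gi": 0.300, "Gu": 0.468}


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class FamilySpec:
    """One toxin family: size, length distribution, expression and motif."""

    name: str
    motif: str
    length_aa: tuple[float, float] = (200.0, 20.0)
    gland_expression_scale: float = 1.0
    muscle_leak: float = 1e-4
    n_genes_per_species: int = 3

    def validate(self) -> None:
        if len(self.motif) != 12:
            raise ConfigError(f"families[{self.name}].motif must be a 12-mer")
        if any(a not in AA20 for a in self.motif):
            raise ConfigError(f"families[{self.name}].motif has nonstandard residues")
        if not 0.0 <= self.muscle_leak <= 0.01:
            raise ConfigError(f"families[{self.name}].muscle_leak outside [0, 0.01]")
        if self.n_genes_per_species < 0:
            raise ConfigError(f"families[{self.name}].n_genes_per_species negative")
        if self.length_aa[0] < 30:
            raise ConfigError(f"families[{self.name}].length_aa mean below 30")


@dataclass
class SimulationConfig:
    species: tuple[str, ...] = DEFAULT_SPECIES
    families: list[FamilySpec] = field(default_factory=list)
    ortholog_design: list[tuple[str, tuple[str, ...]]] | None = None
    divergence: float = 0.02
    family_divergence: float = 0.05
    n_background_genes: int = 30
    depth_gland: int = 200_000
    depth_muscle: int = 200_000
    n_observed_peptides: int = 100
    decoy_fraction: float = 0.6
    spot_noise_sigma: float = 0.2
    transcript_composition: dict | None = None
    protein_composition: dict | None = None
    gland_toxin_fraction: dict | float | None = None
    mass_window: tuple[float, float] = (800.0, 4000.0)
    seed: int = 0

    def __post_init__(self):
        if not self.families:
            self.families = [
                FamilySpec(name, DEFAULT_MOTIFS[name],
                           _DEFAULT_FAMILY_SHAPES[name])
                for name in DEFAULT_MOTIFS
            ]

    def validate(self) -> None:
        if not self.species:
            raise ConfigError("species list is empty")
        if len(set(self.species)) != len(self.species):
            raise ConfigError("species labels must be unique")
        for fam in self.families:
            fam.validate()
        if not 0.0 <= self.divergence <= 0.5:
            raise ConfigError("divergence outside [0, 0.5]")
        if not 0.0 <= self.family_divergence <= 0.5:
            raise ConfigError("family_divergence outside [0, 0.5]")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ConfigError("decoy_fraction outside [0, 1]")
        if self.depth_gland <= 0 or self.depth_muscle <= 0:
            raise ConfigError("depth_gland and depth_muscle must be positive")
        if self.n_observed_peptides < 0:
            raise ConfigError("n_observed_peptides negative")
        if self.n_background_genes < 1:
            raise ConfigError("n_background_genes must be at least 1")
        if self.ortholog_design is not None:
            fams = {f.name for f in self.families}
            for fam, subset in self.ortholog_design:
                if fam not in fams:
                    raise ConfigError(f"ortholog_design references unknown family {fam}")
                if not subset or any(s not in self.species for s in subset):
                    raise ConfigError("ortholog_design subset must be nonempty known species")

    # -- resolved study conditions -------------------------------------

    def resolved_design(self) -> list[tuple[str, tuple[str, ...]]]:
        """Explicit gene-cluster design: (family, species subset) per cluster.

        The default for three species places, per family, one cluster in all
        three species, two in alternating species pairs, and one private
        cluster per species, so every Venn region is populated.
        """
        if self.ortholog_design is not None:
            return [(fam, tuple(s for s in self.species if s in subset))
                    for fam, subset in self.ortholog_design]
        design = []
        sp = self.species
        for i, fam in enumerate(self.families):
            if len(sp) == 3:
                a, b, c = sp
                design += [(fam.name, (a, b, c)), (fam.name, (a, c)),
                           (fam.name, (a, b) if i % 2 == 0 else (b, c))]
                design += [(fam.name, (s,)) for s in sp]
            else:
                design += [(fam.name, tuple(sp))] * max(fam.n_genes_per_species, 1)
        return design

    def resolved_transcript_composition(self) -> dict:
        if self.transcript_composition is not None:
            table = self.transcript_composition
        elif set(self.species) <= set(DEFAULT_TRANSCRIPT_COMPOSITION):
            table = {s: DEFAULT_TRANSCRIPT_COMPOSITION[s] for s in self.species}
        else:
            scales = {f.name: f.gland_expression_scale for f in self.families}
            total = sum(scales.values())
            table = {s: {k: v / total for k, v in scales.items()}
                     for s in self.species}
        out = {}
        for s in self.species:
            row = {f.name: float(table[s].get(f.name, 0.0)) for f in self.families}
            tot = sum(row.values())
            if tot <= 0:
                raise ConfigError(f"transcript_composition for {s} sums to zero")
            out[s] = {k: v / tot for k, v in row.items()}
        return out

    def resolved_protein_composition(self) -> dict:
        if self.protein_composition is not None:
            table = self.protein_composition
        elif set(self.species) <= set(DEFAULT_PROTEIN_COMPOSITION):
            table = {s: DEFAULT_PROTEIN_COMPOSITION[s] for s in self.species}
        else:
            tc = self.resolved_transcript_composition()
            table = {s: {k: 0.5 * v for k, v in tc[s].items()} for s in self.species}
        return {s: {f.name: float(table[s].get(f.name, 0.0)) for f in self.families}
                for s in self.species}

    def resolved_gland_toxin_fraction(self) -> dict:
        if self.gland_toxin_fraction is None:
            frac = {s: DEFAULT_GLAND_TOXIN_FRACTION.get(s, 0.4)
                    for s in self.species}
        elif isinstance(self.gland_toxin_fraction, dict):
            missing = [s for s in self.species if s not in self.gland_toxin_fraction]
            if missing:
                raise ConfigError(f"gland_toxin_fraction missing species {missing}")
            frac = {s: float(self.gland_toxin_fraction[s]) for s in self.species}
        else:
            frac = {s: float(self.gland_toxin_fraction) for s in self.species}
        for s, v in frac.items():
            if not 0.0 < v < 1.0:
                raise ConfigError(f"gland_toxin_fraction[{s}] outside (0, 1)")
        return frac


@dataclass
class GroundTruth:
    """Planted quantities for recovery tests."""

    planted_composition: dict          # species -> family -> toxin fraction
    planted_protein_composition: dict  # species -> family -> fraction of gel
    gland_toxin_fraction: dict         # species -> fraction of gland reads
    cluster_membership: dict           # cluster id -> sorted species list
    transcript_family: dict            # transcript id -> family ('' = background)
    enriched_flags: dict               # transcript id -> gland-enriched truth
    peptide_origin: dict               # "<species>:<row>" -> source id | "decoy"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True, indent=1)


@dataclass
class SyntheticDataset:
    transcripts: dict                  # species -> list of (id, nt_seq)
    proteins: dict                     # transcript id -> aa_seq
    counts: pd.DataFrame               # otu_id, length, species, tissue, count
    spots: pd.DataFrame                # species, spot_id, mw_kda, pi, intensity, family
    peptides: pd.DataFrame             # species, spot_id, peptide, ion_score
    panel: list                        # (id, family, is_toxin, aa_seq)
    spot_protein: dict                 # spot id -> transcript id

    def write(self, outdir: str | Path, ground_truth: GroundTruth | None = None) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for sp in sorted(self.transcripts):
            with open(out / f"transcripts_{sp}.fasta", "w") as fh:
                for tid, seq in self.transcripts[sp]:
                    fh.write(f">{sp}|{tid}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i:i + 70] + "\n")
        self.counts.to_csv(out / "counts.tsv", sep="\t", index=False)
        self.spots.to_csv(out / "spots.tsv", sep="\t", index=False,
                          float_format="%.4f")
        self.peptides.to_csv(out / "peptides.tsv", sep="\t", index=False,
                             float_format="%.1f")
        with open(out / "panel.fasta", "w") as fh:
            for pid, family, is_toxin, aa in self.panel:
                flag = "toxin" if is_toxin else "nontoxin"
                fh.write(f">{pid}|{family}|{flag}\n")
                for i in range(0, len(aa), 70):
                    fh.write(aa[i:i + 70] + "\n")
        if ground_truth is not None:
            (out / "ground_truth.json").write_text(ground_truth.to_json())


# ---------------------------------------------------------------------------
# sequence-level generators


def _random_protein(length: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(AA20), size=length)
    return "".join(AA20[i] for i in idx)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    parts = []
    for aa in protein:
        codons = _CODONS_FOR[aa]
        parts.append(codons[rng.integers(0, len(codons))])
    parts.append(STOP_CODONS[rng.integers(0, 3)])
    return "".join(parts)


def generate_toxin_gene(spec: FamilySpec, rng: np.random.Generator) -> str:
    """One full CDS (ATG..stop) whose translation embeds the family motif."""
    spec.validate()
    mean, sd = spec.length_aa
    length = max(int(round(rng.normal(mean, sd))), len(spec.motif) + 20)
    core = _random_protein(length - 1, rng)
    pos = int(rng.integers(0, len(core) - len(spec.motif) + 1))
    core = core[:pos] + spec.motif + core[pos + len(spec.motif):]
    return _reverse_translate("M" + core, rng)


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Random nucleotide substitutions at the given per-site rate.

    Length is preserved; the start codon and the final codon are never
    touched; a substitution that would create a new in-frame (frame 0) stop
    codon is redirected to another base, keeping full-CDS inputs translatable.
    """
    if not 0.0 <= rate <= 0.5:
        raise ValueError(f"substitution rate {rate} outside [0, 0.5]")
    if rate == 0.0 or len(seq) < 7:
        return seq
    chars = list(seq)
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for pos in hit:
        if pos < 3 or pos >= len(seq) - 3:
            continue
        options = [b for b in _BASES if b != chars[pos]]
        order = rng.permutation(len(options))
        c0 = 3 * (pos // 3)
        for k in order:
            old = chars[pos]
            chars[pos] = options[k]
            codon = "".join(chars[c0:c0 + 3])
            if len(codon) < 3 or codon not in STOP_CODONS:
                break
            chars[pos] = old
    return "".join(chars)


def sample_counts(weights, lengths, depth: int, rng: np.random.Generator):
    """Multinomial read counts with P(category) ∝ weight × length.

    RPKM divides counts by length, so this sampling scheme makes RPKM an
    unbiased estimate of the expression weights.
    """
    w = np.asarray(weights, dtype=float)
    ln = np.asarray(lengths, dtype=float)
    if w.shape != ln.shape:
        raise ValueError("weights and lengths differ in shape")
    if np.any(w < 0):
        raise ValueError("negative expression weight")
    mass = w * ln
    total = mass.sum()
    if total <= 0:
        raise ValueError("total expression weight is zero")
    return rng.multinomial(depth, mass / total)


def project_spot(protein: str, abundance: float, rng: np.random.Generator,
                 noise_sigma: float = 0.2) -> tuple[float, float, float]:
    """Project a protein onto the 2-DE gel: (MW kDa, pI, intensity).

    MW is the monoisotopic mass / 1000; pI is clamped to the pH 3-10
    gradient of the gel strip; intensity is abundance × lognormal noise
    (exactly abundance when ``noise_sigma`` is 0).
    """
    if not protein:
        raise ValueError("empty protein")
    mw_kda = monoisotopic_mass(protein) / 1000.0
    pi = float(np.clip(isoelectric_point(protein), 3.0, 10.0))
    intensity = float(abundance * np.exp(rng.normal(0.0, noise_sigma)))
    return mw_kda, pi, intensity


def sample_observed_peptides(proteins, n: int, delta: float,
                             rng: np.random.Generator, *,
                             mass_window=(800.0, 4000.0), max_missed: int = 2,
                             library=None) -> list[dict]:
    """Draw n observed peptides from abundance-weighted proteins.

    ``proteins`` is a sequence of (id, aa_seq, abundance).  Each draw picks a
    protein (probability ∝ abundance), then a uniform in-window tryptic
    peptide of it.  A ``delta`` fraction become decoys: one random residue
    substitution, rejection-sampled until the mutant occurs in no protein of
    ``library`` (default: the input proteins), so decoys are guaranteed
    unmatched.  Returns dicts with aa_seq / origin / spot source id.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta outside [0, 1]")
    lo, hi = mass_window
    lib = list(library) if library is not None else [p[1] for p in proteins]
    menu = []
    for pid, aa, abundance in proteins:
        peps = sorted({p.aa_seq for p in digest(aa, max_missed)
                       if in_mass_window(p, lo, hi)})
        if peps and abundance > 0:
            menu.append((pid, peps, float(abundance)))
    if not menu:
        raise ValueError("no protein yields an in-window tryptic peptide")
    probs = np.array([m[2] for m in menu])
    probs /= probs.sum()
    records = []
    for _ in range(n):
        pid, peps, _ = menu[rng.choice(len(menu), p=probs)]
        pep = peps[rng.integers(0, len(peps))]
        origin = pid
        if rng.random() < delta:
            for _attempt in range(500):
                pos = int(rng.integers(0, len(pep)))
                alt = AA20[rng.integers(0, len(AA20))]
                if alt == pep[pos]:
                    continue
                mutant = pep[:pos] + alt + pep[pos + 1:]
                if not any(mutant in seq for seq in lib):
                    pep, origin = mutant, "decoy"
                    break
            else:  # pragma: no cover - rejection sampling essentially never fails
                raise RuntimeError("could not construct a decoy peptide")
        score = float(np.round(rng.uniform(20.0, 90.0), 1))
        records.append({"aa_seq": pep, "origin": origin, "source": pid,
                        "ion_score": score})
    return records


# ---------------------------------------------------------------------------
# full dataset


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study conditions with a given seed."""
    return SimulationConfig(seed=seed, **overrides)


def generate_dataset(config: SimulationConfig) -> tuple[SyntheticDataset, GroundTruth]:
    """Generate the full four-table dataset plus ground truth, deterministically."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = list(config.species)
    fam_by_name = {f.name: f for f in config.families}
    design = config.resolved_design()
    comp_tx = config.resolved_transcript_composition()
    comp_prot = config.resolved_protein_composition()
    toxin_frac = config.resolved_gland_toxin_fraction()

    # family ancestors (also the reference panel)
    family_gene = {f.name: generate_toxin_gene(f, rng) for f in config.families}

    # ortholog clusters and species copies
    transcripts = {sp: [] for sp in species}
    transcript_family: dict[str, str] = {}
    cluster_membership: dict[str, list[str]] = {}
    genes_in = {sp: {f.name: [] for f in config.families} for sp in species}
    cluster_ancestor: dict[str, str] = {}
    for idx, (fam, subset) in enumerate(design):
        cid = f"{fam}_c{idx:03d}"
        ancestor = mutate_sequence(family_gene[fam], config.family_divergence, rng)
        cluster_ancestor[cid] = ancestor
        cluster_membership[cid] = sorted(subset, key=species.index)
        for sp in cluster_membership[cid]:
            tid = f"{cid}_{sp}"
            # divergence is the pairwise rate BETWEEN species' copies, so
            # each copy diverges divergence/2 from the cluster ancestor
            seq = mutate_sequence(ancestor, config.divergence / 2.0, rng)
            transcripts[sp].append((tid, seq))
            transcript_family[tid] = fam
            genes_in[sp][fam].append(tid)

    # background (non-toxin, species-private) genes
    for sp in species:
        for i in range(config.n_background_genes):
            length = max(int(round(rng.normal(250, 40))), 80)
            gene = _reverse_translate("M" + _random_protein(length - 1, rng), rng)
            tid = f"BG{i:03d}_{sp}"
            transcripts[sp].append((tid, gene))
            transcript_family[tid] = ""

    proteins = {tid: translate(seq)
                for sp in species for tid, seq in transcripts[sp]}

    # expression weights and counts
    count_rows = []
    for sp in species:
        ids = [tid for tid, _ in transcripts[sp]]
        lengths = np.array([len(seq) for _, seq in transcripts[sp]], dtype=float)
        w_gland = np.zeros(len(ids))
        w_muscle = np.zeros(len(ids))
        bg_ids = [tid for tid in ids if transcript_family[tid] == ""]
        bg_w = rng.dirichlet(np.ones(len(bg_ids))) * (1.0 - toxin_frac[sp])
        bg_map = dict(zip(bg_ids, bg_w))
        for k, tid in enumerate(ids):
            fam = transcript_family[tid]
            if fam:
                share = comp_tx[sp][fam] / max(len(genes_in[sp][fam]), 1)
                w_gland[k] = toxin_frac[sp] * share
                w_muscle[k] = fam_by_name[fam].muscle_leak * w_gland[k]
            else:
                w_gland[k] = bg_map[tid]
                w_muscle[k] = bg_map[tid]
        for tissue, weights, depth in (("gland", w_gland, config.depth_gland),
                                       ("muscle", w_muscle, config.depth_muscle)):
            counts = sample_counts(weights, lengths, depth, rng)
            for tid, ln, c in zip(ids, lengths, counts):
                count_rows.append((tid, int(ln), sp, tissue, int(c)))
    counts_df = pd.DataFrame(
        count_rows, columns=["otu_id", "length", "species", "tissue", "count"])

    # 2-DE spots
    spot_rows = []
    spot_protein: dict[str, str] = {}
    for sp in species:
        idx = 0
        for fam in (f.name for f in config.families):
            members = genes_in[sp][fam]
            frac = comp_prot[sp][fam]
            if not members or frac <= 0:
                continue
            for tid in members:
                sid = f"{sp}_s{idx:02d}"
                idx += 1
                mw, pi, inten = project_spot(
                    proteins[tid], frac / len(members), rng,
                    config.spot_noise_sigma)
                spot_rows.append((sp, sid, mw, pi, inten, fam))
                spot_protein[sid] = tid
        identified = sum(comp_prot[sp].values())
        bg_ids = [tid for tid, _ in transcripts[sp]
                  if transcript_family[tid] == ""][:10]
        for tid in bg_ids:
            sid = f"{sp}_s{idx:02d}"
            idx += 1
            mw, pi, inten = project_spot(
                proteins[tid], (1.0 - identified) / len(bg_ids), rng,
                config.spot_noise_sigma)
            spot_rows.append((sp, sid, mw, pi, inten, ""))
            spot_protein[sid] = tid
    spots_df = pd.DataFrame(
        spot_rows,
        columns=["species", "spot_id", "mw_kda", "pi", "intensity", "family"])

    # observed tryptic peptides (per species, with planted decoy fraction)
    all_proteins = sorted(proteins.values())
    pep_rows = []
    peptide_origin: dict[str, str] = {}
    for sp in species:
        sp_spots = spots_df[spots_df.species == sp]
        items = [(sid, proteins[spot_protein[sid]], inten)
                 for sid, inten in zip(sp_spots.spot_id, sp_spots.intensity)]
        recs = sample_observed_peptides(
            items, config.n_observed_peptides, config.decoy_fraction, rng,
            mass_window=config.mass_window, library=all_proteins)
        for i, rec in enumerate(recs):
            sid = rec["source"]
            pep_rows.append((sp, sid, rec["aa_seq"], rec["ion_score"]))
            origin = rec["origin"]
            peptide_origin[f"{sp}:{i}"] = (
                "decoy" if origin == "decoy" else spot_protein[origin])
    peptides_df = pd.DataFrame(
        pep_rows, columns=["species", "spot_id", "peptide", "ion_score"])

    # reference panel: the family ancestors plus each cluster (paralog)
    # ancestor as a known family member — real toxin panels carry many
    # reference isoforms per family — plus non-toxin (background) entries
    panel = [(f"REF_{fam}", fam, True, translate(gene))
             for fam, gene in family_gene.items()]
    panel += [(f"REF_{cid}", cid.split("_c")[0], True, translate(seq))
              for cid, seq in cluster_ancestor.items()]
    first_sp = species[0]
    for tid, _ in transcripts[first_sp]:
        if transcript_family[tid] == "":
            panel.append((f"REF_{tid}", f"NONTOXIN-{tid}", False, proteins[tid]))
        if sum(1 for p in panel if not p[2]) >= 3:
            break

    truth = GroundTruth(
        planted_composition=comp_tx,
        planted_protein_composition=comp_prot,
        gland_toxin_fraction=toxin_frac,
        cluster_membership=cluster_membership,
        transcript_family=transcript_family,
        enriched_flags={tid: bool(fam) for tid, fam in transcript_family.items()},
        peptide_origin=peptide_origin,
    )
    dataset = SyntheticDataset(
        transcripts=transcripts, proteins=proteins, counts=counts_df,
        spots=spots_df, peptides=peptides_df, panel=panel,
        spot_protein=spot_protein)
    return dataset, truth
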