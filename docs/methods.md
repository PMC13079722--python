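# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, in the spirit of a methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Sequence chemistry

**ORF prediction.** All six frames of a transcript are scanned; an ORF runs
from an ATG to the first in-frame stop (TAA/TAG/TGA), stop included, with a
default minimum of 50 aa. Every ATG defines its own ORF, so nested starts
sharing a stop are all reported; `longest_only` keeps the single longest
(ties: + strand first, then smallest start). Coordinates are 0-based
half-open and strand-local (minus-strand ORFs index into the reverse
complement). 3′-partial ORFs (no stop before the sequence end) are off by
default and available via a flag. The caller behind real venomics CDS sets
is unnamed and version-dependent; this scanner is the simplest defensible
predictor and is verified against an exhaustive (strand, start, end)
enumeration oracle for sequences ≤ 300 nt.

**Translation** uses the standard genetic code. A trailing stop is
stripped; an *internal* stop raises an error rather than truncating, so
frame mistakes surface immediately; any codon containing N yields X.

**Tryptic digestion** cleaves C-terminal to K or R except before P and
returns all peptides with 0–2 missed cleavages by default. Two structural
identities are enforced by tests: the 0-missed peptides concatenate back to
the protein, and m-missed peptides are exactly the in-order concatenations
of m+1 consecutive 0-missed peptides. Monoisotopic masses are the residue
sums plus one water (18.010565 Da), cross-checked against pyteomics.

**Mass window.** The MALDI acquisition range m/z 800–4000 is applied to the
*neutral* monoisotopic mass; the ~1.007 Da proton of the singly charged ion
is negligible against the 3200 Da window and is ignored. The window is
inclusive at both ends.

**Mascot score** is −10·log₁₀(P) (log base 10, the standard Mascot
definition; P is the random-match probability).

**Isoelectric point** solves net charge = 0 by bisection on pH 0–14
(tolerance well below 10⁻³) using the EMBOSS pKa set (N-term 8.6, C-term
3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1). pI here only
positions simulated spots on the gel's pH 3–10 axis, so internal
consistency — verified against a 10⁻⁴-step grid scan — is what matters, not
agreement with any particular published pKa set.

## Peptide matching

The default library mode is **substring**: an observed peptide matches if
it occurs contiguously in any translated protein. This makes no assumption
about tryptic termini on the library side; a **tryptic** mode (library keys
restricted to in-window digest peptides) is available for stricter
searches. MALDI peptide mass fingerprinting cannot distinguish I from L, so
`il_mode` collapses both to a common symbol on both sides; it defaults to
off but is recommended for PMF data. Ambiguity codes B/Z/X never match
unless an explicit wildcard flag is set (conservative matching). A peptide
matching several proteins counts once in the per-species matched/total
summary; `matched_ids` preserves the multiplicity.

## Toxin annotation

Real venomics annotation pipelines search external databases whose content
changes over time. To keep annotation self-contained and testable, this
package instead aligns each translated query against a **labeled reference
panel** with Smith–Waterman local alignment (BLOSUM62; affine gaps with
open 11, extend 1, a gap of length k costing `open + (k−1)·extend` — the
common protein-search parameterization). This is a deliberate replacement
for database search, not a reproduction of it.

Scores are normalized by the query's self-alignment score, giving a
length-robust value in [0, 1] that needs no database statistics. Queries
below τ = 0.4 are *unidentified*; otherwise the best panel entry (ties to
the lexicographically smallest reference id) sets the family and the
toxin / non-toxin status. Non-toxin calls therefore require explicit
NONTOXIN panel entries, which the synthetic panel provides. The engine is
Biopython's PairwiseAligner; tests pin it to a brute-force enumeration of
all local alignments for sequences ≤ 6 aa.

## Quantification

Two denominators are kept deliberately different, matching how each omic
level is conventionally reported: protein-level family percentages are
fractions of the **total** spot volume (so unidentified spots dilute them
and the family percentages sum to the identified coverage), while
transcript-level percentages are fractions of **toxin-only** RPKM (and sum
to 100). RPKM is `C·10⁹/(L·N)`; RPKM and FPKM are treated as synonymous
abundance measures here, and the expression transform is `log₁₀(v + 0.1)`.
For spot tables, normalization is per gel over all detected spots — the
reading consistent with identified-spot coverages being quoted as
percentages of the whole gel.

## Enrichment and markers

**Gland enrichment.** The underlying study design pools individuals into
single gland and muscle libraries, so no replicate-aware dispersion model
is fittable. Enrichment is therefore a two-sided **Fisher exact test** on
pooled counts (`[[c_g, N_g − c_g], [c_m, N_m − c_m]]`) — an explicit
substitute, not a reproduction of an unnamed test. log₂ fold changes use a
0.1 RPKM pseudocount; an OTU is gland-enriched when p < α = 0.05 *and* the
fold change is positive. Multiple testing uses Benjamini–Hochberg (the
conventional choice where only "adjusted p" is specified); volcano
classification requires adjusted p < 0.05 and |log₂FC| ≥ 1 (the fold floor
is configurable).

**Cross-species OTU matching.** Identity between transcripts is estimated
by k-mer containment `C = |K_a ∩ K_b| / min(|K_a|, |K_b|)` mapped to
per-site identity as `C^(1/k)` (k = 8; a k-mer survives only if all k sites
match); pairs where the shorter sequence is under 200 nt use exact global
alignment identity (edlib) instead. Clusters are single-linkage connected
components over edges with identity ≥ θ = 0.95 and length ratio ≥ 0.8,
deterministic after sorting inputs by (species, otu). θ and the coverage
floor are configurable and echoed in every report.

**Venn conventions.** Three-species region counts are reported both as
exclusive regions and as pairwise-inclusive counts (pair counts that
include the triple region). The inclusive convention is the one under
which reported unique/pairwise/triple counts and their percentage shares
are mutually consistent (unique 81/94/52 + pairwise-only 140/40/11 +
triple 149 gives a union of 567, reproducing the quoted 26.3 / 51.0 /
14.3 % shares); both are emitted, inclusive marked as the quoting
convention.

**Term enrichment** is the upper-tail hypergeometric P(X ≥ k) over a
user-supplied term→members map with BH adjustment across terms — a generic
stand-in for GO enrichment that needs no ontology download (no DAG
propagation).

## Concordance

Before comparison, the protein profile is renormalized to the toxin-only
denominator so both profiles sum to 100. Per family,
`log₂((p + ε)/(t + ε))` with pseudo-percent ε = 0.1; |ratio| ≤ 1 is
concordant, above protein-biased, below transcript-biased. The band width
of one doubling matches the qualitative discrepancy calls this comparison
is meant to quantify (e.g. a family with two-thirds of toxin RPKM but a
minority of gel volume flags transcript-biased). Spearman ρ over paired
family percentages summarizes each species' overall agreement.

## Synthetic data generator

The generator's defaults *are* the study conditions the pipeline targets:

* **Three species** (Gb, Gi, Gu) × gland/muscle, library depth 2×10⁵ reads
  each — deep enough that composition recovery is sampling-noise limited
  (multinomial error ≪ 2 percentage points), small enough to run in
  seconds.
* **Seven toxin families** (SVMP, SVSP, PLA2, M-LAO, CTL, CRISP, VEGF)
  with protein lengths loosely matching the real families, each carrying a
  conserved 12-mer motif (canonical signature regions for the enzymatic
  families, fixed invented 12-mers otherwise).
* **Planted transcript compositions** mirroring the real venom gland
  dominance structure (Gb: SVMP 82.7 % of toxin RPKM; Gi: SVSP 57.0 %; Gu:
  SVMP 67.7 %) and planted protein-level compositions mirroring the 2-DE
  quantification (identified spots ≈ 55.7 / 55.6 / 40.0 % of gel volume).
* **Gland toxin fractions** 37.3 / 30.0 / 46.8 % of gland expression;
  muscle toxin expression is `muscle_leak` × gland expression (default
  10⁻⁴), reproducing the < 0.1 % muscle toxin fraction.
* **Ortholog design**: per family, one cluster shared by all three
  species, two clusters in alternating species pairs, and one private
  cluster per species — populating every Venn region. `divergence` (default
  0.02) is the expected *pairwise* substitution rate between two species'
  copies, so each copy diverges `divergence/2` from its cluster ancestor;
  clusters within a family diverge at `family_divergence` (default 0.05),
  keeping same-family clusters well below the θ = 0.95 merge threshold.
  The reference panel contains the family ancestors plus every cluster
  ancestor (real panels carry many reference isoforms per family), so a
  query's distance to its nearest panel entry is `divergence` itself.
* **Counts** are multinomial with category probability ∝ expression ×
  length, which makes RPKM an unbiased estimator of the planted weights —
  recovery tests are exact in expectation.
* **Spots**: MW = monoisotopic mass / 1000, pI clamped to the gel's pH
  3–10 gradient, intensity = planted abundance × lognormal noise
  (σ = 0.2; strictly positive, exact when σ = 0).
* **Observed peptides** (default 100/species; the matched/total columns of
  a real MS evidence table are the emulated object): abundance-weighted
  tryptic peptides inside the 800–4000 Da window. A `decoy_fraction`
  (default 0.6, mirroring the ~40 % transcriptome-match rate of real
  MALDI evidence) receives one random residue substitution,
  rejection-sampled until absent from *every* translated protein, so the
  planted matched fraction is exactly 1 − δ in expectation.

Substitutions never touch the start codon or the final codon and are
redirected away from creating new in-frame stops, so every emitted
transcript remains a full-length translatable CDS; this slightly constrains
the substitution process but keeps per-site rates accurate to well within
the tolerances the tests use.

**What the generator does not emulate** — and hence what green tests do
not show about real data: sequencing-read error and assembly artifacts
(transcripts are emitted directly, not assembled), isoform/allele
collapse, gel co-migration (each spot is one protein), spot saturation,
Mascot scoring behavior (ion scores are decorative draws), PTMs and
non-tryptic termini, and database incompleteness (the panel always
contains the true families). Conclusions about recovery therefore concern
the pipeline's arithmetic and statistical machinery, not upstream data
quality.

## Problem sizes and determinism

Default runs use 42 toxin gene clusters (≈ 70 toxin transcripts across
species), 30 background genes per species, depth 2×10⁵ per library and 100
observed peptides per species — sized so the full pipeline completes in
seconds while keeping every recovery margin comfortable. All randomness
flows from one `numpy.random.default_rng(seed)`; outputs (tables, FASTA,
JSON reports) are written with fixed ordering and formatting, so identical
configurations and seeds reproduce byte-identical files.

## Known limitations

* The Fisher test on pooled counts understates biological variability;
  with replicated designs a negative-binomial model would replace it.
* Self-score normalization penalizes queries much longer than their best
  panel match; fragment queries score high against full-length references
  but not vice versa.
* The k-mer identity estimate assumes roughly uniform divergence; strongly
  clustered mutations or large indels bias it (the exact-alignment path
  covers only short sequences).
* The three-way toxin / non-toxin / unidentified split depends entirely on
  panel coverage; an impoverished panel inflates "unidentified".
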