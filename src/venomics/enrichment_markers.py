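"""Gland-enrichment testing, cross-species OTU clustering, Venn partitioning,
reference-species ranking, and generic term enrichment.

The study design has pooled libraries without replicates, so gland-vs-muscle
enrichment is assessed with a two-sided Fisher exact test on pooled read
counts — an explicit substitute for a replicate-aware model, not a
reproduction of one.  Cross-species OTU matching uses a k-mer containment
identity estimate (exact alignment identity for short sequences) with
greedy single-linkage clustering at a configurable identity threshold.

Venn counts for three species are reported in BOTH conventions: exclusive
regions (each OTU cluster in exactly one region) and pairwise-inclusive
counts (pairs including the triple region), the latter being how shared-OTU
counts are conventionally quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import edlib
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TissueCountPair",
    "EnrichmentResult",
    "SequenceCluster",
    "VennCounts",
    "TermEnrichment",
    "fisher_exact_2x2",
    "gland_enrichment",
    "adjust_enrichment",
    "bh_adjust",
    "volcano_classify",
    "estimate_identity",
    "cluster_across_species",
    "venn_counts",
    "venn_from_region_counts",
    "rank_by_reference",
    "term_enrichment",
]


@dataclass(frozen=True)
class TissueCountPair:
    otu_id: str
    count_gland: int
    count_muscle: int
    total_gland: int
    total_muscle: int
    rpkm_gland: float
    rpkm_muscle: float

    def __post_init__(self):
        if self.total_gland <= 0 or self.total_muscle <= 0:
            raise ValueError("library totals must be positive")
        if not (0 <= self.count_gland <= self.total_gland
                and 0 <= self.count_muscle <= self.total_muscle):
            raise ValueError("counts must lie within library totals")


@dataclass
class EnrichmentResult:
    otu_id: str
    log2fc: float
    p: float
    padj: float
    enriched: bool


@dataclass(frozen=True)
class SequenceCluster:
    cluster_id: str
    members: tuple  # of (species, otu_id)

    @property
    def species_set(self) -> frozenset:
        return frozenset(sp for sp, _ in self.members)


@dataclass
class VennCounts:
    """Region counts for a 3-species Venn partition of OTU clusters."""

    unique: dict                 # species -> count (single-species region)
    pairwise_exclusive: dict     # frozenset({a, b}) -> count (pair region only)
    triple: int
    union_size: int

    def pairwise_inclusive(self, a: str, b: str) -> int:
        return self.pairwise_exclusive[frozenset((a, b))] + self.triple

    def share_percent(self, count: int) -> float:
        return 100.0 * count / self.union_size if self.union_size else 0.0

    def summary(self) -> dict:
        pairs = sorted(self.pairwise_exclusive, key=sorted)
        return {
            "union_size": self.union_size,
            "unique": dict(sorted(self.unique.items())),
            "unique_percent": {k: round(self.share_percent(v), 1)
                               for k, v in sorted(self.unique.items())},
            "pairwise_exclusive": {"&".join(sorted(p)): self.pairwise_exclusive[p]
                                   for p in pairs},
            "pairwise_inclusive": {"&".join(sorted(p)): self.pairwise_inclusive(*sorted(p))
                                   for p in pairs},
            "pairwise_inclusive_percent": {
                "&".join(sorted(p)): round(
                    self.share_percent(self.pairwise_inclusive(*sorted(p))), 1)
                for p in pairs},
            "triple": self.triple,
            "triple_percent": round(self.share_percent(self.triple), 1),
        }


@dataclass(frozen=True)
class TermEnrichment:
    term: str
    k: int   # study hits
    n: int   # study size
    K: int   # population hits
    M: int   # population size
    p: float
    padj: float


# ---------------------------------------------------------------------------
# differential gland/muscle enrichment


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sum of hypergeometric probabilities (fixed margins) of tables at most
    as probable as the observed one.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be nonnegative integers")
    return float(min(stats.fisher_exact([[a, b], [c, d]],
                                        alternative="two-sided")[1], 1.0))


def gland_enrichment(pair: TissueCountPair, alpha: float = 0.05) -> EnrichmentResult:
    """Fisher test of gland vs muscle pooled counts for one OTU.

    log2 fold change uses a 0.1 RPKM pseudocount; 'enriched' means raw
    p < alpha with a positive fold change (padj is filled in batch by
    :func:`adjust_enrichment`).
    """
    p = fisher_exact_2x2(pair.count_gland, pair.total_gland - pair.count_gland,
                         pair.count_muscle, pair.total_muscle - pair.count_muscle)
    log2fc = math.log2((pair.rpkm_gland + 0.1) / (pair.rpkm_muscle + 0.1))
    return EnrichmentResult(pair.otu_id, log2fc, p, p,
                            enriched=(p < alpha and log2fc > 0))


def adjust_enrichment(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Fill Benjamini-Hochberg adjusted p-values across a result batch."""
    if not results:
        return results
    padj = bh_adjust([r.p for r in results])
    for r, q in zip(results, padj):
        r.padj = float(q)
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano_classify(log2fc: float, padj: float, alpha: float = 0.05,
                     min_lfc: float = 1.0) -> str:
    """Volcano-plot class: 'up_in_A', 'up_in_B' or 'ns'."""
    if not (math.isfinite(log2fc) and math.isfinite(padj)):
        raise ValueError("inputs must be finite")
    if padj < alpha and log2fc >= min_lfc:
        return "up_in_A"
    if padj < alpha and log2fc <= -min_lfc:
        return "up_in_B"
    return "ns"


# ---------------------------------------------------------------------------
# cross-species OTU clustering and Venn partitioning


def _alignment_identity(a: str, b: str) -> float:
    """Global alignment identity: matched columns / alignment columns."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = cols = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return matches / cols if cols else 0.0


def estimate_identity(seq_a: str, seq_b: str, k: int = 8) -> float:
    """Sequence identity in [0, 1].

    Short sequences (min length < 200) get exact global-alignment identity;
    longer pairs get a k-mer containment estimate C = |shared k-mers| /
    min(|k-mers|), mapped to per-site identity as C**(1/k) (a k-mer survives
    only if all k sites match).
    """
    if min(len(seq_a), len(seq_b)) < k:
        raise ValueError(f"sequences must be at least k={k} long")
    if min(len(seq_a), len(seq_b)) < 200:
        return _alignment_identity(seq_a, seq_b)
    km_a = {seq_a[i:i + k] for i in range(len(seq_a) - k + 1)}
    km_b = {seq_b[i:i + k] for i in range(len(seq_b) - k + 1)}
    containment = len(km_a & km_b) / min(len(km_a), len(km_b))
    return containment ** (1.0 / k) if containment > 0 else 0.0


def cluster_across_species(sequences, theta: float = 0.95,
                           min_coverage: float = 0.8,
                           k: int = 8) -> list[SequenceCluster]:
    """Greedy single-linkage clustering of (species, otu_id, seq) triples.

    Edges join pairs with identity >= theta and length ratio (shorter /
    longer) >= min_coverage; connected components are clusters.  Input is
    sorted by (species, otu_id) first, so the result is deterministic.
    """
    items = sorted(sequences, key=lambda t: (t[0], t[1]))
    if not items:
        raise ValueError("no sequences to cluster")
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i, j in combinations(range(n), 2):
        sa, sb = items[i][2], items[j][2]
        ratio = min(len(sa), len(sb)) / max(len(sa), len(sb))
        if ratio < min_coverage:
            continue
        if estimate_identity(sa, sb, k) >= theta:
            union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for cidx, root in enumerate(sorted(groups)):
        members = tuple((items[i][0], items[i][1]) for i in groups[root])
        clusters.append(SequenceCluster(f"CL{cidx:04d}", members))
    return clusters


def venn_counts(clusters, species) -> VennCounts:
    """Region counts for exactly three species from OTU clusters."""
    species = tuple(species)
    if len(species) != 3 or len(set(species)) != 3:
        raise ValueError("venn_counts requires exactly 3 distinct species")
    unique = {s: 0 for s in species}
    pairwise = {frozenset(p): 0 for p in combinations(species, 2)}
    triple = 0
    union = 0
    for cl in clusters:
        present = cl.species_set & set(species)
        if not present:
            continue
        union += 1
        if len(present) == 1:
            unique[next(iter(present))] += 1
        elif len(present) == 2:
            pairwise[frozenset(present)] += 1
        else:
            triple += 1
    return VennCounts(unique, pairwise, triple, union)


def venn_from_region_counts(unique: dict, pairwise_inclusive: dict,
                            triple: int) -> VennCounts:
    """Build VennCounts from reported region counts.

    ``pairwise_inclusive`` follows the convention in which each pairwise
    shared count includes the OTUs shared by all three species.
    """
    pairwise_exclusive = {frozenset(p): v - triple
                          for p, v in pairwise_inclusive.items()}
    if any(v < 0 for v in pairwise_exclusive.values()):
        raise ValueError("pairwise-inclusive count below the triple count")
    union = sum(unique.values()) + sum(pairwise_exclusive.values()) + triple
    return VennCounts(dict(unique), pairwise_exclusive, triple, union)


# ---------------------------------------------------------------------------
# ranking and term enrichment


def rank_by_reference(expression, family: str, reference_species: str) -> list[str]:
    """Family members ordered by descending reference-species expression.

    ``expression`` is a DataFrame with columns otu_id, species, rpkm and
    family.  Ties break by ascending otu_id.
    """
    if reference_species not in set(expression["species"]):
        raise ValueError(f"unknown reference species {reference_species!r}")
    sub = expression[(expression["family"] == family)
                     & (expression["species"] == reference_species)]
    ranked = sub.sort_values(["rpkm", "otu_id"], ascending=[False, True])
    return list(dict.fromkeys(ranked["otu_id"]))


def term_enrichment(study, population, term_map) -> list[TermEnrichment]:
    """Hypergeometric upper-tail enrichment of study hits per term.

    P(X >= k) with population size M, K term members in the population and a
    study of size n containing k term members; BH-adjusted across terms.
    """
    study = set(study)
    population = set(population)
    stray = study - population
    if stray:
        raise ValueError(f"study members outside the population: {sorted(stray)[:5]}")
    M, n = len(population), len(study)
    rows = []
    for term in sorted(term_map):
        members = set(term_map[term]) & population
        K = len(members)
        k = len(members & study)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append((term, k, n, K, M, min(p, 1.0)))
    padj = bh_adjust([r[5] for r in rows]) if rows else []
    return [TermEnrichment(*row, float(q)) for row, q in zip(rows, padj)]
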