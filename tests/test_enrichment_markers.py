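"""Enrichment statistics, sequence clustering, Venn partitioning, ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from Bio import Align
from hypothesis import given, settings, strategies as st

from venomics.enrichment_markers import (
    TissueCountPair,
    bh_adjust,
    cluster_across_species,
    estimate_identity,
    fisher_exact_2x2,
    gland_enrichment,
    rank_by_reference,
    term_enrichment,
    venn_counts,
    venn_from_region_counts,
    volcano_classify,
)
from venomics.synthetic_data import mutate_sequence

from _oracles import bh_stepup, fisher_two_sided, hypergeom_upper_tail


# ---------------------------------------------------------------------------
# Fisher exact test


def test_balanced_table_has_p_one():
    assert fisher_exact_2x2(5, 5, 5, 5) == 1.0


def test_fisher_row_column_symmetry():
    assert fisher_exact_2x2(8, 2, 1, 9) == pytest.approx(fisher_exact_2x2(8, 1, 2, 9))
    assert fisher_exact_2x2(8, 2, 1, 9) == pytest.approx(fisher_exact_2x2(1, 9, 8, 2))


def test_fisher_rejects_negative_entries():
    with pytest.raises(ValueError):
        fisher_exact_2x2(-1, 2, 3, 4)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
def test_fisher_matches_rational_enumeration_oracle(a, b, c, d):
    # all margins <= 30
    assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
        fisher_two_sided(a, b, c, d), rel=1e-6, abs=1e-12)


def test_gland_enrichment_decision_rule():
    equal = TissueCountPair("x", 50, 50, 100_000, 100_000, 5.0, 5.0)
    r = gland_enrichment(equal)
    assert not r.enriched and r.log2fc == 0.0 and r.p > 0.9
    strong = TissueCountPair("y", 100, 0, 100_000, 100_000, 10.0, 0.0)
    r = gland_enrichment(strong)
    assert r.enriched and r.p < 1e-6 and r.log2fc > 0
    # significance alone is not enough: muscle-biased OTUs are never "gland enriched"
    inverted = TissueCountPair("z", 0, 100, 100_000, 100_000, 0.0, 10.0)
    assert not gland_enrichment(inverted).enriched


# ---------------------------------------------------------------------------
# multiple testing and volcano classification


def test_bh_adjust_reference_cases():
    assert bh_adjust([0.2]).tolist() == [0.2]
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


@settings(max_examples=80, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=25))
def test_bh_adjust_matches_stepup_oracle_and_dominates_p(pvals):
    adj = bh_adjust(pvals)
    assert np.allclose(adj, bh_stepup(pvals))
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    order = np.argsort(pvals)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_bh_adjust_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@pytest.mark.parametrize("lfc,padj,expected", [
    (3.0, 0.5, "ns"),
    (3.0, 0.01, "up_in_A"),
    (-2.0, 0.01, "up_in_B"),
    (0.5, 0.001, "ns"),           # below the fold-change floor
])
def test_volcano_classification(lfc, padj, expected):
    assert volcano_classify(lfc, padj) == expected
    flipped = {"up_in_A": "up_in_B", "up_in_B": "up_in_A", "ns": "ns"}[expected]
    assert volcano_classify(-lfc, padj) == flipped


# ---------------------------------------------------------------------------
# identity estimation and clustering


def _aligned_identity_oracle(a, b):
    """Independent global-alignment identity via Biopython."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    matches = sum(1 for x, y in zip(str(aln[0]), str(aln[1]))
                  if x == y and x != "-")
    return matches / aln.length


def test_identity_extremes():
    seq = "ACGTTGCA" * 40
    assert estimate_identity(seq, seq) == 1.0
    other = "TTTTGGGG" * 40
    assert estimate_identity(seq, other) == 0.0
    with pytest.raises(ValueError):
        estimate_identity("ACGT", seq)


def test_kmer_identity_tracks_alignment_identity_at_low_divergence():
    rng = np.random.default_rng(31)
    base = "ATG" + "".join(rng.choice(list("ACGT"), size=994)) + "TAA"
    for seed in range(4):
        mutant = mutate_sequence(base, 0.02, np.random.default_rng(seed))
        est = estimate_identity(base, mutant)
        ref = _aligned_identity_oracle(base, mutant)
        assert est == pytest.approx(ref, abs=0.02)


def test_clustering_extremes():
    seq = "ACGTTGCA" * 40
    same = [("A", "a1", seq), ("B", "b1", seq), ("C", "c1", seq)]
    clusters = cluster_across_species(same)
    assert len(clusters) == 1 and len(clusters[0].members) == 3
    rng = np.random.default_rng(37)
    distinct = [(sp, f"{sp}1", "".join(rng.choice(list("ACGT"), size=320)))
                for sp in ("A", "B", "C")]
    assert len(cluster_across_species(distinct)) == 3


def test_clustering_recovers_planted_orthologs_exactly(default_sim):
    ds, gt = default_sim
    labeled = [(sp, tid, seq) for sp in ds.transcripts
               for tid, seq in ds.transcripts[sp] if gt.transcript_family[tid]]
    clusters = cluster_across_species(labeled, theta=0.95, min_coverage=0.8)
    found = {frozenset(otu for _, otu in c.members) for c in clusters}
    truth = {}
    for tid, fam in gt.transcript_family.items():
        if fam:
            truth.setdefault(tid.rsplit("_", 1)[0], set()).add(tid)
    assert found == set(map(frozenset, truth.values()))


# ---------------------------------------------------------------------------
# Venn partitioning


class _Cluster:
    def __init__(self, species):
        self.species_set = frozenset(species)


def test_venn_counts_hand_tally_across_all_regions():
    clusters = [_Cluster(s) for s in
                [("A",), ("A",), ("B",), ("C",),
                 ("A", "B"), ("A", "C"), ("A", "C"), ("B", "C"),
                 ("A", "B", "C"), ("A", "B", "C"), ("A", "B", "C")]]
    v = venn_counts(clusters, ("A", "B", "C"))
    assert v.unique == {"A": 2, "B": 1, "C": 1}
    assert v.pairwise_exclusive == {frozenset("AB"): 1, frozenset("AC"): 2,
                                    frozenset("BC"): 1}
    assert v.triple == 3 and v.union_size == 11
    assert v.pairwise_inclusive("A", "C") == 5
    assert v.unique["A"] + v.unique["B"] + v.unique["C"] + \
        sum(v.pairwise_exclusive.values()) + v.triple == v.union_size


def test_venn_counts_all_single_species():
    clusters = [_Cluster(("A",)), _Cluster(("B",))]
    v = venn_counts(clusters, ("A", "B", "C"))
    assert v.triple == 0 and all(n == 0 for n in v.pairwise_exclusive.values())


def test_venn_requires_exactly_three_species():
    with pytest.raises(ValueError):
        venn_counts([], ("A", "B"))
    with pytest.raises(ValueError):
        venn_counts([], ("A", "B", "C", "D"))


def test_venn_from_region_counts_inclusive_convention():
    v = venn_from_region_counts(
        {"A": 2, "B": 1, "C": 1},
        {frozenset("AB"): 4, frozenset("AC"): 5, frozenset("BC"): 4}, 3)
    assert v.pairwise_exclusive == {frozenset("AB"): 1, frozenset("AC"): 2,
                                    frozenset("BC"): 1}
    assert v.union_size == 11
    with pytest.raises(ValueError):
        venn_from_region_counts({"A": 1, "B": 1, "C": 1},
                                {frozenset("AB"): 1, frozenset("AC"): 2,
                                 frozenset("BC"): 2}, 2)


# ---------------------------------------------------------------------------
# ranking and term enrichment


def test_rank_by_reference_sorting_and_determinism():
    df = pd.DataFrame({
        "otu_id": ["o1", "o2", "o3"], "species": "Gb", "family": "SVMP",
        "rpkm": [10.0, 5.0, 20.0],
    })
    assert rank_by_reference(df, "SVMP", "Gb") == ["o3", "o1", "o2"]
    shuffled = df.sample(frac=1.0, random_state=3)
    assert rank_by_reference(shuffled, "SVMP", "Gb") == ["o3", "o1", "o2"]
    single = df.iloc[:1]
    assert rank_by_reference(single, "SVMP", "Gb") == ["o1"]
    with pytest.raises(ValueError, match="reference species"):
        rank_by_reference(df, "SVMP", "Gx")


def test_term_enrichment_closed_forms():
    population = [f"g{i}" for i in range(20)]
    study = population[:5]
    full_term = {"all": population}
    [res] = term_enrichment(study, population, full_term)
    assert res.p == pytest.approx(1.0)
    perfect = {"hit": population[:5]}
    [res] = term_enrichment(study, population, perfect)
    assert res.p == pytest.approx(1.0 / math.comb(20, 5))
    with pytest.raises(ValueError, match="outside the population"):
        term_enrichment(["zz"], population, full_term)


def test_term_enrichment_matches_enumeration_for_small_populations():
    rng = np.random.default_rng(41)
    population = [f"g{i}" for i in range(12)]  # M <= 15
    for _ in range(6):
        n = int(rng.integers(1, 8))
        study = list(rng.choice(population, size=n, replace=False))
        K = int(rng.integers(1, 10))
        term = {"t": population[:K]}
        [res] = term_enrichment(study, population, term)
        k = len(set(study) & set(population[:K]))
        assert res.k == k
        assert res.p == pytest.approx(hypergeom_upper_tail(12, K, n, k), rel=1e-9)
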