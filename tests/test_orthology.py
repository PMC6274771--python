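"""Protein alignment and the two-track ortholog identification."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from florevol.orthology import (
    align_proteins,
    assign_orthologs,
    bit_score,
    domain_track_candidates,
    multi_assigned,
    reciprocal_best_hit,
)
from florevol.records import GeneRecord, OrthologAssignment
from florevol.simulate import simulate_proteomes

_B62 = substitution_matrices.load("BLOSUM62")
_NEG = float("-inf")


def oracle_align_score(a, b, mode, open_=10.0, ext=1.0):
    """Independent Gotoh affine-gap DP (gap of length L costs
    open + (L-1) * extend), exhaustive over the three-state recursion."""
    n, m = len(a), len(b)
    local = mode == "local"
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -open_ - (i - 1) * ext
        if local:
            M[i][0] = 0.0
    for j in range(1, m + 1):
        Y[0][j] = -open_ - (j - 1) * ext
        if local:
            M[0][j] = 0.0
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            if local:
                M[i][j] = max(M[i][j], s, 0.0)
                best = max(best, M[i][j])
            X[i][j] = max(M[i - 1][j] - open_, X[i - 1][j] - ext)
            Y[i][j] = max(M[i][j - 1] - open_, Y[i][j - 1] - ext)
    return best if local else max(M[n][m], X[n][m], Y[n][m])


# ---------------------------------------------------------------------------
# align_proteins
# ---------------------------------------------------------------------------

def test_self_alignment_is_perfect():
    res = align_proteins("MKTAYIAKQR", "MKTAYIAKQR", mode="local")
    assert res.identity_pct == 100.0
    assert res.coverage_a == res.coverage_b == 1.0


def test_textbook_local_alignment_score_matches_dp_oracle():
    # frozen from the oracle below: optimal local BLOSUM62 score, open 10 / ext 1
    assert oracle_align_score("HEAGAWGHEE", "PAWHEAE", "local") == 18.0
    res = align_proteins("HEAGAWGHEE", "PAWHEAE", mode="local", gap_open=10, gap_extend=1)
    assert res.score == 18.0


@pytest.mark.parametrize("mode", ["local", "global"])
@pytest.mark.parametrize("seed", range(6))
def test_alignment_scores_match_dp_oracle_on_random_pairs(mode, seed):
    rng = np.random.default_rng(seed)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    a = "".join(aa[i] for i in rng.integers(0, 20, size=int(rng.integers(5, 30))))
    b = "".join(aa[i] for i in rng.integers(0, 20, size=int(rng.integers(5, 30))))
    assert align_proteins(a, b, mode=mode).score == pytest.approx(
        oracle_align_score(a, b, mode)
    )


def test_disjoint_sequences_have_zero_identity():
    res = align_proteins("AAAA", "CCCC", mode="global")
    assert res.identity_pct == 0.0


def test_alignment_input_validation():
    with pytest.raises(ValueError):
        align_proteins("", "MKT")
    with pytest.raises(ValueError):
        align_proteins("MKT", "MK9T")
    align_proteins("MKXT", "MKT")  # X is allowed


def test_bit_score_is_monotone():
    assert bit_score(200) > bit_score(100) > bit_score(0)


# ---------------------------------------------------------------------------
# domain track
# ---------------------------------------------------------------------------

def _rec(gene_id, protein, domains=(), species="Brassica"):
    return GeneRecord(gene_id=gene_id, species=species, protein=protein,
                      domains=frozenset(domains))


@pytest.fixture()
def long_protein():
    rng = np.random.default_rng(42)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(0, 20, size=200))


def test_domain_track_keeps_shared_domain_full_identity(long_protein):
    q = _rec("ATQ1", long_protein, {"D1"}, species="Athaliana")
    t = _rec("BRT1", long_protein, {"D1", "D9"})
    hits = domain_track_candidates([t], [q])
    assert [h.brassica_gene for h in hits["ATQ1"]] == ["BRT1"]
    assert hits["ATQ1"][0].identity_pct == 100.0


def test_domain_track_rejects_low_query_coverage(long_protein):
    q = _rec("ATQ1", long_protein, {"D1"}, species="Athaliana")
    fragment = long_protein[: len(long_protein) * 2 // 5]  # 40% of the query
    t = _rec("BRT1", fragment, {"D1"})
    hits = domain_track_candidates([t], [q])
    assert hits["ATQ1"] == []


def test_domain_track_rejects_disjoint_domains_despite_identity(long_protein):
    q = _rec("ATQ1", long_protein, {"D1"}, species="Athaliana")
    t = _rec("BRT1", long_protein, {"D2"})
    hits = domain_track_candidates([t], [q])
    assert hits["ATQ1"] == []


def test_domain_track_skips_domainless_queries(long_protein):
    q = _rec("ATQ1", long_protein, frozenset(), species="Athaliana")
    t = _rec("BRT1", long_protein, {"D1"})
    assert domain_track_candidates([t], [q]) == {}


# ---------------------------------------------------------------------------
# reciprocal best hit
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def identical_proteomes():
    return simulate_proteomes(
        n_families=20, n_lost=0, n_duplicated=0, divergence=0.0, seed=3
    )


def test_rbh_on_identical_proteomes_is_identity_mapping(identical_proteomes):
    queries, targets, truth = identical_proteomes
    pairs = reciprocal_best_hit(queries, targets)
    assert {(a.brassica_gene, a.arabidopsis_query) for a in pairs} == set(
        truth.ortholog_pairs
    )
    assert all(a.identity_pct == 100.0 for a in pairs)


def test_rbh_is_symmetric(identical_proteomes):
    queries, targets, _ = identical_proteomes
    fwd = {(a.brassica_gene, a.arabidopsis_query)
           for a in reciprocal_best_hit(queries, targets)}
    # swapping the input roles yields the same pairs with roles reversed
    rev = {(a.arabidopsis_query, a.brassica_gene)
           for a in reciprocal_best_hit(targets, queries)}
    assert rev == fwd


def test_rbh_empty_sets_allowed():
    assert reciprocal_best_hit([], []) == []


def test_rbh_drops_pairs_failing_coverage(long_protein):
    q = _rec("ATQ1", long_protein, species="Athaliana")
    t = _rec("BRT1", long_protein[:60], species="Brassica")  # 30% of the query
    assert reciprocal_best_hit([q], [t]) == []


# ---------------------------------------------------------------------------
# combined assignment
# ---------------------------------------------------------------------------

def test_assign_orthologs_rejects_duplicate_ids(long_protein):
    q = _rec("ATQ1", long_protein, {"D1"}, species="Athaliana")
    with pytest.raises(ValueError):
        assign_orthologs([], [q, q])


def test_method_tags_partition_by_query_domain_emptiness():
    queries, targets, truth = simulate_proteomes(
        n_families=40, n_lost=4, n_duplicated=0, divergence=0.05, seed=7
    )
    assignments, lost = assign_orthologs(targets, queries)
    domained = {q.gene_id for q in queries if q.domains}
    for a in assignments:
        expected = "domain_intersect" if a.arabidopsis_query in domained else "reciprocal_best"
        assert a.method == expected


def test_lost_queries_are_exactly_the_lost_families():
    queries, targets, truth = simulate_proteomes(
        n_families=40, n_lost=4, n_duplicated=0, divergence=0.05, seed=7
    )
    assignments, lost = assign_orthologs(targets, queries)
    with_copy = {q for _, q in truth.ortholog_pairs}
    assert set(lost) == {q.gene_id for q in queries} - with_copy
    assert len(lost) == 4


def test_no_retained_assignment_below_half_coverage(proteome_recovery):
    *_, assignments, _ = proteome_recovery
    assert all(a.coverage >= 0.5 for a in assignments)
    with pytest.raises(ValueError):
        OrthologAssignment("b", "a", "reciprocal_best", 90.0, 0.4, 100.0)


def test_multi_assignment_flagging():
    a1 = OrthologAssignment("b1", "q1", "domain_intersect", 90.0, 1.0, 100.0)
    a2 = OrthologAssignment("b1", "q2", "domain_intersect", 88.0, 1.0, 90.0)
    a3 = OrthologAssignment("b2", "q1", "domain_intersect", 90.0, 1.0, 100.0)
    assert multi_assigned([a1, a2, a3]) == {"b1": ["q1", "q2"]}
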