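"""Li-Wu-Luo estimator: site classification, counting, correction, combination.

The independent oracle used throughout derives codon degeneracy and the
LWL85 formulas from Biopython's codon table, separately from the package's
own genetic-code table and counting code.
"""

from __future__ import annotations

import itertools
import math

import pytest
from Bio.Data import CodonTable

from florevol.errors import EmptyAlignmentError, FrameError, SaturationError
from florevol.kaks import (
    CodonAlignment,
    classify_selection,
    codon_align,
    compute_kaks,
    count_sites_and_differences,
    k2p_correct,
    kaks_from_cds_pair,
    site_degeneracy,
    translate_cds,
)
from florevol.simulate import simulate_codon_pair

# ---------------------------------------------------------------------------
# independent oracle: degeneracy and single-difference LWL85 from Biopython
# ---------------------------------------------------------------------------

_BIO_TABLE = CodonTable.unambiguous_dna_by_id[1]
_SENSE = sorted(set(_BIO_TABLE.forward_table) - set(_BIO_TABLE.stop_codons))


def oracle_degeneracy(codon: str, position: int) -> int:
    aa = _BIO_TABLE.forward_table[codon]
    p = position - 1
    syn = 0
    for base in "ACGT":
        if base == codon[p]:
            continue
        alt = codon[:p] + base + codon[p + 1 :]
        if alt not in _BIO_TABLE.stop_codons and _BIO_TABLE.forward_table[alt] == aa:
            syn += 1
    return {3: 4, 0: 0}.get(syn, 2)


def oracle_is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def oracle_single_diff_kaks(codon_pairs):
    """LWL85 on codon pairs with <= 1 difference each, straight from the
    published formulas (no multi-hit enumeration needed)."""
    L = {0: 0.0, 2: 0.0, 4: 0.0}
    S = {0: 0.0, 2: 0.0, 4: 0.0}
    V = {0: 0.0, 2: 0.0, 4: 0.0}
    for ca, cb in codon_pairs:
        for pos in (1, 2, 3):
            L[oracle_degeneracy(ca, pos)] += 0.5
            L[oracle_degeneracy(cb, pos)] += 0.5
        diffs = [p for p in range(3) if ca[p] != cb[p]]
        assert len(diffs) <= 1
        for p in diffs:
            da, db = oracle_degeneracy(ca, p + 1), oracle_degeneracy(cb, p + 1)
            tab = S if oracle_is_transition(ca[p], cb[p]) else V
            if da == db:
                tab[da] += 1.0
            else:
                tab[da] += 0.5
                tab[db] += 0.5

    def k2p(P, Q):
        if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
            return None  # saturated: correction undefined
        A = 0.5 * math.log(1 / (1 - 2 * P - Q)) - 0.25 * math.log(1 / (1 - 2 * Q))
        B = 0.5 * math.log(1 / (1 - 2 * Q))
        return A, B

    AB = {}
    for cls in (0, 2, 4):
        P = S[cls] / L[cls] if L[cls] else 0.0
        Q = V[cls] / L[cls] if L[cls] else 0.0
        AB[cls] = k2p(P, Q)
    if any(v is None for v in AB.values()):
        return None, None, L
    K0 = sum(AB[0])
    K4 = sum(AB[4])
    ks = 3 * (L[2] * AB[2][0] + L[4] * K4) / (L[2] + 3 * L[4])
    ka = 3 * (L[0] * K0 + L[2] * AB[2][1]) / (3 * L[0] + 2 * L[2])
    return ka, ks, L


# ---------------------------------------------------------------------------
# translation and codon alignment
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "cds,protein",
    [("ATGGCT", "MA"), ("ATGGCTTAA", "MA"), ("atggct", "MA"), ("GGGGGA", "GG")],
)
def test_translate_cds(cds, protein):
    assert translate_cds(cds) == protein


@pytest.mark.parametrize("cds", ["ATGTAAGCT", "ATGGC", "ATGNNN"])
def test_translate_rejects_bad_frames(cds):
    with pytest.raises(FrameError):
        translate_cds(cds)


def test_codon_align_identical_sequences_is_gap_free():
    aln = codon_align("ATGGCTGGG", "ATGGCTGGG")
    assert aln.gapped_cds_a == aln.gapped_cds_b == "ATGGCTGGG"


def test_codon_align_inserts_whole_codon_gap():
    aln = codon_align("ATGGCTGCT", "ATGGCT")
    assert len(aln.gapped_cds_a) == len(aln.gapped_cds_b) == 9
    assert aln.gapped_cds_a.replace("-", "") == "ATGGCTGCT"
    assert aln.gapped_cds_b.replace("-", "") == "ATGGCT"
    assert aln.gapped_cds_b.count("-") == 3  # one whole-codon gap


@pytest.mark.parametrize("seed", range(5))
def test_codon_align_gaps_are_codon_multiples(seed):
    import numpy as np

    from florevol.simulate import random_cds

    rng = np.random.default_rng(seed)
    a = random_cds(int(rng.integers(10, 40)), rng)
    b = random_cds(int(rng.integers(10, 40)), rng)
    aln = codon_align(a, b)
    assert aln.gapped_cds_a.count("-") % 3 == 0
    assert aln.gapped_cds_b.count("-") % 3 == 0
    CodonAlignment(aln.gapped_cds_a, aln.gapped_cds_b)  # invariants hold


# ---------------------------------------------------------------------------
# degeneracy classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "codon,position,expected",
    [("GGG", 3, 4), ("GGG", 1, 0), ("GGG", 2, 0), ("ATT", 3, 2), ("ATG", 3, 0)],
)
def test_site_degeneracy_examples(codon, position, expected):
    assert site_degeneracy(codon, position) == expected


def test_site_degeneracy_matches_code_table_oracle_everywhere():
    for codon in _SENSE:
        for pos in (1, 2, 3):
            assert site_degeneracy(codon, pos) == oracle_degeneracy(codon, pos), (
                codon, pos,
            )


def test_site_degeneracy_rejects_stop_codons():
    with pytest.raises(ValueError):
        site_degeneracy("TAA", 1)


# ---------------------------------------------------------------------------
# site/difference counting
# ---------------------------------------------------------------------------

def test_hand_fixture_glycine_transition():
    """10 GGG codons vs 9 GGG + 1 GGA: one synonymous transition at a
    fourfold site; L0=20, L4=10."""
    aln = CodonAlignment("GGG" * 10, "GGG" * 9 + "GGA")
    c = count_sites_and_differences(aln)
    assert (c.L0, c.L2, c.L4) == (20.0, 0.0, 10.0)
    assert c.S4 == 1.0
    assert c.S0 == c.S2 == c.V0 == c.V2 == c.V4 == 0.0


def test_identical_sequences_have_no_differences():
    aln = CodonAlignment("ATGGCTAAA", "ATGGCTAAA")
    c = count_sites_and_differences(aln)
    assert c.S0 + c.S2 + c.S4 + c.V0 + c.V2 + c.V4 == 0.0


@pytest.mark.parametrize("seed", range(8))
def test_multi_difference_counts_are_conserved(seed):
    """For any codon pair, attributed differences sum to the Hamming count."""
    import numpy as np

    rng = np.random.default_rng(seed)
    pairs = []
    while len(pairs) < 20:
        ca, cb = (
            _SENSE[rng.integers(len(_SENSE))],
            _SENSE[rng.integers(len(_SENSE))],
        )
        if ca != cb:
            pairs.append((ca, cb))
    for ca, cb in pairs:
        c = count_sites_and_differences(CodonAlignment(ca, cb))
        n_diff = sum(1 for x, y in zip(ca, cb) if x != y)
        total = c.S0 + c.S2 + c.S4 + c.V0 + c.V2 + c.V4
        assert total == pytest.approx(n_diff, abs=1e-9)


def test_all_gap_alignment_is_an_error():
    with pytest.raises(EmptyAlignmentError):
        count_sites_and_differences(CodonAlignment("---", "---"))


def test_gapped_columns_are_excluded():
    aln = CodonAlignment("GGG" + "---", "GGG" + "AAA")
    c = count_sites_and_differences(aln)
    assert c.L0 + c.L2 + c.L4 == 3.0  # one ungapped column only


# ---------------------------------------------------------------------------
# K2P correction and combination
# ---------------------------------------------------------------------------

def test_k2p_zero_proportions():
    assert k2p_correct(0.0, 0.0) == (0.0, 0.0)


def test_k2p_transitions_only():
    A, B = k2p_correct(0.1, 0.0)
    assert A == pytest.approx(0.5 * math.log(1.25), abs=1e-9)
    assert A == pytest.approx(0.11157, abs=1e-4)
    assert B == 0.0


def test_k2p_saturation():
    with pytest.raises(SaturationError):
        k2p_correct(0.5, 0.1)


def test_compute_kaks_identical_pair_is_undefined_ratio():
    aln = CodonAlignment("GGGAAATTT", "GGGAAATTT")
    res = compute_kaks(count_sites_and_differences(aln))
    assert res.ka == 0.0 and res.ks == 0.0
    assert res.ratio is None
    assert res.selection_class == "undefined"


def test_compute_kaks_hand_fixture_value():
    aln = CodonAlignment("GGG" * 10, "GGG" * 9 + "GGA")
    res = compute_kaks(count_sites_and_differences(aln))
    assert res.ka == 0.0
    assert res.ks == pytest.approx(0.1116, abs=1e-4)


@pytest.mark.parametrize("seed", range(10))
def test_small_alignments_match_independent_oracle(seed):
    """<=5-codon alignments with <=1 difference per codon agree exactly with
    the Biopython-table oracle."""
    import numpy as np

    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(2, 6))
    pairs = []
    for _ in range(n):
        ca = _SENSE[rng.integers(len(_SENSE))]
        if rng.random() < 0.6:
            p = int(rng.integers(0, 3))
            for base in "ACGT":
                cb = ca[:p] + base + ca[p + 1 :]
                if cb != ca and cb not in _BIO_TABLE.stop_codons:
                    break
            else:
                cb = ca
        else:
            cb = ca
        pairs.append((ca, cb))
    aln = CodonAlignment("".join(p[0] for p in pairs), "".join(p[1] for p in pairs))
    counts = count_sites_and_differences(aln)
    res = compute_kaks(counts)
    ka, ks, L = oracle_single_diff_kaks(pairs)
    assert counts.L0 == pytest.approx(L[0])
    assert counts.L2 == pytest.approx(L[2])
    assert counts.L4 == pytest.approx(L[4])
    if ka is None:  # oracle saturated; the estimator must agree
        assert res.ka is None and res.ks is None
    else:
        assert res.ka == pytest.approx(ka, abs=1e-12)
        assert res.ks == pytest.approx(ks, abs=1e-12)


def test_site_totals_partition_alignment_length():
    for seed in range(5):
        a, b = simulate_codon_pair(60, 0.3, 2.0, 0.2, seed)
        c = count_sites_and_differences(CodonAlignment(a, b))
        assert c.L0 + c.L2 + c.L4 == pytest.approx(3 * 60)


@pytest.mark.parametrize("seed", range(5))
def test_estimate_is_symmetric_in_sequence_order(seed):
    a, b = simulate_codon_pair(200, 0.4, 2.0, 0.4, seed)
    r1 = kaks_from_cds_pair(a, b)
    r2 = kaks_from_cds_pair(b, a)
    assert r1.ka == pytest.approx(r2.ka, abs=1e-12)
    assert r1.ks == pytest.approx(r2.ks, abs=1e-12)


def test_ks_monotone_in_synonymous_transitions():
    """Adding synonymous transitions at fourfold sites never decreases Ks."""
    n = 30
    prev = -1.0
    for k in range(0, 8):
        b = "GGA" * k + "GGG" * (n - k)
        res = compute_kaks(count_sites_and_differences(CodonAlignment("GGG" * n, b)))
        assert res.ks >= prev
        prev = res.ks


# ---------------------------------------------------------------------------
# selection classes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ratio,expected",
    [(0.2052, "negative"), (1.0874, "positive"), (1.0, "neutral"), (None, "undefined")],
)
def test_classify_selection(ratio, expected):
    assert classify_selection(ratio) == expected


def test_classify_selection_tolerance_band():
    assert classify_selection(0.9989, tolerance=0.05) == "neutral"
    assert classify_selection(0.9989, tolerance=0.0) == "negative"


def test_classify_selection_rejects_negative_ratio():
    with pytest.raises(ValueError):
        classify_selection(-0.1)
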