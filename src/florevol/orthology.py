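"""Two-track ortholog identification between a Brassica proteome and
A. thaliana queries.

Queries carrying functional-domain annotations go down the *domain track*:
a Brassica gene is a candidate iff it shares at least one domain ID with
the query (standing in for a profile search hit) AND a pairwise protein
alignment passes the score and 50%-coverage thresholds; the two conditions
are intersected.  Queries without any annotated domain go down the
*reciprocal-best-hit track*: each must be its candidate's best hit and vice
versa, under the same alignment thresholds.

Alignments use an affine-gap BLOSUM62 aligner.  In place of a
database-dependent E-value cutoff, scores are converted to bit scores with
fixed Karlin-Altschul constants (lambda = 0.267, K = 0.041, the ungapped
BLOSUM62 values) and thresholded at 50 bits by default; the threshold is a
parameter everywhere it is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import GeneRecord, OrthologAssignment

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

KARLIN_ALTSCHUL_LAMBDA = 0.267
KARLIN_ALTSCHUL_K = 0.041

DEFAULT_MIN_BITS = 50.0
DEFAULT_MIN_COVERAGE = 0.5
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def bit_score(raw_score: float) -> float:
    """Convert a raw BLOSUM62 alignment score to bits."""
    return (KARLIN_ALTSCHUL_LAMBDA * raw_score - math.log(KARLIN_ALTSCHUL_K)) / math.log(2.0)


@dataclass
class AlignmentResult:
    score: float
    identity_pct: float
    coverage_a: float
    coverage_b: float
    aligned_a: str
    aligned_b: str

    @property
    def bits(self) -> float:
        return bit_score(self.score)


def _make_aligner(mode: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _BLOSUM62
    # Biopython convention: a gap of length L costs open + (L-1) * extend.
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _validate_protein(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"{label}: empty protein sequence")
    seq = seq.upper()
    bad = set(seq) - _AA_ALPHABET
    if bad:
        raise ValueError(f"{label}: unknown residues {sorted(bad)}")
    return seq


def align_proteins(
    a: str,
    b: str,
    mode: str = "local",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal pairwise protein alignment under BLOSUM62 with affine gaps.

    Identity is computed over aligned columns excluding gaps; coverage is
    the aligned span divided by the sequence length (per sequence).
    """
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    a = _validate_protein(a, "a")
    b = _validate_protein(b, "b")
    aligner = _make_aligner(mode, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    matches = compared = 0
    for ca, cb in zip(ga, gb):
        if ca == "-" or cb == "-":
            continue
        compared += 1
        if ca == cb:
            matches += 1
    identity_pct = 100.0 * matches / compared if compared else 0.0
    blocks = alignment.aligned  # ((a-segments), (b-segments))
    if len(blocks[0]):
        span_a = blocks[0][-1][1] - blocks[0][0][0]
        span_b = blocks[1][-1][1] - blocks[1][0][0]
    else:
        span_a = span_b = 0
    return AlignmentResult(
        score=float(alignment.score),
        identity_pct=identity_pct,
        coverage_a=span_a / len(a),
        coverage_b=span_b / len(b),
        aligned_a=ga,
        aligned_b=gb,
    )


def alignment_score(
    a: str,
    b: str,
    mode: str = "local",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Score-only alignment (no traceback); used for all-vs-all screens."""
    aligner = _make_aligner(mode, gap_open, gap_extend)
    return float(aligner.score(a.upper(), b.upper()))


def _passes(
    res: AlignmentResult, min_bits: float, min_coverage: float, coverage_on: str
) -> bool:
    if coverage_on == "query":
        cov = res.coverage_b  # by convention b is the query in this module
    elif coverage_on == "min":
        cov = min(res.coverage_a, res.coverage_b)
    else:
        raise ValueError(f"coverage_on must be 'query' or 'min', got {coverage_on!r}")
    return res.bits >= min_bits and cov >= min_coverage


def domain_track_candidates(
    targets: Sequence[GeneRecord],
    queries: Sequence[GeneRecord],
    min_bits: float = DEFAULT_MIN_BITS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> dict[str, list[OrthologAssignment]]:
    """Domain-intersection candidates for domain-containing queries.

    For each query, targets sharing >= 1 domain ID are aligned (local mode);
    those passing the score and query-side coverage thresholds are retained.
    Queries with an empty domain set are skipped (they belong to the
    reciprocal track) rather than raising.
    """
    by_domain: dict[str, list[GeneRecord]] = {}
    for t in targets:
        for d in t.domains:
            by_domain.setdefault(d, []).append(t)
    out: dict[str, list[OrthologAssignment]] = {}
    for q in queries:
        if not q.domains:
            continue
        seen: set[str] = set()
        hits: list[OrthologAssignment] = []
        for d in sorted(q.domains):
            for t in by_domain.get(d, []):
                if t.gene_id in seen:
                    continue
                seen.add(t.gene_id)
                res = align_proteins(t.protein, q.protein, mode="local")
                if _passes(res, min_bits, min_coverage, "query"):
                    hits.append(
                        OrthologAssignment(
                            brassica_gene=t.gene_id,
                            arabidopsis_query=q.gene_id,
                            method="domain_intersect",
                            identity_pct=res.identity_pct,
                            coverage=res.coverage_b,
                            score=res.score,
                        )
                    )
        out[q.gene_id] = sorted(hits, key=lambda h: (-h.score, h.brassica_gene))
    return out


def _best_hits(
    rows: Sequence[GeneRecord],
    cols: Sequence[GeneRecord],
    results: Mapping[tuple[str, str], AlignmentResult],
) -> dict[str, str]:
    """Best column gene per row gene, ties broken by (score, lexicographic id)."""
    best: dict[str, str] = {}
    for r in rows:
        candidates = [
            (-results[(r.gene_id, c.gene_id)].score, c.gene_id) for c in cols
        ]
        if candidates:
            # highest score; lexicographically smallest id among ties
            _, gene = min(candidates)
            best[r.gene_id] = gene
    return best


def reciprocal_best_hit(
    setA: Sequence[GeneRecord],
    setB: Sequence[GeneRecord],
    min_bits: float = DEFAULT_MIN_BITS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    coverage_on: str = "query",
) -> list[OrthologAssignment]:
    """Mutual-best-hit ortholog pairs between two proteomes.

    ``setA`` plays the query (A. thaliana) role: retained assignments have
    ``arabidopsis_query`` from setA and ``brassica_gene`` from setB.
    A pair is retained iff each member is the other's top-scoring hit and
    the alignment passes the bit-score and coverage thresholds.
    """
    if not setA or not setB:
        return []
    results: dict[tuple[str, str], AlignmentResult] = {}
    for qa in setA:
        for tb in setB:
            # align(target, query): b-side coverage is the query's
            results[(qa.gene_id, tb.gene_id)] = align_proteins(
                tb.protein, qa.protein, mode="local"
            )
    bestAB = _best_hits(setA, setB, results)
    resultsBA = {(b, a): res for (a, b), res in results.items()}
    bestBA = _best_hits(setB, setA, resultsBA)
    out = []
    for qa in sorted(setA, key=lambda g: g.gene_id):
        b_id = bestAB.get(qa.gene_id)
        if b_id is None or bestBA.get(b_id) != qa.gene_id:
            continue
        res = results[(qa.gene_id, b_id)]
        if _passes(res, min_bits, min_coverage, coverage_on):
            out.append(
                OrthologAssignment(
                    brassica_gene=b_id,
                    arabidopsis_query=qa.gene_id,
                    method="reciprocal_best",
                    identity_pct=res.identity_pct,
                    coverage=res.coverage_b,
                    score=res.score,
                )
            )
    return out


def assign_orthologs(
    targets: Sequence[GeneRecord],
    queries: Sequence[GeneRecord],
    min_bits: float = DEFAULT_MIN_BITS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> tuple[list[OrthologAssignment], list[str]]:
    """Combined two-track assignment.

    Domain-containing queries use the domain-intersection track (all passing
    targets kept); domainless queries use reciprocal best hit.  Returns
    (assignments, lost_queries) where lost queries are those with no
    surviving target in either track.
    """
    for name, recs in (("targets", targets), ("queries", queries)):
        ids = [r.gene_id for r in recs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate gene_ids in {name}")
    with_domains = [q for q in queries if q.domains]
    without_domains = [q for q in queries if not q.domains]

    assignments: list[OrthologAssignment] = []
    assigned_queries: set[str] = set()

    domain_hits = domain_track_candidates(targets, with_domains, min_bits, min_coverage)
    for q_id, hits in domain_hits.items():
        assignments.extend(hits)
        if hits:
            assigned_queries.add(q_id)

    rbh = reciprocal_best_hit(without_domains, targets, min_bits, min_coverage)
    assignments.extend(rbh)
    assigned_queries.update(a.arabidopsis_query for a in rbh)

    lost = sorted(q.gene_id for q in queries if q.gene_id not in assigned_queries)
    assignments.sort(key=lambda a: (a.arabidopsis_query, a.brassica_gene))
    return assignments, lost


def multi_assigned(assignments: Iterable[OrthologAssignment]) -> dict[str, list[str]]:
    """Brassica genes assigned to more than one query (flagged, not resolved)."""
    by_target: dict[str, list[str]] = {}
    for a in assignments:
        by_target.setdefault(a.brassica_gene, []).append(a.arabidopsis_query)
    return {t: sorted(qs) for t, qs in by_target.items() if len(set(qs)) > 1}
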