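"""Pairwise Ka/Ks estimation under the Li-Wu-Luo (1985) model.

The estimator partitions the three positions of every codon into
degeneracy classes — nondegenerate (0), twofold (2) and fourfold (4) —
counts transition/transversion differences per class (averaging over all
minimal mutational pathways for codons differing at 2-3 positions), applies
the Kimura two-parameter correction per class, and combines:

    Ks = 3 (L2 A2 + L4 K4) / (L2 + 3 L4)
    Ka = 3 (L0 K0 + L2 B2) / (3 L0 + 2 L2)

where, for class i with transition proportion P_i and transversion
proportion Q_i, A_i is the corrected transition distance, B_i the corrected
transversion distance, and K_i = A_i + B_i. Transitions at twofold sites
are (almost always) synonymous, hence A2 contributes to Ks and B2 to Ka.

Ka/Ks < 1, = 1 and > 1 are read as negative (purifying), neutral and
positive selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable

from .errors import EmptyAlignmentError, FrameError, SaturationError

_BASES = "ACGT"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

#: Standard genetic code (DNA codons), stop codons mapped to '*'.
GENETIC_CODE: dict[str, str] = {}
_code_spec = (
    "TTT F TTC F TTA L TTG L CTT L CTC L CTA L CTG L "
    "ATT I ATC I ATA I ATG M GTT V GTC V GTA V GTG V "
    "TCT S TCC S TCA S TCG S CCT P CCC P CCA P CCG P "
    "ACT T ACC T ACA T ACG T GCT A GCC A GCA A GCG A "
    "TAT Y TAC Y TAA * TAG * CAT H CAC H CAA Q CAG Q "
    "AAT N AAC N AAA K AAG K GAT D GAC D GAA E GAG E "
    "TGT C TGC C TGA * TGG W CGT R CGC R CGA R CGG R "
    "AGT S AGC S AGA R AGG R GGT G GGC G GGA G GGG G"
).split()
for _c, _aa in zip(_code_spec[0::2], _code_spec[1::2]):
    GENETIC_CODE[_c] = _aa

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T; anything else (between distinct bases) is a transversion."""
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS with the standard code.

    A trailing stop codon is stripped; an internal stop or a length not
    divisible by 3 raises :class:`FrameError`.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} is not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    protein = []
    for i, codon in enumerate(codons):
        aa = GENETIC_CODE.get(codon)
        if aa is None:
            raise FrameError(f"unknown codon {codon!r} at codon index {i}")
        if aa == "*":
            raise FrameError(f"internal stop codon {codon} at codon index {i}")
        protein.append(aa)
    return "".join(protein)


def site_degeneracy(codon: str, position: int) -> int:
    """Degeneracy class (0, 2 or 4) of one codon position.

    4 if every alternative base at the position is synonymous, 0 if none is,
    2 otherwise.  The threefold-degenerate Ile third position falls under
    "otherwise" and is classified twofold, the standard LWL85 convention.
    Substitutions to stop codons count as nonsynonymous.
    """
    codon = codon.upper()
    if codon in STOP_CODONS or codon not in GENETIC_CODE:
        raise ValueError(f"not a sense codon: {codon!r}")
    if position not in (1, 2, 3):
        raise ValueError(f"position must be 1, 2 or 3, got {position}")
    p = position - 1
    aa = GENETIC_CODE[codon]
    n_syn = 0
    for base in _BASES:
        if base == codon[p]:
            continue
        alt = codon[:p] + base + codon[p + 1 :]
        if GENETIC_CODE[alt] == aa:
            n_syn += 1
    if n_syn == 3:
        return 4
    if n_syn == 0:
        return 0
    return 2


@dataclass
class CodonAlignment:
    """A gapped pairwise CDS alignment whose gaps are whole codons."""

    gapped_cds_a: str
    gapped_cds_b: str

    def __post_init__(self) -> None:
        a, b = self.gapped_cds_a, self.gapped_cds_b
        if len(a) != len(b):
            raise ValueError("aligned sequences differ in length")
        if len(a) % 3 != 0:
            raise ValueError("alignment length is not a multiple of 3")
        for seq in (a, b):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if "-" in codon and codon != "---":
                    raise ValueError(f"partial-codon gap {codon!r} at {i}")

    def codon_columns(self) -> list[tuple[str, str]]:
        a, b = self.gapped_cds_a, self.gapped_cds_b
        return [(a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)]

    def ungapped_columns(self) -> list[tuple[str, str]]:
        return [
            (ca, cb) for ca, cb in self.codon_columns() if "-" not in ca + cb
        ]


def codon_align(cds_a: str, cds_b: str) -> CodonAlignment:
    """Protein-guided codon alignment.

    The two CDS are translated, the proteins aligned globally (affine-gap
    BLOSUM62), and the protein gaps back-translated into whole-codon gaps.
    """
    from .orthology import align_proteins  # local import: avoid cycle at load

    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    prot_a = translate_cds(cds_a)
    prot_b = translate_cds(cds_b)
    if not prot_a or not prot_b:
        raise FrameError("empty protein after translation")
    res = align_proteins(prot_a, prot_b, mode="global")
    ga, gb = res.aligned_a, res.aligned_b
    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(ga, gb):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    return CodonAlignment("".join(out_a), "".join(out_b))


@dataclass
class SiteCounts:
    """Per-class site totals and transition/transversion difference counts."""

    L0: float = 0.0
    L2: float = 0.0
    L4: float = 0.0
    S0: float = 0.0
    S2: float = 0.0
    S4: float = 0.0
    V0: float = 0.0
    V2: float = 0.0
    V4: float = 0.0

    def L(self, cls: int) -> float:
        return getattr(self, f"L{cls}")


def _single_step_attribution(
    codon_from: str, codon_to: str, position0: int
) -> list[tuple[int, float, bool]]:
    """Attribution of one substitution step: [(class, weight, is_transition)].

    If the two codons disagree on the degeneracy class of the changed
    position, half the difference is attributed to each class (the LWL85
    convention of averaging over the two sequences).
    """
    deg_from = site_degeneracy(codon_from, position0 + 1)
    deg_to = site_degeneracy(codon_to, position0 + 1)
    ts = is_transition(codon_from[position0], codon_to[position0])
    if deg_from == deg_to:
        return [(deg_from, 1.0, ts)]
    return [(deg_from, 0.5, ts), (deg_to, 0.5, ts)]


def _pathways(ca: str, cb: str, allow_stops: bool) -> list[list[tuple[str, str, int]]]:
    """All orderings of the differing positions as lists of (from, to, pos) steps.

    Pathways whose intermediate codons are stops are dropped unless
    ``allow_stops``.
    """
    diff_positions = [i for i in range(3) if ca[i] != cb[i]]
    paths = []
    for order in itertools.permutations(diff_positions):
        current = ca
        steps = []
        ok = True
        for pos in order:
            nxt = current[:pos] + cb[pos] + current[pos + 1 :]
            if not allow_stops and nxt in STOP_CODONS:
                ok = False
                break
            steps.append((current, nxt, pos))
            current = nxt
        if ok:
            paths.append(steps)
    return paths


def count_sites_and_differences(aln: CodonAlignment) -> SiteCounts:
    """LWL85 site and difference counting over the ungapped codon columns.

    Site totals L_i average the two sequences' per-class position counts.
    For codon pairs differing at 2-3 positions, every minimal mutational
    pathway avoiding stop-codon intermediates is enumerated and the steps
    averaged with equal weight (if all pathways cross a stop, the
    restriction is lifted for that pair).  Gapped columns are excluded.
    """
    columns = aln.ungapped_columns()
    if not columns:
        raise EmptyAlignmentError("no ungapped codon columns to compare")
    counts = SiteCounts()
    for ca, cb in columns:
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon in alignment column {ca}/{cb}")
        for pos in range(3):
            for codon in (ca, cb):
                cls = site_degeneracy(codon, pos + 1)
                setattr(counts, f"L{cls}", counts.L(cls) + 0.5)
        if ca == cb:
            continue
        paths = _pathways(ca, cb, allow_stops=False)
        if not paths:  # every route blocked by a stop codon intermediate
            paths = _pathways(ca, cb, allow_stops=True)
        w_path = 1.0 / len(paths)
        for steps in paths:
            for c_from, c_to, pos in steps:
                for cls, w, ts in _single_step_attribution(c_from, c_to, pos):
                    attr = "S" if ts else "V"
                    name = f"{attr}{cls}"
                    setattr(counts, name, getattr(counts, name) + w * w_path)
    return counts


def k2p_correct(P: float, Q: float) -> tuple[float, float]:
    """Kimura two-parameter correction of transition/transversion proportions.

    Returns (A, B): the corrected transition and transversion distances.
    Raises :class:`SaturationError` when the logs are undefined.
    """
    if P < 0 or Q < 0:
        raise ValueError("proportions must be nonnegative")
    one_m2pq = 1.0 - 2.0 * P - Q
    one_m2q = 1.0 - 2.0 * Q
    if one_m2pq <= 0 or one_m2q <= 0:
        raise SaturationError(
            f"saturated proportions P={P:.4f}, Q={Q:.4f}: correction undefined"
        )
    A = 0.5 * math.log(1.0 / one_m2pq) - 0.25 * math.log(1.0 / one_m2q)
    B = 0.5 * math.log(1.0 / one_m2q)
    return A, B


@dataclass
class KaKsResult:
    ka: float | None
    ks: float | None
    ratio: float | None
    A2: float | None = None
    A4: float | None = None
    B0: float | None = None
    B2: float | None = None
    B4: float | None = None
    selection_class: str = "undefined"


def classify_selection(ratio: float | None, tolerance: float = 0.0) -> str:
    """Selection class from a Ka/Ks ratio.

    Below 1 is negative (purifying), above 1 positive, exactly 1 neutral.
    ``tolerance`` widens the neutral band to [1-tol, 1+tol]; the default 0
    is the strict reading.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    if ratio is None:
        return "undefined"
    if ratio < 0:
        raise ValueError(f"negative Ka/Ks ratio: {ratio}")
    if ratio < 1.0 - tolerance:
        return "negative"
    if ratio > 1.0 + tolerance:
        return "positive"
    return "neutral"


def compute_kaks(counts: SiteCounts, neutral_tolerance: float = 0.0) -> KaKsResult:
    """Combine per-class K2P distances into Ka, Ks and the selection class."""
    L0, L2, L4 = counts.L0, counts.L2, counts.L4
    if L0 + L2 + L4 <= 0:
        raise EmptyAlignmentError("no sites counted")

    def props(cls: int) -> tuple[float, float]:
        L = counts.L(cls)
        if L == 0:
            return 0.0, 0.0
        return getattr(counts, f"S{cls}") / L, getattr(counts, f"V{cls}") / L

    try:
        A0, B0 = k2p_correct(*props(0))
        A2, B2 = k2p_correct(*props(2))
        A4, B4 = k2p_correct(*props(4))
    except SaturationError:
        return KaKsResult(ka=None, ks=None, ratio=None, selection_class="undefined")

    K0, K4 = A0 + B0, A4 + B4
    ks = 3.0 * (L2 * A2 + L4 * K4) / (L2 + 3.0 * L4) if (L2 + 3 * L4) > 0 else None
    ka = 3.0 * (L0 * K0 + L2 * B2) / (3.0 * L0 + 2.0 * L2) if (3 * L0 + 2 * L2) > 0 else None
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(
        ka=ka,
        ks=ks,
        ratio=ratio,
        A2=A2,
        A4=A4,
        B0=B0,
        B2=B2,
        B4=B4,
        selection_class=classify_selection(ratio, neutral_tolerance),
    )


def kaks_from_cds_pair(
    cds_a: str, cds_b: str, neutral_tolerance: float = 0.0
) -> KaKsResult:
    """Convenience: codon-align two CDS and run the LWL85 estimator."""
    aln = codon_align(cds_a, cds_b)
    return compute_kaks(count_sites_and_differences(aln), neutral_tolerance)


def kaks_table(
    pairs: Iterable[tuple[str, str, str, str]], neutral_tolerance: float = 0.0
):
    """Tabulate LWL85 results for (name_a, name_b, cds_a, cds_b) tuples.

    Returns a pandas DataFrame matching the TSV interface:
    gene_a, gene_b, L0, L2, L4, Ka, Ks, KaKs, class (NA for undefined).
    """
    import pandas as pd

    rows = []
    for name_a, name_b, cds_a, cds_b in pairs:
        aln = codon_align(cds_a, cds_b)
        counts = count_sites_and_differences(aln)
        res = compute_kaks(counts, neutral_tolerance)
        rows.append(
            {
                "gene_a": name_a,
                "gene_b": name_b,
                "L0": round(counts.L0, 4),
                "L2": round(counts.L2, 4),
                "L4": round(counts.L4, 4),
                "Ka": round(res.ka, 6) if res.ka is not None else None,
                "Ks": round(res.ks, 6) if res.ks is not None else None,
                "KaKs": round(res.ratio, 6) if res.ratio is not None else None,
                "class": res.selection_class,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "L0", "L2", "L4", "Ka", "Ks", "KaKs", "class"]
    )
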