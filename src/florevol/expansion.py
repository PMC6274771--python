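"""Gene-family expansion statistics for an allopolyploid and its progenitors.

Flowering-time genes belong to one or two of eight pathways (Ph, Ve, Ag,
Am, Ho, Su, Au, Fi: photoperiod/light signaling, vernalization, aging,
ambient temperature, hormone, sugar, autonomous, flowering-time
integrator).  Pathway totals count dual-pathway genes in both pathways
(the "parenthetical" totals); exclusive counts do not.

Two expansion statistics are computed:

* the A. thaliana-relative expansion ratio (Brassica count / A. thaliana
  count for the same pathway), and
* the gene-number ratio Gamma = (C1/C2) / (N1/N2), where C1 and C2 are a
  pathway's gene counts in a progenitor (B. rapa or B. oleracea) and in
  B. napus, and N1/N2 the genome-wide coding-gene totals.  Gamma < 1 means
  the pathway expanded in B. napus relative to genome-wide expectation;
  Gamma > 1 means it contracted.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .records import GeneRecord, is_unanchored

PATHWAY_CODES = frozenset({"Ph", "Ve", "Ag", "Am", "Ho", "Su", "Au", "Fi"})


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding as used for displayed ratios."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def validate_pathway_table(table: Mapping[str, Iterable[str]]) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    for gene, paths in table.items():
        ps = frozenset(paths)
        unknown = ps - PATHWAY_CODES
        if unknown:
            raise ValueError(f"{gene}: unknown pathway code(s) {sorted(unknown)}")
        if not 1 <= len(ps) <= 2:
            raise ValueError(f"{gene}: genes belong to 1 or 2 pathways, got {len(ps)}")
        out[gene] = ps
    return out


def pathway_totals(table: Mapping[str, Iterable[str]]) -> dict[str, tuple[int, int]]:
    """Per-pathway (exclusive_count, total_count).

    The exclusive count covers single-pathway genes only; the total adds
    every dual-pathway gene to both of its pathways, so summing exclusive
    counts plus each dual-pathway gene once recovers the number of genes.
    """
    table = validate_pathway_table(table)
    exclusive = {p: 0 for p in sorted(PATHWAY_CODES)}
    total = {p: 0 for p in sorted(PATHWAY_CODES)}
    for paths in table.values():
        for p in paths:
            total[p] += 1
        if len(paths) == 1:
            (p,) = paths
            exclusive[p] += 1
    return {p: (exclusive[p], total[p]) for p in sorted(PATHWAY_CODES)}


def expansion_ratio(count_brassica: int, count_ath: int, decimals: int = 2) -> float:
    """Brassica-to-A. thaliana gene-count ratio for one pathway."""
    if count_ath <= 0:
        raise ValueError("A. thaliana count must be positive")
    if count_brassica < 0:
        raise ValueError("counts must be nonnegative")
    return round_half_up(count_brassica / count_ath, decimals)


@dataclass(frozen=True)
class ExpansionInput:
    """Counts feeding Gamma: pathway counts C1/C2 and genome totals N1/N2."""

    C1: int  # pathway genes in the progenitor species
    C2: int  # pathway genes in B. napus
    N1: int  # coding genes in the progenitor genome
    N2: int  # coding genes in the B. napus genome

    def __post_init__(self) -> None:
        for name in ("C1", "C2", "N1", "N2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def gamma_ratio(inp: ExpansionInput, decimals: int | None = 2) -> float:
    """Gene-number ratio Gamma = (C1/C2)/(N1/N2).

    ``decimals=None`` returns the unrounded value.
    """
    value = (inp.C1 / inp.C2) / (inp.N1 / inp.N2)
    if decimals is None:
        return value
    return round_half_up(value, decimals)


def chromosome_distribution(
    records: Iterable[GeneRecord],
) -> tuple[dict[str, int], int]:
    """Counts of genes per chromosome, plus the unanchored-scaffold total."""
    counts: dict[str, int] = {}
    unanchored = 0
    for rec in records:
        if is_unanchored(rec.chromosome):
            unanchored += 1
        else:
            counts[rec.chromosome] = counts.get(rec.chromosome, 0) + 1
    return dict(sorted(counts.items())), unanchored


def expansion_report(
    table_progenitor: Mapping[str, Iterable[str]],
    table_napus: Mapping[str, Iterable[str]],
    N1: int,
    N2: int,
    decimals: int = 2,
):
    """Per-pathway Gamma table from two pathway-membership tables.

    Both the exclusive-count and the shared-inclusive (total) Gamma are
    reported, since published tables are not always explicit about which
    count feeds the ratio; the total-based column is the headline one.
    """
    import pandas as pd

    prog = pathway_totals(table_progenitor)
    nap = pathway_totals(table_napus)
    rows = []
    for p in sorted(PATHWAY_CODES):
        ex1, tot1 = prog[p]
        ex2, tot2 = nap[p]
        rows.append(
            {
                "pathway": p,
                "progenitor_exclusive": ex1,
                "progenitor_total": tot1,
                "napus_exclusive": ex2,
                "napus_total": tot2,
                "gamma_total": (
                    gamma_ratio(ExpansionInput(tot1, tot2, N1, N2), decimals)
                    if tot1 > 0 and tot2 > 0
                    else None
                ),
                "gamma_exclusive": (
                    gamma_ratio(ExpansionInput(ex1, ex2, N1, N2), decimals)
                    if ex1 > 0 and ex2 > 0
                    else None
                ),
            }
        )
    all_prog = len(table_progenitor)
    all_nap = len(table_napus)
    rows.append(
        {
            "pathway": "All",
            "progenitor_exclusive": all_prog,
            "progenitor_total": all_prog,
            "napus_exclusive": all_nap,
            "napus_total": all_nap,
            "gamma_total": gamma_ratio(ExpansionInput(all_prog, all_nap, N1, N2), decimals),
            "gamma_exclusive": gamma_ratio(ExpansionInput(all_prog, all_nap, N1, N2), decimals),
        }
    )
    return pd.DataFrame(rows)
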