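"""Core record types and plain-text I/O (FASTA via Biopython, TSV via pandas).

A :class:`GeneRecord` bundles everything the pipeline knows about one gene:
coordinates, coding sequence, protein sequence and functional-domain
annotations. Records are deliberately permissive — any field other than
``gene_id`` and ``species`` may be empty — because the different stages
consume different slices of the data (orthology needs proteins and domains,
Ka/Ks needs CDS, the chromosome census needs locations only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Chromosome labels treated as "not anchored to a chromosome".  Brassica
#: gene models on unplaced scaffolds carry pseudo-chromosomes such as
#: ``Ann``/``Cnn`` (A/C subgenome, unknown position) or ``Scaffold000xx``.
UNANCHORED_MARKERS = frozenset({"", "NA", "Ann", "Cnn", "Unn"})


def is_unanchored(chromosome: str | None) -> bool:
    if chromosome is None:
        return True
    if chromosome in UNANCHORED_MARKERS:
        return True
    return chromosome.lower().startswith("scaffold")


@dataclass
class GeneRecord:
    gene_id: str
    species: str
    chromosome: str | None = None
    start: int = 0
    end: int = 0
    cds: str = ""
    protein: str = ""
    domains: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.domains = frozenset(self.domains)
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start ({self.start}) > end ({self.end})"
            )
        if self.cds and self.protein and len(self.cds) != 3 * len(self.protein):
            raise ValueError(
                f"{self.gene_id}: CDS length {len(self.cds)} is not 3x protein "
                f"length {len(self.protein)}"
            )

    @property
    def anchored(self) -> bool:
        return not is_unanchored(self.chromosome)


@dataclass(frozen=True)
class OrthologAssignment:
    """One Brassica gene assigned to one A. thaliana query.

    ``method`` records which identification track produced the call:
    ``domain_intersect`` (shared functional domain + passing alignment) or
    ``reciprocal_best`` (mutual best hit between the proteomes).
    """

    brassica_gene: str
    arabidopsis_query: str
    method: str  # {"domain_intersect", "reciprocal_best"}
    identity_pct: float
    coverage: float
    score: float

    def __post_init__(self) -> None:
        if self.method not in ("domain_intersect", "reciprocal_best"):
            raise ValueError(f"unknown method {self.method!r}")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity_pct out of range: {self.identity_pct}")
        if self.coverage < 0.5:
            raise ValueError(
                f"assignment {self.brassica_gene}~{self.arabidopsis_query} has "
                f"coverage {self.coverage:.3f} < 0.5 and must not be retained"
            )


# ---------------------------------------------------------------------------
# FASTA / TSV helpers
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as an uncompressed FASTA file."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_domain_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV ``gene_id<TAB>domain_id`` (one row per domain)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "domain_id"],
                         dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return {}
    out: dict[str, set[str]] = {}
    for gene, dom in zip(df["gene_id"], df["domain_id"]):
        out.setdefault(gene, set()).add(dom)
    return {g: frozenset(ds) for g, ds in out.items()}


def write_domain_table(domains: dict[str, Iterable[str]], path: str | Path) -> None:
    rows = [(g, d) for g in sorted(domains) for d in sorted(domains[g])]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_location_table(path: str | Path) -> pd.DataFrame:
    """Read TSV ``gene_id<TAB>chromosome<TAB>start<TAB>end``."""
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["gene_id", "chromosome", "start", "end"],
        dtype={"gene_id": str, "chromosome": str, "start": int, "end": int},
        comment="#",
    )


def assignments_to_frame(assignments: Sequence[OrthologAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "brassica_gene": a.brassica_gene,
                "at_query": a.arabidopsis_query,
                "method": a.method,
                "identity": round(a.identity_pct, 4),
                "coverage": round(a.coverage, 4),
                "score": round(a.score, 4),
            }
            for a in assignments
        ],
        columns=["brassica_gene", "at_query", "method", "identity", "coverage", "score"],
    )


def frame_to_assignments(df: pd.DataFrame) -> list[OrthologAssignment]:
    return [
        OrthologAssignment(
            brassica_gene=row.brassica_gene,
            arabidopsis_query=row.at_query,
            method=row.method,
            identity_pct=float(row.identity),
            coverage=float(row.coverage),
            score=float(row.score),
        )
        for row in df.itertuples(index=False)
    ]
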