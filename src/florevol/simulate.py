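"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the data the comparative analysis consumes:

* :func:`simulate_codon_pair` — a coding-sequence pair diverged by a
  Markov substitution process with a controlled true dN/dS (omega),
  transition/transversion bias (kappa) and expected synonymous divergence,
  for Ka/Ks estimator recovery experiments.
* :func:`simulate_proteomes` — an ortholog-structured proteome pair
  (query = A. thaliana role, target = Brassica role) with configurable
  family loss and duplication, plus domain annotations, for the
  ortholog-identification tracks.
* :func:`simulate_expression` — an FPKM organ-expression matrix with a
  planted (rank-preserving, Gaussian-copula) correlation between a gene's
  true omega and its mean expression, for the selection-vs-expression
  correlation analysis.

:func:`simulate_study` combines them at codon level into one mutually
consistent dataset (CDS, proteins, domains, pathways, locations,
expression) that the pipeline runs end to end.

All randomness flows through a single integer seed per call; there is no
global random state.  Sequences are always in frame and free of internal
stop codons (substitutions creating stops are never proposed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ORGAN_CODES, ExpressionMatrix
from .kaks import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, is_transition, site_degeneracy
from .records import GeneRecord

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Fraction of gene families without any annotated functional domain,
#: matching the census of the study's 295 query genes (19 domainless).
DEFAULT_P_DOMAINLESS = 19.0 / 295.0
#: Dual-pathway membership rate (34 of 295 query genes sit in two pathways).
DEFAULT_P_DUAL_PATHWAY = 34.0 / 295.0

PATHWAY_CODES = ("Ph", "Ve", "Ag", "Am", "Ho", "Su", "Au", "Fi")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    omega_true: dict[str, float] = field(default_factory=dict)
    ks_true: dict[str, float] = field(default_factory=dict)
    correlation_target: float = 0.0
    seed: int = 0

    def to_tsv(self, path) -> None:
        rows = []
        for target_id, query_id in self.ortholog_pairs:
            rows.append(
                (
                    target_id,
                    query_id,
                    f"{self.omega_true.get(target_id, float('nan')):.6f}",
                    f"{self.ks_true.get(target_id, float('nan')):.6f}",
                )
            )
        pd.DataFrame(rows, columns=["gene_id", "ortholog_id", "omega_true", "ks_true"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Codon-pair evolution
# ---------------------------------------------------------------------------

def _substitution_table(omega: float, kappa: float):
    """For each sense codon: list of (position, new_codon, rate, is_synonymous).

    Changes to stop codons get rate 0 (they are never proposed), synonymous
    changes rate 1 or kappa (transition), nonsynonymous changes the same
    times omega.
    """
    table: dict[str, list[tuple[int, str, float, bool]]] = {}
    for codon in SENSE_CODONS:
        entries = []
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1 :]
                if alt in STOP_CODONS:
                    continue
                syn = GENETIC_CODE[alt] == GENETIC_CODE[codon]
                rate = kappa if is_transition(codon[pos], base) else 1.0
                if not syn:
                    rate *= omega
                if rate > 0:
                    entries.append((pos, alt, rate, syn))
        table[codon] = entries
    return table


def synonymous_sites(codons: Sequence[str]) -> float:
    """LWL85 synonymous site count (L2 + 3 L4) / 3 of a codon sequence."""
    L2 = L4 = 0
    for codon in codons:
        for pos in (1, 2, 3):
            deg = site_degeneracy(codon, pos)
            if deg == 2:
                L2 += 1
            elif deg == 4:
                L4 += 1
    return (L2 + 3.0 * L4) / 3.0


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random in-frame CDS of uniform sense codons (no stops)."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def evolve_cds(
    cds: str,
    omega: float,
    kappa: float,
    branch_ks: float,
    rng: np.random.Generator,
) -> str:
    """Evolve a CDS until its expected synonymous divergence reaches branch_ks.

    A Gillespie jump process proposes single-nucleotide changes with rates
    kappa (transitions) vs 1 (transversions), scaled by omega for
    nonsynonymous changes; stop-codon targets have rate zero.  The process
    stops when the time-integrated synonymous rate reaches
    branch_ks x (LWL85 synonymous sites of the ancestor), so the expected
    number of synonymous substitutions per synonymous site equals branch_ks.
    """
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    table = _substitution_table(omega, kappa)
    tot = np.array([sum(r for _, _, r, _ in table[c]) for c in codons])
    syn = np.array([sum(r for _, _, r, s in table[c] if s) for c in codons])
    target = branch_ks * synonymous_sites(codons)
    accrued = 0.0
    while True:
        R_tot = tot.sum()
        R_syn = syn.sum()
        if R_tot <= 0 or R_syn <= 0:
            break
        dt = rng.exponential(1.0 / R_tot)
        if accrued + R_syn * dt >= target:
            break
        accrued += R_syn * dt
        # pick the codon, then the change within it, proportional to rate
        cum = np.cumsum(tot)
        i = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        entries = table[codons[i]]
        rates = np.array([r for _, _, r, _ in entries])
        j = int(np.searchsorted(np.cumsum(rates), rng.random() * rates.sum(), side="right"))
        codons[i] = entries[j][1]
        tot[i] = sum(r for _, _, r, _ in table[codons[i]])
        syn[i] = sum(r for _, _, r, s in table[codons[i]] if s)
    return "".join(codons)


def simulate_codon_pair(
    n_codons: int,
    omega: float,
    kappa: float,
    branch_ks: float,
    seed: int,
) -> tuple[str, str]:
    """A random ancestral CDS and a descendant evolved at known omega/Ks."""
    if n_codons < 1:
        raise ValueError(f"n_codons must be >= 1, got {n_codons}")
    if omega < 0 or kappa <= 0 or branch_ks < 0:
        raise ValueError("omega and branch_ks must be >= 0 and kappa > 0")
    rng = np.random.default_rng(seed)
    cds_a = random_cds(n_codons, rng)
    cds_b = evolve_cds(cds_a, omega, kappa, branch_ks, rng)
    return cds_a, cds_b


# ---------------------------------------------------------------------------
# Proteome pair with known orthology
# ---------------------------------------------------------------------------

def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(_AA20[i] for i in rng.integers(0, 20, size=length))


def _mutate_protein(protein: str, divergence: float, rng: np.random.Generator) -> str:
    out = list(protein)
    hits = np.flatnonzero(rng.random(len(out)) < divergence)
    for i in hits:
        choices = _AA20.replace(out[i], "")
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def simulate_proteomes(
    n_families: int,
    n_lost: int,
    n_duplicated: int,
    divergence: float,
    seed: int,
    *,
    min_length: int = 120,
    max_length: int = 400,
    p_domainless: float = DEFAULT_P_DOMAINLESS,
) -> tuple[list[GeneRecord], list[GeneRecord], SimulationTruth]:
    """An ortholog-structured proteome pair with known truth.

    Each family has one query protein; retained families get one (or, for
    duplicated families, two to three) target copies mutated from it at the
    per-site rate ``divergence``; lost families have no target copy.
    A fraction of families carries no domain annotation and must be found
    by the reciprocal track.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must be in [0, 1], got {divergence}")
    if n_lost < 0 or n_duplicated < 0 or n_lost + n_duplicated > n_families:
        raise ValueError("need n_lost + n_duplicated <= n_families, both >= 0")
    rng = np.random.default_rng(seed)
    fam_ids = np.arange(n_families)
    special = rng.choice(fam_ids, size=n_lost + n_duplicated, replace=False)
    lost = set(special[:n_lost].tolist())
    duplicated = set(special[n_lost:].tolist())

    pool_size = max(1, round(n_families * 117 / 295))
    domain_pool = [f"DOM{i:05d}" for i in range(pool_size)]

    queries: list[GeneRecord] = []
    targets: list[GeneRecord] = []
    truth = SimulationTruth(seed=seed)
    for f in range(n_families):
        length = int(rng.integers(min_length, max_length + 1))
        protein = _random_protein(length, rng)
        if rng.random() < p_domainless:
            domains: frozenset[str] = frozenset()
        else:
            k = int(rng.integers(1, 3))
            idx = rng.choice(pool_size, size=min(k, pool_size), replace=False)
            domains = frozenset(domain_pool[i] for i in idx)
        q_id = f"ATQ{f:04d}"
        queries.append(
            GeneRecord(gene_id=q_id, species="Athaliana", protein=protein, domains=domains)
        )
        if f in lost:
            continue
        n_copies = int(rng.integers(2, 4)) if f in duplicated else 1
        for c in range(n_copies):
            t_id = f"BRT{f:04d}_{c + 1}"
            targets.append(
                GeneRecord(
                    gene_id=t_id,
                    species="Brassica",
                    protein=_mutate_protein(protein, divergence, rng),
                    domains=domains,
                )
            )
            truth.ortholog_pairs.append((t_id, q_id))
    return queries, targets, truth


# ---------------------------------------------------------------------------
# Expression matrix with a planted selection-expression correlation
# ---------------------------------------------------------------------------

def simulate_expression(
    omega_by_gene: Mapping[str, float],
    n_organs: int = 14,
    correlation_target: float = -0.5,
    seed: int = 0,
    *,
    organs: Sequence[str] | None = None,
    base_log_expression: float = 2.0,
    gene_sd: float = 1.2,
    organ_sd: float = 0.8,
) -> ExpressionMatrix:
    """FPKM organ matrix whose mean log-expression tracks -omega.

    A latent per-gene level m_i = rho u_i + sqrt(1 - rho^2) eps_i couples
    the standardized omega (u_i) to expression with correlation
    rho = correlation_target; organ values add independent noise on the
    log2 scale and are transformed back to nonnegative FPKM.  With all
    omegas equal the coupling is undefined and the matrix is pure noise.
    """
    if abs(correlation_target) > 1:
        raise ValueError(f"|correlation_target| must be <= 1, got {correlation_target}")
    if n_organs < 2:
        raise ValueError(f"n_organs must be >= 2, got {n_organs}")
    if organs is None:
        organs = list(ORGAN_CODES) if n_organs == 14 else [f"Org{i + 1}" for i in range(n_organs)]
    if len(organs) != n_organs:
        raise ValueError("len(organs) must equal n_organs")
    rng = np.random.default_rng(seed)
    genes = list(omega_by_gene)
    omega = np.array([omega_by_gene[g] for g in genes], dtype=float)
    sd = omega.std()
    u = (omega - omega.mean()) / sd if sd > 0 else np.zeros_like(omega)
    rho = correlation_target
    latent = rho * u + np.sqrt(1.0 - rho**2) * rng.standard_normal(len(genes))
    mu = np.clip(base_log_expression + gene_sd * latent, 0.0, None)
    log_values = np.clip(
        mu[:, None] + organ_sd * rng.standard_normal((len(genes), n_organs)), 0.0, None
    )
    fpkm = np.exp2(log_values) - 1.0
    df = pd.DataFrame(fpkm, index=pd.Index(genes, name="gene_id"), columns=list(organs))
    return ExpressionMatrix(df, scale="fpkm")


# ---------------------------------------------------------------------------
# Combined study-scale dataset (codon-level, mutually consistent)
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Everything the pipeline consumes, plus the generating truth."""

    queries: list[GeneRecord]
    targets: list[GeneRecord]
    truth: SimulationTruth
    pathways: dict[str, frozenset[str]]  # per query AND target gene
    expression: ExpressionMatrix


def simulate_study(
    n_families: int = 200,
    n_lost: int = 20,
    n_duplicated: int = 30,
    seed: int = 0,
    *,
    kappa: float = 2.0,
    omega_log_mean: float = np.log(0.2),
    omega_log_sd: float = 0.6,
    ks_log_mean: float = np.log(0.5),
    ks_log_sd: float = 0.35,
    min_codons: int = 80,
    max_codons: int = 300,
    correlation_target: float = -0.5,
    p_domainless: float = DEFAULT_P_DOMAINLESS,
    p_dual_pathway: float = DEFAULT_P_DUAL_PATHWAY,
    p_unanchored: float = 0.1,
) -> StudyData:
    """Simulate a full desk-scale study at codon level.

    Per family, an ancestral CDS is the query gene; each retained target
    copy evolves from it with its own true omega (lognormal around 0.2,
    the purifying regime typical of flowering-time orthologs) and true Ks
    (lognormal around 0.5).  Proteins are translations of the CDS, so the
    orthology and Ka/Ks stages see mutually consistent sequences.  Families
    inherit domains and 1-2 flowering pathways; genes get chromosome
    locations (a fraction unanchored); target-gene expression carries the
    planted omega correlation.
    """
    if n_lost + n_duplicated > n_families:
        raise ValueError("need n_lost + n_duplicated <= n_families")
    rng = np.random.default_rng(seed)
    fam_ids = np.arange(n_families)
    special = rng.choice(fam_ids, size=n_lost + n_duplicated, replace=False)
    lost = set(special[:n_lost].tolist())
    duplicated = set(special[n_lost:].tolist())

    pool_size = max(1, round(n_families * 117 / 295))
    domain_pool = [f"DOM{i:05d}" for i in range(pool_size)]
    at_chroms = [f"Chr{i}" for i in range(1, 6)]
    br_chroms = [f"A{i:02d}" for i in range(1, 11)] + [f"C{i:02d}" for i in range(1, 10)]

    queries: list[GeneRecord] = []
    targets: list[GeneRecord] = []
    pathways: dict[str, frozenset[str]] = {}
    truth = SimulationTruth(seed=seed, correlation_target=correlation_target)

    for f in range(n_families):
        n_codons = int(rng.integers(min_codons, max_codons + 1))
        ancestor = random_cds(n_codons, rng)
        if rng.random() < p_domainless:
            domains: frozenset[str] = frozenset()
        else:
            k = int(rng.integers(1, 3))
            idx = rng.choice(pool_size, size=min(k, pool_size), replace=False)
            domains = frozenset(domain_pool[i] for i in idx)
        n_path = 2 if rng.random() < p_dual_pathway else 1
        fam_paths = frozenset(
            PATHWAY_CODES[i] for i in rng.choice(len(PATHWAY_CODES), size=n_path, replace=False)
        )
        q_id = f"ATQ{f:04d}"
        q_start = int(rng.integers(1, 5_000_000))
        from .kaks import translate_cds

        queries.append(
            GeneRecord(
                gene_id=q_id,
                species="Athaliana",
                chromosome=at_chroms[int(rng.integers(0, len(at_chroms)))],
                start=q_start,
                end=q_start + 3 * n_codons - 1,
                cds=ancestor,
                protein=translate_cds(ancestor),
                domains=domains,
            )
        )
        pathways[q_id] = fam_paths
        if f in lost:
            continue
        n_copies = int(rng.integers(2, 4)) if f in duplicated else 1
        for c in range(n_copies):
            t_id = f"BRT{f:04d}_{c + 1}"
            omega_g = float(np.clip(rng.lognormal(omega_log_mean, omega_log_sd), 0.01, 1.5))
            ks_g = float(np.clip(rng.lognormal(ks_log_mean, ks_log_sd), 0.05, 1.5))
            cds = evolve_cds(ancestor, omega_g, kappa, ks_g, rng)
            if rng.random() < p_unanchored:
                chrom = "Ann" if rng.random() < 0.5 else "Cnn"
            else:
                chrom = br_chroms[int(rng.integers(0, len(br_chroms)))]
            t_start = int(rng.integers(1, 5_000_000))
            targets.append(
                GeneRecord(
                    gene_id=t_id,
                    species="Brassica",
                    chromosome=chrom,
                    start=t_start,
                    end=t_start + 3 * n_codons - 1,
                    cds=cds,
                    protein=translate_cds(cds),
                    domains=domains,
                )
            )
            pathways[t_id] = fam_paths
            truth.ortholog_pairs.append((t_id, q_id))
            truth.omega_true[t_id] = omega_g
            truth.ks_true[t_id] = ks_g

    expr_seed = int(rng.integers(0, 2**31 - 1))
    expression = simulate_expression(
        truth.omega_true,
        n_organs=14,
        correlation_target=correlation_target,
        seed=expr_seed,
    )
    return StudyData(
        queries=queries, targets=targets, truth=truth, pathways=pathways, expression=expression
    )
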