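"""End-to-end orchestration of the synthetic comparative analysis.

Stages (in dependency order):

``simulate``    write a codon-level synthetic study (proteomes, CDS, domain
                and pathway tables, locations, FPKM matrix, truth table).
``orthologs``   two-track ortholog assignment + lost-query list.
``kaks``        LWL85 Ka/Ks for every assigned pair.
``expansion``   per-pathway Gamma report and chromosome census.
``phylo``       NJ + bootstrap trees for the multi-copy families.
``expression``  normalization and per-gene breadth/average/category.
``correlate``   selection-vs-expression correlation report.

Every stage logs its parameters and seed, writes its outputs under one
directory, and records a manifest (file -> sha256) so that reruns with the
same configuration can be checked for byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expansion as expansion_mod
from . import expression as expression_mod
from . import kaks as kaks_mod
from . import orthology as orthology_mod
from . import phylogeny as phylogeny_mod
from . import records as records_mod
from . import simulate as simulate_mod
from .errors import DependencyError

logger = logging.getLogger("florevol")

STAGES = ("simulate", "orthologs", "kaks", "expansion", "phylo", "expression", "correlate")

_STAGE_DEPS: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "orthologs": ("simulate",),
    "kaks": ("orthologs",),
    "expansion": ("simulate",),
    "phylo": ("simulate",),
    "expression": ("simulate",),
    "correlate": ("kaks", "expression"),
}


@dataclass
class PipelineConfig:
    outdir: str = "florevol_run"
    seed: int = 0
    # synthetic-study conditions
    n_families: int = 200
    n_lost: int = 20
    n_duplicated: int = 30
    kappa: float = 2.0
    correlation_target: float = -0.5
    # thresholds
    min_bits: float = orthology_mod.DEFAULT_MIN_BITS
    min_coverage: float = orthology_mod.DEFAULT_MIN_COVERAGE
    expression_threshold: float = expression_mod.DEFAULT_EXPRESSION_THRESHOLD
    neutral_tolerance: float = 0.0
    high_cut: float = 2.0
    specificity_cut: float = 4.0
    # genome totals feeding Gamma (synthetic placeholders, configurable)
    N1: int = 20000
    N2: int = 40000
    bootstrap_reps: int = 1000
    threads: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        if self.threads != 1:
            raise ValueError("the pipeline is single-threaded; set threads: 1")
        if not 0 <= self.min_coverage <= 1:
            raise ValueError("min_coverage must be in [0, 1]")
        if self.neutral_tolerance < 0 or self.expression_threshold < 0:
            raise ValueError("thresholds must be nonnegative")
        if abs(self.correlation_target) > 1:
            raise ValueError("|correlation_target| must be <= 1")


@dataclass
class StageResult:
    stage: str
    files: dict[str, str] = field(default_factory=dict)  # name -> sha256


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(cfg: PipelineConfig, stage: str, files: list[Path]) -> StageResult:
    outdir = Path(cfg.outdir)
    manifest_dir = outdir / "manifests"
    manifest_dir.mkdir(parents=True, exist_ok=True)
    result = StageResult(stage=stage, files={f.name: _sha256(f) for f in sorted(files)})
    payload = {
        "stage": stage,
        "seed": cfg.seed,
        "params": asdict(cfg),
        "files": result.files,
    }
    with open(manifest_dir / f"{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return result


def _require(cfg: PipelineConfig, stage: str) -> None:
    for dep in _STAGE_DEPS[stage]:
        if not (Path(cfg.outdir) / "manifests" / f"{dep}.json").exists():
            raise DependencyError(stage, dep)


def _setup_logging(cfg: PipelineConfig) -> None:
    if logger.handlers:
        return
    logger.setLevel(logging.INFO)
    stream = logging.StreamHandler()
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    filelog = logging.FileHandler(Path(cfg.outdir) / "pipeline.log")
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    for h in (stream, filelog):
        h.setFormatter(fmt)
        logger.addHandler(h)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig) -> list[Path]:
    out = Path(cfg.outdir)
    study = simulate_mod.simulate_study(
        n_families=cfg.n_families,
        n_lost=cfg.n_lost,
        n_duplicated=cfg.n_duplicated,
        seed=cfg.seed,
        kappa=cfg.kappa,
        correlation_target=cfg.correlation_target,
    )
    files = []

    def _w(name: str, writer) -> None:
        path = out / name
        writer(path)
        files.append(path)

    _w("query_proteins.faa", lambda p: records_mod.write_fasta(
        [(g.gene_id, g.protein) for g in study.queries], p))
    _w("target_proteins.faa", lambda p: records_mod.write_fasta(
        [(g.gene_id, g.protein) for g in study.targets], p))
    _w("query_cds.fna", lambda p: records_mod.write_fasta(
        [(g.gene_id, g.cds) for g in study.queries], p))
    _w("target_cds.fna", lambda p: records_mod.write_fasta(
        [(g.gene_id, g.cds) for g in study.targets], p))
    _w("query_domains.tsv", lambda p: records_mod.write_domain_table(
        {g.gene_id: g.domains for g in study.queries if g.domains}, p))
    _w("target_domains.tsv", lambda p: records_mod.write_domain_table(
        {g.gene_id: g.domains for g in study.targets if g.domains}, p))

    def _write_pathways(genes, path):
        rows = [(g.gene_id, ",".join(sorted(study.pathways[g.gene_id]))) for g in genes]
        pd.DataFrame(rows, columns=["gene_id", "pathways"]).to_csv(path, sep="\t", index=False)

    _w("pathways_query.tsv", lambda p: _write_pathways(study.queries, p))
    _w("pathways_target.tsv", lambda p: _write_pathways(study.targets, p))

    def _write_locations(genes, path):
        rows = [(g.gene_id, g.chromosome, g.start, g.end) for g in genes]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)

    _w("locations_query.tsv", lambda p: _write_locations(study.queries, p))
    _w("locations_target.tsv", lambda p: _write_locations(study.targets, p))
    _w("expression_fpkm.tsv", lambda p: study.expression.to_tsv(p))
    _w("truth.tsv", lambda p: study.truth.to_tsv(p))

    # aligned FASTA per multi-copy family (query + target copies; the
    # simulator introduces no indels, so family members are pre-aligned)
    by_query: dict[str, list[str]] = {}
    for t_id, q_id in study.truth.ortholog_pairs:
        by_query.setdefault(q_id, []).append(t_id)
    prot = {g.gene_id: g.protein for g in study.queries + study.targets}
    fam_records = []
    for q_id in sorted(by_query):
        if len(by_query[q_id]) >= 2:  # query + >=2 copies -> >= 3 taxa
            members = [q_id] + sorted(by_query[q_id])
            fam_records.append((q_id, members))
    lines = []
    for q_id, members in fam_records:
        for m in members:
            lines.append((f"{q_id}|{m}", prot[m]))
    _w("families_aligned.faa", lambda p: records_mod.write_fasta(lines, p))
    logger.info(
        "simulate: %d queries, %d targets, %d multi-copy families",
        len(study.queries), len(study.targets), len(fam_records),
    )
    return files


def _load_gene_records(cfg: PipelineConfig, side: str) -> list[records_mod.GeneRecord]:
    out = Path(cfg.outdir)
    proteins = records_mod.read_fasta(out / f"{side}_proteins.faa")
    cds = records_mod.read_fasta(out / f"{side}_cds.fna")
    domains = records_mod.read_domain_table(out / f"{side}_domains.tsv")
    locs = records_mod.read_location_table(out / f"locations_{side}.tsv")
    loc_by_gene = {r.gene_id: r for r in locs.itertuples(index=False)}
    recs = []
    for gene_id, protein in proteins.items():
        loc = loc_by_gene.get(gene_id)
        recs.append(
            records_mod.GeneRecord(
                gene_id=gene_id,
                species="Athaliana" if side == "query" else "Brassica",
                chromosome=loc.chromosome if loc else None,
                start=int(loc.start) if loc else 0,
                end=int(loc.end) if loc else 0,
                cds=cds.get(gene_id, ""),
                protein=protein,
                domains=domains.get(gene_id, frozenset()),
            )
        )
    return recs


def _stage_orthologs(cfg: PipelineConfig) -> list[Path]:
    _require(cfg, "orthologs")
    out = Path(cfg.outdir)
    queries = _load_gene_records(cfg, "query")
    targets = _load_gene_records(cfg, "target")
    assignments, lost = orthology_mod.assign_orthologs(
        targets, queries, min_bits=cfg.min_bits, min_coverage=cfg.min_coverage
    )
    df = records_mod.assignments_to_frame(assignments)
    df.to_csv(out / "orthologs.tsv", sep="\t", index=False)
    pd.DataFrame({"lost_query": lost}).to_csv(out / "lost_queries.tsv", sep="\t", index=False)
    multi = orthology_mod.multi_assigned(assignments)
    logger.info(
        "orthologs: %d assignments, %d lost queries, %d multi-assigned targets",
        len(assignments), len(lost), len(multi),
    )
    return [out / "orthologs.tsv", out / "lost_queries.tsv"]


def _stage_kaks(cfg: PipelineConfig) -> list[Path]:
    _require(cfg, "kaks")
    out = Path(cfg.outdir)
    ortho = pd.read_csv(out / "orthologs.tsv", sep="\t")
    # one pair per Brassica gene: keep the top-scoring query
    ortho = ortho.sort_values(["brassica_gene", "score"], ascending=[True, False])
    ortho = ortho.drop_duplicates("brassica_gene", keep="first")
    cds_t = records_mod.read_fasta(out / "target_cds.fna")
    cds_q = records_mod.read_fasta(out / "query_cds.fna")
    pairs = [
        (row.brassica_gene, row.at_query, cds_t[row.brassica_gene], cds_q[row.at_query])
        for row in ortho.itertuples(index=False)
        if row.brassica_gene in cds_t and row.at_query in cds_q
    ]
    table = kaks_mod.kaks_table(pairs, neutral_tolerance=cfg.neutral_tolerance)
    table.to_csv(out / "kaks.tsv", sep="\t", index=False, na_rep="NA")
    logger.info("kaks: %d pairs estimated", len(table))
    return [out / "kaks.tsv"]


def _read_pathway_tsv(path: Path) -> dict[str, frozenset[str]]:
    df = pd.read_csv(path, sep="\t")
    return {
        row.gene_id: frozenset(str(row.pathways).split(","))
        for row in df.itertuples(index=False)
    }


def _stage_expansion(cfg: PipelineConfig) -> list[Path]:
    _require(cfg, "expansion")
    out = Path(cfg.outdir)
    table_q = _read_pathway_tsv(out / "pathways_query.tsv")
    table_t = _read_pathway_tsv(out / "pathways_target.tsv")
    report = expansion_mod.expansion_report(table_q, table_t, N1=cfg.N1, N2=cfg.N2)
    report.to_csv(out / "expansion_report.tsv", sep="\t", index=False, na_rep="NA")
    targets = _load_gene_records(cfg, "target")
    counts, unanchored = expansion_mod.chromosome_distribution(targets)
    rows = [{"chromosome": c, "n_genes": n} for c, n in counts.items()]
    rows.append({"chromosome": "unanchored", "n_genes": unanchored})
    pd.DataFrame(rows).to_csv(out / "chromosome_distribution.tsv", sep="\t", index=False)
    logger.info("expansion: %d pathways reported, %d unanchored genes", len(report), unanchored)
    return [out / "expansion_report.tsv", out / "chromosome_distribution.tsv"]


def _stage_phylo(cfg: PipelineConfig) -> list[Path]:
    _require(cfg, "phylo")
    out = Path(cfg.outdir)
    fam_seqs = records_mod.read_fasta(out / "families_aligned.faa")
    families: dict[str, dict[str, str]] = {}
    for name, seq in fam_seqs.items():
        fam, member = name.split("|", 1)
        families.setdefault(fam, {})[member] = seq
    rng = np.random.default_rng(cfg.seed)
    newicks = []
    support_frames = []
    for fam in sorted(families):
        aln = families[fam]
        if len(aln) < 3:
            continue
        tree = phylogeny_mod.bootstrap_support(
            aln, n_reps=cfg.bootstrap_reps, seed=int(rng.integers(0, 2**31 - 1))
        )
        newicks.append(phylogeny_mod.write_newick(tree))
        st = phylogeny_mod.support_table(tree)
        if not st.empty:  # 3-taxon trees have no nontrivial bipartitions
            st.insert(0, "family", fam)
            support_frames.append(st)
    (out / "trees.nwk").write_text("\n".join(newicks) + "\n")
    if support_frames:
        pd.concat(support_frames).to_csv(out / "support.tsv", sep="\t", index=False)
    else:
        pd.DataFrame(columns=["family", "bipartition", "support_pct"]).to_csv(
            out / "support.tsv", sep="\t", index=False
        )
    logger.info("phylo: %d family trees", len(newicks))
    return [out / "trees.nwk", out / "support.tsv"]


def _stage_expression(cfg: PipelineConfig) -> list[Path]:
    _require(cfg, "expression")
    out = Path(cfg.outdir)
    m = expression_mod.ExpressionMatrix.from_tsv(out / "expression_fpkm.tsv", scale="fpkm")
    m = expression_mod.average_replicates(m)
    m = expression_mod.normalize_log2p1(m)
    stats = expression_mod.gene_statistics(
        m,
        threshold=cfg.expression_threshold,
        high_cut=cfg.high_cut,
        specificity_cut=cfg.specificity_cut,
    )
    stats.to_csv(out / "expression_stats.tsv", sep="\t", na_rep="NA", float_format="%.4f")
    logger.info("expression: %d genes, %d silent",
                len(stats), int((stats["category"] == "silent").sum()))
    return [out / "expression_stats.tsv"]


def _stage_correlate(cfg: PipelineConfig) -> list[Path]:
    _require(cfg, "correlate")
    out = Path(cfg.outdir)
    kaks_df = pd.read_csv(out / "kaks.tsv", sep="\t", na_values="NA").set_index("gene_a")
    stats_df = pd.read_csv(out / "expression_stats.tsv", sep="\t", na_values="NA").set_index("gene_id")
    report = expression_mod.selection_expression_report(kaks_df, stats_df)
    report.to_csv(out / "correlation_report.tsv", sep="\t", index=False, na_rep="NA")
    logger.info("correlate: %d correlations", len(report))
    return [out / "correlation_report.tsv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "orthologs": _stage_orthologs,
    "kaks": _stage_kaks,
    "expansion": _stage_expansion,
    "phylo": _stage_phylo,
    "expression": _stage_expression,
    "correlate": _stage_correlate,
}


def run_stage(name: str, cfg: PipelineConfig) -> StageResult:
    """Run one stage; raises DependencyError if prerequisites are missing."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
    cfg.validate()
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg)
    logger.info("running stage %s (seed=%d)", name, cfg.seed)
    files = _STAGE_FUNCS[name](cfg)
    return _write_manifest(cfg, name, files)


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in order and assemble a summary report.

    The summary covers gene counts, lost queries, the per-pathway Gamma
    table, the Ka/Ks distribution (mean, range, fraction above the mean,
    positively selected genes) and the selection-expression correlations.
    """
    for stage in STAGES:
        run_stage(stage, cfg)
    out = Path(cfg.outdir)
    ortho = pd.read_csv(out / "orthologs.tsv", sep="\t")
    lost = pd.read_csv(out / "lost_queries.tsv", sep="\t")
    kaks_df = pd.read_csv(out / "kaks.tsv", sep="\t", na_values="NA")
    gamma = pd.read_csv(out / "expansion_report.tsv", sep="\t", na_values="NA")
    corr = pd.read_csv(out / "correlation_report.tsv", sep="\t", na_values="NA")
    ratios = kaks_df["KaKs"].dropna()
    summary = {
        "n_queries_assigned": int(ortho["at_query"].nunique()),
        "n_target_genes": int(ortho["brassica_gene"].nunique()),
        "n_lost_queries": int(len(lost)),
        "kaks_mean": round(float(ratios.mean()), 4) if len(ratios) else None,
        "kaks_min": round(float(ratios.min()), 4) if len(ratios) else None,
        "kaks_max": round(float(ratios.max()), 4) if len(ratios) else None,
        "kaks_pct_above_mean": (
            round(100.0 * float((ratios > ratios.mean()).mean()), 2) if len(ratios) else None
        ),
        "positively_selected": sorted(
            kaks_df.loc[kaks_df["class"] == "positive", "gene_a"].tolist()
        ),
        "gamma": {
            row.pathway: row.gamma_total
            for row in gamma.itertuples(index=False)
            if pd.notna(row.gamma_total)
        },
        "correlations": {
            f"{row.selection_stat}~{row.expression_stat}": {
                "r": row.r, "r2": row.r2, "p": row.p_value, "n": int(row.n)
            }
            for row in corr.itertuples(index=False)
            if pd.notna(row.r)
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("run_all complete: %s", out / "summary.json")
    return summary
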