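"""Organ expression statistics and their correlation with selection pressure.

The workflow mirrors the RNA-seq side of the study: FPKM values over 14
B. napus organs are normalized as log2(FPKM + 1); a gene's *expression
breadth* is the number of organs with normalized expression strictly above
0.5, and its *average expression* is the mean over those organs only.
Per-gene selection statistics (Ka, Ks, Ka/Ks) are then correlated with
breadth and average expression (Pearson by default, Spearman optionally).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, StateError

#: The 14 organ codes: root, stem, leaf, bud, anthocaulus, calyx, petal,
#: pistil, stamen, anther, capillament, inflorescence top, seed, silique
#: pericarp.  Seeds and silique pericarps are sampled at 10/21/30 days
#: after flowering, which appear as timepoint columns (e.g. ``Se.10``).
ORGAN_CODES = (
    "Ro", "St", "Le", "Bu", "Ao", "Cal", "Pe", "Pi", "Sta", "At", "Cap",
    "It", "Se", "SP",
)

DEFAULT_EXPRESSION_THRESHOLD = 0.5

_REP_RE = re.compile(r"^[Rr](?:ep)?\d+$")


@dataclass
class ExpressionMatrix:
    """Genes x organs expression values with an explicit scale flag."""

    values: pd.DataFrame  # index: gene_id; columns: organ[.timepoint]
    scale: str = "fpkm"  # {"fpkm", "log2p1"}

    def __post_init__(self) -> None:
        if self.scale not in ("fpkm", "log2p1"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def organs(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.4f")

    @classmethod
    def from_tsv(cls, path, scale: str = "fpkm") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(df, scale=scale)


def average_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Average biological-replicate columns.

    A column named ``organ[.timepoint].R<n>`` (``R1``, ``rep2``, ...) is a
    replicate of ``organ[.timepoint]``; purely numeric suffixes such as
    ``Se.10`` are timepoints, not replicates, and are kept as distinct
    organ columns.
    """
    groups: dict[str, list[str]] = {}
    for col in m.values.columns:
        parts = col.split(".")
        base = ".".join(parts[:-1]) if len(parts) > 1 and _REP_RE.match(parts[-1]) else col
        groups.setdefault(base, []).append(col)
    data = {base: m.values[cols].mean(axis=1) for base, cols in groups.items()}
    return ExpressionMatrix(pd.DataFrame(data, index=m.values.index), scale=m.scale)


def normalize_log2p1(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(FPKM + 1) normalization; refuses to run twice."""
    if m.scale != "fpkm":
        raise StateError("matrix is already log2(FPKM+1)-normalized")
    return ExpressionMatrix(np.log2(m.values + 1.0), scale="log2p1")


def expression_breadth(
    values: np.ndarray | pd.Series, threshold: float = DEFAULT_EXPRESSION_THRESHOLD
) -> int:
    """Number of organs with normalized expression strictly above threshold."""
    arr = np.asarray(values, dtype=float)
    return int((arr > threshold).sum())


def average_expression(
    values: np.ndarray | pd.Series, threshold: float = DEFAULT_EXPRESSION_THRESHOLD
) -> float:
    """Mean over the organs exceeding the threshold; NaN if none does."""
    arr = np.asarray(values, dtype=float)
    expressed = arr[arr > threshold]
    if expressed.size == 0:
        return float("nan")
    return float(expressed.mean())


def classify_pattern(
    values: np.ndarray | pd.Series,
    high_cut: float = 2.0,
    specificity_cut: float = 4.0,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> str:
    """Coarse expression-pattern category on the log2 scale.

    ``silent`` (no organ above threshold), ``organ_specific`` (expressed in
    at most 2 organs, or max/mean over expressed organs >= specificity_cut),
    ``high`` (average expression >= high_cut) or ``weak``.  The cuts are a
    parameterized reconstruction of the high/weak/organ-specific
    trichotomy; no canonical thresholds exist, so they are configurable and
    should be read as qualitative.
    """
    arr = np.asarray(values, dtype=float)
    breadth = expression_breadth(arr, threshold)
    if breadth == 0:
        return "silent"
    expressed = arr[arr > threshold]
    if breadth <= 2 or expressed.max() / expressed.mean() >= specificity_cut:
        return "organ_specific"
    if average_expression(arr, threshold) >= high_cut:
        return "high"
    return "weak"


def gene_statistics(
    m: ExpressionMatrix,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
    high_cut: float = 2.0,
    specificity_cut: float = 4.0,
) -> pd.DataFrame:
    """Per-gene breadth, average expression and pattern category."""
    if m.scale != "log2p1":
        raise StateError("gene statistics require a log2(FPKM+1) matrix")
    rows = []
    for gene_id, row in m.values.iterrows():
        rows.append(
            {
                "gene_id": gene_id,
                "breadth": expression_breadth(row, threshold),
                "average_expression": average_expression(row, threshold),
                "category": classify_pattern(row, high_cut, specificity_cut, threshold),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    method: str = "pearson"
    r2: float = field(init=False)

    def __post_init__(self) -> None:
        self.r2 = self.r**2


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Correlation between two per-gene statistics.

    NaN entries are dropped pairwise; the p-value is the two-sided test
    from the t distribution with n - 2 degrees of freedom (Pearson) or the
    corresponding Spearman test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return CorrelationResult(r=float(r), p_value=float(p), n=n, method=method)


def selection_expression_report(
    kaks_df: pd.DataFrame,
    stats_df: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate Ka/Ks, Ka and Ks with average expression and breadth.

    ``kaks_df`` is the Ka/Ks table indexed (or indexable) by Brassica gene;
    ``stats_df`` is the per-gene expression statistics table.  Genes with
    undefined statistics drop out pairwise.
    """
    merged = kaks_df.join(stats_df, how="inner")
    rows = []
    for stat in ("KaKs", "Ka", "Ks"):
        for expr in ("average_expression", "breadth"):
            try:
                res = correlate(merged[stat], merged[expr], method=method)
                rows.append(
                    {
                        "selection_stat": stat,
                        "expression_stat": expr,
                        "r": round(res.r, 4),
                        "r2": round(res.r2, 4),
                        "p_value": res.p_value,
                        "n": res.n,
                    }
                )
            except DegenerateInputError:
                rows.append(
                    {
                        "selection_stat": stat,
                        "expression_stat": expr,
                        "r": None, "r2": None, "p_value": None,
                        "n": int(merged[[stat, expr]].dropna().shape[0]),
                    }
                )
    return pd.DataFrame(rows)
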