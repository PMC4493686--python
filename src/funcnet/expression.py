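"""Expression matrices: parsing, log transform, z-scoring, kNN imputation,
co-expression network construction, and a minimal QC summary.

The processing chain mirrors the standard normalization recipe for
repository-derived expression tables: per-gene z-score transformation (mean
zero, standard deviation one across samples), then imputation of missing
values by a weighted average over each gene's 10 nearest neighbor genes,
weighted by inverse relative (per-shared-column RMS) Euclidean distance.
Co-expression edges are Pearson correlations, Fisher z-transformed, and
standardized within the dataset so edge weights are comparable z-scores
across data sources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import WeightedNetwork

__all__ = [
    "ExpressionMatrix",
    "GeneStats",
    "ImputationConfig",
    "ImputedCell",
    "ImputationReport",
    "CoexpressionConfig",
    "parse_expression_table",
    "write_expression_table",
    "transform_log2",
    "zscore_rows",
    "impute_knn",
    "build_coexpression_network",
    "qc_summary",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix; NaN marks missing values.

    ``data`` is a pandas DataFrame indexed by unique gene ids with unique
    sample-id columns. ``sample_conditions`` optionally labels samples
    (e.g., case/control) for downstream differential expression.
    """

    data: pd.DataFrame
    sample_conditions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class GeneStats:
    """Per-gene observed-value statistics from z-scoring.

    ``table`` has columns mean, sd (n-1 denominator), n_observed; ``flagged``
    lists zero-variance genes set to all-zero; ``dropped`` lists genes removed
    for having fewer than the minimum observed values.
    """

    table: pd.DataFrame
    flagged: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ImputationConfig:
    k_impute: int = 10
    epsilon: float = 1e-6
    min_shared: int = 3

    def __post_init__(self) -> None:
        if self.k_impute < 1:
            raise ValueError("k_impute must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class ImputedCell:
    gene: str
    sample: str
    neighbors: tuple[str, ...]
    distances: tuple[float, ...]
    weights: tuple[float, ...]
    fallback_used: bool


@dataclass
class ImputationReport:
    cells: list[ImputedCell] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class CoexpressionConfig:
    similarity: str = "pearson"
    transform: str = "fisher_z"
    standardize: str = "within_dataset"
    report_threshold: float = 2.0


def parse_expression_table(path) -> ExpressionMatrix:
    """Read a TSV with sample-id header and gene ids in the first column.

    Empty cells and "NA" are missing. Ragged rows, duplicate gene ids, and
    non-numeric cells are rejected with their location.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[1:]
        ncol = len(header)
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise ValueError(
                    f"{path}: line {lineno}: expected {ncol} columns, got {len(parts)}"
                )
            genes.append(parts[0])
            row: list[float] = []
            for j, cell in enumerate(parts[1:], start=1):
                if cell == "" or cell.upper() == "NA":
                    row.append(math.nan)
                else:
                    try:
                        row.append(float(cell))
                    except ValueError:
                        raise ValueError(
                            f"{path}: line {lineno}, column {j + 1}: non-numeric cell {cell!r}"
                        ) from None
            rows.append(row)
    df = pd.DataFrame(rows, index=genes, columns=samples, dtype=float)
    return ExpressionMatrix(df)


def write_expression_table(m: ExpressionMatrix, path) -> None:
    """Write TSV deterministically: sorted gene rows, %.10g cells, NA missing."""
    df = m.data.sort_index()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(str(c) for c in df.columns) + "\n")
        for gene, row in zip(df.index, df.to_numpy()):
            cells = ["NA" if math.isnan(v) else f"{v:.10g}" for v in row]
            fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")


def transform_log2(m: ExpressionMatrix, shift: float = 1.0) -> ExpressionMatrix:
    """Elementwise x -> log2(x + shift); missing values preserved."""
    x = m.values()
    bad = (x + shift <= 0) & ~np.isnan(x)
    if bad.any():
        gi, sj = np.nonzero(bad)
        cells = [(m.gene_ids[i], m.sample_ids[j]) for i, j in zip(gi[:5], sj[:5])]
        raise ValueError(f"nonpositive values after shift {shift}: {cells}")
    out = np.where(np.isnan(x), np.nan, np.log2(np.where(np.isnan(x), 1.0, x + shift)))
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        sample_conditions=m.sample_conditions,
    )


def zscore_rows(m: ExpressionMatrix, min_observed: int = 3) -> tuple[ExpressionMatrix, GeneStats]:
    """Per-gene z-scores over observed entries: z = (x - mean) / sd.

    Genes with fewer than ``min_observed`` observed values are dropped;
    zero-variance genes are set to all-zero and flagged. Missing cells stay
    missing (imputation is a separate step).
    """
    if m.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    x = m.values()
    n_obs = np.sum(~np.isnan(x), axis=1)
    keep = n_obs >= min_observed
    dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
    x = x[keep]
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(x, axis=1)
        sd = np.nanstd(x, axis=1, ddof=1)
    flagged = [g for g, s in zip(genes, sd) if s == 0]
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu[:, None]) / safe_sd[:, None]
    z[sd == 0, :] = np.where(np.isnan(x[sd == 0, :]), np.nan, 0.0)
    stats = pd.DataFrame(
        {"mean": mu, "sd": sd, "n_observed": n_obs[keep]}, index=genes
    )
    out = ExpressionMatrix(
        pd.DataFrame(z, index=genes, columns=m.data.columns),
        sample_conditions=m.sample_conditions,
    )
    return out, GeneStats(table=stats, flagged=flagged, dropped=dropped)


def impute_knn(
    m_z: ExpressionMatrix, cfg: ImputationConfig = ImputationConfig()
) -> tuple[ExpressionMatrix, ImputationReport]:
    """Fill each missing cell from the k nearest neighbor genes.

    For a missing cell (g, j) the candidates are genes observed at column j
    that share at least ``min_shared`` observed columns with g. The distance
    to a candidate h is the RMS difference over the shared observed columns
    (the "relative" Euclidean distance: sum of squared differences divided by
    the number of shared columns, then square-rooted), so genes with
    different missingness patterns are comparable. The ``k_impute`` nearest
    candidates contribute with weights proportional to 1/(d + epsilon),
    normalized to sum to one. With no candidates the gene's observed mean is
    used and the cell is flagged as a fallback.
    """
    x = m_z.values().copy()
    obs = ~np.isnan(x)
    if (~obs).sum() == 0:
        return m_z, ImputationReport()
    if (obs.sum(axis=1) == 0).any():
        empty = [g for g, o in zip(m_z.gene_ids, obs.sum(axis=1)) if o == 0]
        raise ValueError(f"genes with no observed values: {empty[:5]}")
    genes = m_z.gene_ids
    samples = m_z.sample_ids
    x0 = np.where(obs, x, 0.0)
    obs_f = obs.astype(float)
    # pairwise shared-column counts and squared distances over shared columns
    shared = obs_f @ obs_f.T
    # sum over shared c of (x_g - x_h)^2 = sum x_g^2*obs_h + sum x_h^2*obs_g - 2 sum x_g x_h
    sq = x0**2
    cross = x0 @ x0.T
    ssd = (sq @ obs_f.T) + (obs_f @ sq.T) - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.maximum(ssd, 0.0) / shared)
    np.fill_diagonal(dist, np.inf)
    dist[shared < 1] = np.inf
    row_means = np.nansum(x0, axis=1) / obs.sum(axis=1)

    report = ImputationReport()
    out = x.copy()
    miss_g, miss_j = np.nonzero(~obs)
    for g, j in zip(miss_g, miss_j):
        cand = np.nonzero(obs[:, j] & (shared[g] >= cfg.min_shared) & np.isfinite(dist[g]))[0]
        if cand.size == 0:
            out[g, j] = row_means[g]
            report.cells.append(
                ImputedCell(genes[g], samples[j], (), (), (), fallback_used=True)
            )
            continue
        d = dist[g, cand]
        order = np.argsort(d, kind="stable")[: cfg.k_impute]
        nbr = cand[order]
        dn = d[order]
        w = 1.0 / (dn + cfg.epsilon)
        w = w / w.sum()
        out[g, j] = float(w @ x[nbr, j])
        report.cells.append(
            ImputedCell(
                genes[g],
                samples[j],
                tuple(genes[i] for i in nbr),
                tuple(float(v) for v in dn),
                tuple(float(v) for v in w),
                fallback_used=False,
            )
        )
    return (
        ExpressionMatrix(
            pd.DataFrame(out, index=m_z.data.index, columns=m_z.data.columns),
            sample_conditions=m_z.sample_conditions,
        ),
        report,
    )


def build_coexpression_network(
    m: ExpressionMatrix,
    cfg: CoexpressionConfig = CoexpressionConfig(),
    dataset_id: str = "",
) -> WeightedNetwork:
    """Complete co-expression network with standardized Fisher-z weights.

    Pearson r for every unordered gene pair over all samples, clamped to
    |r| <= 1 - 1e-12, Fisher-transformed (atanh), then standardized across
    all pairs of the dataset to mean 0, sd 1. The resulting weights are the
    normalized co-expression z-scores used for cross-source integration.
    """
    n_genes, n_samples = m.shape
    if n_samples < 4:
        raise ValueError("co-expression requires at least 4 samples")
    if n_genes < 3:
        raise ValueError("co-expression requires at least 3 genes")
    x = m.values()
    if np.isnan(x).any():
        raise ValueError("matrix must be complete (impute first)")
    if (np.std(x, axis=1) == 0).any():
        raise ValueError("zero-variance gene present; z-score upstream first")
    r = np.corrcoef(x)
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    t = np.arctanh(r)
    iu, ju = np.triu_indices(n_genes, k=1)
    vals = t[iu, ju]
    mu, sd = vals.mean(), vals.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate co-expression distribution (all pairs equal)")
    z = (vals - mu) / sd
    genes = m.gene_ids
    edges = {}
    for i, j, w in zip(iu, ju, z):
        a, b = genes[i], genes[j]
        key = (a, b) if a < b else (b, a)
        edges[key] = float(w)
    return WeightedNetwork(
        universe=frozenset(genes),
        edges=edges,
        net_type="coexpression",
        dataset_id=dataset_id,
        complete=True,
    )


def qc_summary(m: ExpressionMatrix) -> dict:
    """Per-sample mean/sd/missing-fraction and per-gene missing-fraction."""
    x = m.values()
    miss = np.isnan(x)
    with np.errstate(invalid="ignore"):
        sample_mean = np.nanmean(x, axis=0) if x.size else np.array([])
        sample_sd = np.nanstd(x, axis=0, ddof=1) if x.size else np.array([])
    per_sample = pd.DataFrame(
        {
            "mean": sample_mean,
            "sd": sample_sd,
            "missing_fraction": miss.mean(axis=0) if x.size else [],
        },
        index=m.sample_ids,
    )
    per_gene = pd.DataFrame(
        {"missing_fraction": miss.mean(axis=1) if x.size else []}, index=m.gene_ids
    )
    return {
        "n_genes": m.shape[0],
        "n_samples": m.shape[1],
        "per_sample": per_sample,
        "per_gene": per_gene,
    }
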