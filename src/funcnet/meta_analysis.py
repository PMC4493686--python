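"""Differential-expression meta-analysis across datasets.

Per-dataset log2 fold changes with Welch variances are pooled per gene under
a random-effects model: y_i ~ N(mu, v_i + tau^2), with the between-study
variance tau^2 estimated either by restricted maximum likelihood (REML,
default) or the closed-form DerSimonian-Laird moment estimator (DL). Pooled
effects get normal z-tests, Benjamini-Hochberg FDR control across genes, and
permutation-based gene-set enrichment on the meta p-values.

The pooling model is exposed statsmodels-style: ``RandomEffectsMeta(y, v)``
is the model, ``.fit()`` returns a results object with estimates, standard
errors, heterogeneity diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .expression import ExpressionMatrix

__all__ = [
    "EffectEstimate",
    "MetaResult",
    "GeneSet",
    "EnrichmentResult",
    "RandomEffectsMeta",
    "RandomEffectsMetaResults",
    "per_dataset_effects",
    "pool_random_effects",
    "meta_analyze",
    "adjust_bh",
    "parse_gmt",
    "enrich_gene_sets",
]

Z975 = 1.959963984540054  # Phi^{-1}(0.975)
VARIANCE_FLOOR = 1e-8


@dataclass(frozen=True)
class EffectEstimate:
    """One dataset's log2 fold change (case - control) for one gene."""

    gene: str
    dataset_id: str
    y: float
    v: float
    ci_low: float
    ci_high: float
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError(f"variance must be positive (gene {self.gene})")
        if not (self.ci_low <= self.y <= self.ci_high):
            raise ValueError(f"CI does not bracket the estimate (gene {self.gene})")


@dataclass(frozen=True)
class MetaResult:
    gene: str
    mu_hat: float
    se_mu: float
    tau2: float
    method: str
    q_stat: float
    c_scale: float
    z: float
    p: float
    q: float  # BH-adjusted; NaN until adjusted across the tested set
    k_studies: int


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    direction: str  # up | down
    observed_stat: float
    n_permutations: int
    p_perm: float


def per_dataset_effects(
    m_log2: ExpressionMatrix, labels: dict[str, str] | None = None
) -> list[EffectEstimate]:
    """Welch-type per-gene effects between case and control samples.

    y = mean(case) - mean(control); v = s2_case/n_case + s2_ctrl/n_ctrl;
    95% CI = y +/- 1.96*sqrt(v). The matrix must be on the log2 scale and
    NOT z-scored (z-scoring destroys fold-change units). Degenerate zero
    variances are floored at 1e-8 so pooling stays defined. Genes entirely
    missing in either group are skipped.
    """
    labels = labels if labels is not None else m_log2.sample_conditions
    if labels is None:
        raise ValueError("sample condition labels are required")
    case_cols = [s for s in m_log2.sample_ids if labels.get(s) == "case"]
    ctrl_cols = [s for s in m_log2.sample_ids if labels.get(s) == "control"]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(case_cols)} case / {len(ctrl_cols)} control"
        )
    xc = m_log2.data[case_cols].to_numpy()
    x0 = m_log2.data[ctrl_cols].to_numpy()
    effects: list[EffectEstimate] = []
    for gene, row_c, row_0 in zip(m_log2.gene_ids, xc, x0):
        oc, o0 = row_c[~np.isnan(row_c)], row_0[~np.isnan(row_0)]
        if oc.size < 2 or o0.size < 2:
            continue
        y = float(oc.mean() - o0.mean())
        v = float(oc.var(ddof=1) / oc.size + o0.var(ddof=1) / o0.size)
        v = max(v, VARIANCE_FLOOR)
        half = Z975 * math.sqrt(v)
        effects.append(
            EffectEstimate(
                gene=gene,
                dataset_id=m_log2.data.columns.name or "",
                y=y,
                v=v,
                ci_low=y - half,
                ci_high=y + half,
                n_case=int(oc.size),
                n_control=int(o0.size),
            )
        )
    return effects


class RandomEffectsMeta:
    """Random-effects meta-analysis model for one quantity.

    Parameters
    ----------
    y : array of per-study effect estimates
    v : array of positive within-study variances
    """

    def __init__(self, y, v):
        self.y = np.asarray(y, dtype=float)
        self.v = np.asarray(v, dtype=float)
        if self.y.shape != self.v.shape or self.y.ndim != 1:
            raise ValueError("y and v must be equal-length 1-D arrays")
        if self.y.size == 0:
            raise ValueError("no studies")
        if (self.v <= 0).any():
            raise ValueError("all within-study variances must be positive")

    @property
    def k(self) -> int:
        return self.y.size

    def _mu_se(self, tau2: float) -> tuple[float, float]:
        w = 1.0 / (self.v + tau2)
        mu = float((w * self.y).sum() / w.sum())
        return mu, float(math.sqrt(1.0 / w.sum()))

    def _tau2_dl(self) -> tuple[float, float, float]:
        """DerSimonian-Laird moment estimator; returns (tau2, Q, C)."""
        w = 1.0 / self.v
        ybar = float((w * self.y).sum() / w.sum())
        q = float((w * (self.y - ybar) ** 2).sum())
        c = float(w.sum() - (w**2).sum() / w.sum())
        tau2 = max(0.0, (q - (self.k - 1)) / c) if c > 0 else 0.0
        return tau2, q, c

    def _neg_restricted_loglik(self, tau2: float) -> float:
        w = 1.0 / (self.v + tau2)
        mu = (w * self.y).sum() / w.sum()
        return 0.5 * (
            np.log(self.v + tau2).sum()
            + math.log(w.sum())
            + float((w * (self.y - mu) ** 2).sum())
        )

    def _tau2_reml(self, tol: float = 1e-8) -> float:
        if self.k < 2 or np.allclose(self.y, self.y[0]):
            return 0.0
        upper = 10.0 * max(float(np.var(self.y, ddof=1)), float(self.v.max()))
        if upper <= 0:
            return 0.0
        res = optimize.minimize_scalar(
            self._neg_restricted_loglik,
            bounds=(0.0, upper),
            method="bounded",
            options={"xatol": tol},
        )
        # the bounded minimizer never evaluates exactly at 0; check the edge
        tau2 = float(res.x)
        if self._neg_restricted_loglik(0.0) <= res.fun:
            return 0.0
        return tau2

    def fit(self, method: str = "REML") -> "RandomEffectsMetaResults":
        method = method.upper()
        if method not in ("REML", "DL"):
            raise ValueError(f"unknown method {method!r}")
        tau2_dl, q, c = self._tau2_dl()
        tau2 = self._tau2_reml() if method == "REML" else tau2_dl
        mu, se = self._mu_se(tau2)
        return RandomEffectsMetaResults(
            model=self, method=method, mu=mu, se=se, tau2=tau2, q_stat=q, c_scale=c
        )


@dataclass
class RandomEffectsMetaResults:
    """Fitted pooled effect with heterogeneity diagnostics."""

    model: RandomEffectsMeta
    method: str
    mu: float
    se: float
    tau2: float
    q_stat: float
    c_scale: float

    @property
    def zvalue(self) -> float:
        return self.mu / self.se

    @property
    def pvalue(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.zvalue)))

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return (self.mu - z * self.se, self.mu + z * self.se)

    def summary(self) -> pd.DataFrame:
        lo, hi = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": [self.mu],
                "se": [self.se],
                "ci_low": [lo],
                "ci_high": [hi],
                "tau2": [self.tau2],
                "Q": [self.q_stat],
                "z": [self.zvalue],
                "p": [self.pvalue],
                "k": [self.model.k],
                "method": [self.method],
            },
            index=["pooled"],
        )


def pool_random_effects(
    effects: Sequence[EffectEstimate], method: str = "REML"
) -> MetaResult:
    """Pool one gene's per-dataset effects into a MetaResult.

    A single study passes through with tau2 = 0 and k_studies = 1.
    """
    if not effects:
        raise ValueError("no effects to pool")
    genes = {e.gene for e in effects}
    if len(genes) != 1:
        raise ValueError(f"effects span multiple genes: {sorted(genes)}")
    gene = effects[0].gene
    y = np.array([e.y for e in effects])
    v = np.array([e.v for e in effects])
    if len(effects) == 1:
        mu, se = float(y[0]), float(math.sqrt(v[0]))
        z = mu / se
        return MetaResult(
            gene=gene, mu_hat=mu, se_mu=se, tau2=0.0, method=method.upper(),
            q_stat=0.0, c_scale=0.0, z=z, p=float(2 * stats.norm.sf(abs(z))),
            q=float("nan"), k_studies=1,
        )
    res = RandomEffectsMeta(y, v).fit(method=method)
    return MetaResult(
        gene=gene,
        mu_hat=res.mu,
        se_mu=res.se,
        tau2=res.tau2,
        method=res.method,
        q_stat=res.q_stat,
        c_scale=res.c_scale,
        z=res.zvalue,
        p=res.pvalue,
        q=float("nan"),
        k_studies=len(effects),
    )


def meta_analyze(
    effects: Iterable[EffectEstimate], method: str = "REML"
) -> pd.DataFrame:
    """Pool effects gene-by-gene and BH-adjust the p-values.

    Returns a per-gene table sorted by gene id with columns mu_hat, se_mu,
    tau2, q_stat, c_scale, z, p, q, k_studies.
    """
    by_gene: dict[str, list[EffectEstimate]] = {}
    for e in effects:
        by_gene.setdefault(e.gene, []).append(e)
    if not by_gene:
        raise ValueError("no effects supplied")
    rows = [pool_random_effects(v, method=method) for _, v in sorted(by_gene.items())]
    df = pd.DataFrame(
        {
            "mu_hat": [r.mu_hat for r in rows],
            "se_mu": [r.se_mu for r in rows],
            "tau2": [r.tau2 for r in rows],
            "q_stat": [r.q_stat for r in rows],
            "c_scale": [r.c_scale for r in rows],
            "z": [r.z for r in rows],
            "p": [r.p for r in rows],
            "k_studies": [r.k_studies for r in rows],
        },
        index=[r.gene for r in rows],
    )
    df.index.name = "gene"
    df["q"] = adjust_bh(df["p"].to_numpy())
    return df


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending order statistics,
    clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def parse_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: set name TAB description TAB member genes..."""
    sets: list[GeneSet] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected name, description, members")
            sets.append(GeneSet(name=parts[0], genes=frozenset(g for g in parts[2:] if g)))
    return sets


def enrich_gene_sets(
    meta: pd.DataFrame,
    sets: Sequence[GeneSet],
    B: int = 1000,
    seed: int = 0,
    min_size: int = 3,
) -> list[EnrichmentResult]:
    """Permutation enrichment of gene sets on meta-analysis p-values.

    Genes are split into up (mu_hat > 0) and down (mu_hat < 0) strata. For
    each set and direction, the observed statistic is the mean of -ln(p)
    over set members in the stratum; the null distribution is B random
    same-size subsets of the stratum (gene-label resampling), and
    p_perm = (1 + #{null >= observed}) / (B + 1). Sets with fewer than
    ``min_size`` members in the tested universe are skipped.
    """
    if meta.empty:
        raise ValueError("empty meta-analysis table")
    universe = set(meta.index)
    rng = np.random.default_rng(seed)
    neglogp = -np.log(np.clip(meta["p"].to_numpy(), 1e-300, None))
    strata = {
        "up": np.nonzero(meta["mu_hat"].to_numpy() > 0)[0],
        "down": np.nonzero(meta["mu_hat"].to_numpy() < 0)[0],
    }
    gene_pos = {g: i for i, g in enumerate(meta.index)}
    # null statistics cached per (direction, subset size)
    null_cache: dict[tuple[str, int], np.ndarray] = {}

    def null_stats(direction: str, size: int) -> np.ndarray:
        key = (direction, size)
        if key not in null_cache:
            vals = neglogp[strata[direction]]
            draws = np.empty(B)
            for b in range(B):
                draws[b] = rng.choice(vals, size=size, replace=False).mean()
            null_cache[key] = draws
        return null_cache[key]

    results: list[EnrichmentResult] = []
    for gs in sets:
        members = gs.genes & universe
        if len(members) < min_size:
            continue
        member_idx = np.array(sorted(gene_pos[g] for g in members))
        for direction, stratum in strata.items():
            in_stratum = np.intersect1d(member_idx, stratum)
            if in_stratum.size == 0:
                results.append(
                    EnrichmentResult(gs.name, direction, 0.0, B, 1.0)
                )
                continue
            observed = float(neglogp[in_stratum].mean())
            null = null_stats(direction, in_stratum.size)
            p_perm = float((1 + (null >= observed).sum()) / (B + 1))
            results.append(
                EnrichmentResult(gs.name, direction, observed, B, p_perm)
            )
    return results
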