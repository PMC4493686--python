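"""Seeded synthetic datasets with known ground truth.

Everything the pipeline consumes can be generated offline: expression
matrices with planted co-expression modules (Gaussian equi-correlated factor
model, so the expected within-module correlation is exactly rho),
stochastic-block-model interaction networks with planted clusters,
case-control dataset collections with planted differential-expression
effects drawn from a random-effects model, and whole mock on-disk
repositories (raw matrices + metadata + identifier maps + networks) for
end-to-end pipeline tests. All generators are pure functions of their
arguments and seed; truth files are written alongside fixtures and are never
read by the code under test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, write_expression_table
from .metadata import MetadataRecord, write_metadata
from .networks import WeightedNetwork, edge_key, write_edge_list

__all__ = [
    "FixtureTruth",
    "gen_expression_dataset",
    "gen_interaction_network",
    "gen_case_control_collection",
    "gen_mock_repository",
]


@dataclass
class FixtureTruth:
    """Planted ground truth for a synthetic fixture."""

    seed: int
    module_assignments: dict[str, int] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)
    true_tau: float = 0.0
    network_clusters: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "module_assignments": self.module_assignments,
                "de_genes": self.de_genes,
                "true_tau": self.true_tau,
                "network_clusters": self.network_clusters,
            },
            indent=2,
            sort_keys=True,
        )


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = len(str(n - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def gen_expression_dataset(
    n_genes: int = 100,
    n_samples: int = 20,
    n_modules: int = 3,
    module_size: int = 10,
    rho: float = 0.9,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionMatrix, FixtureTruth]:
    """Expression matrix with planted co-expression modules.

    Module genes follow x = sqrt(rho)*f_m + sqrt(1-rho)*eps with a shared
    per-sample module factor f_m, giving expected pairwise correlation rho
    within a module; background genes are iid N(0,1). Each gene then gets a
    random affine distortion (scale in [0.5, 2], shift in [-1, 1]) so
    z-scoring has work to do, and cells are masked missing completely at
    random at ``missing_rate``.
    """
    if n_modules * module_size > n_genes:
        raise ValueError("modules exceed gene count")
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    if not (0 <= missing_rate < 0.5):
        raise ValueError("missing_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    factors = rng.standard_normal((n_modules, n_samples))
    x = rng.standard_normal((n_genes, n_samples))
    assignments: dict[str, int] = {}
    for m in range(n_modules):
        rows = slice(m * module_size, (m + 1) * module_size)
        x[rows] = np.sqrt(rho) * factors[m] + np.sqrt(1 - rho) * x[rows]
        for g in genes[rows]:
            assignments[g] = m
    scale = rng.uniform(0.5, 2.0, size=n_genes)
    shift = rng.uniform(-1.0, 1.0, size=n_genes)
    x = x * scale[:, None] + shift[:, None]
    if missing_rate > 0:
        mask = rng.random((n_genes, n_samples)) < missing_rate
        x = np.where(mask, np.nan, x)
    df = pd.DataFrame(x, index=genes, columns=[f"S{j}" for j in range(n_samples)])
    truth = FixtureTruth(seed=seed, module_assignments=assignments)
    return ExpressionMatrix(df), truth


def gen_interaction_network(
    n_genes: int = 200,
    n_clusters: int = 5,
    cluster_size: int = 10,
    p_in: float = 0.9,
    p_out: float = 0.05,
    w_in_mean: float = 3.0,
    w_out_mean: float = 0.0,
    seed: int = 0,
    w_sd: float = 0.5,
    net_type: str = "functional",
) -> tuple[WeightedNetwork, FixtureTruth]:
    """Stochastic block model with planted weighted clusters.

    Within-cluster pairs get an edge with probability ``p_in`` and weight
    N(w_in_mean, w_sd^2); all other pairs with probability ``p_out`` and
    weight N(w_out_mean, w_sd^2). The universe covers all genes even when
    isolated.
    """
    if n_clusters * cluster_size > n_genes:
        raise ValueError("clusters exceed gene count")
    for p in (p_in, p_out):
        if not (0 <= p <= 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    cluster_of = {}
    for c in range(n_clusters):
        for g in genes[c * cluster_size : (c + 1) * cluster_size]:
            cluster_of[g] = c
    edges: dict[tuple[str, str], float] = {}
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            gi, gj = genes[i], genes[j]
            same = cluster_of.get(gi, -1) == cluster_of.get(gj, -2)
            p, mu = (p_in, w_in_mean) if same else (p_out, w_out_mean)
            if rng.random() < p:
                edges[edge_key(gi, gj)] = float(rng.normal(mu, w_sd))
    truth = FixtureTruth(seed=seed, network_clusters=cluster_of)
    return (
        WeightedNetwork(
            universe=frozenset(genes),
            edges=edges,
            net_type=net_type,
            dataset_id=f"sbm-seed{seed}",
        ),
        truth,
    )


def gen_case_control_collection(
    n_datasets: int = 6,
    n_genes: int = 200,
    n_per_group: int = 4,
    frac_de: float = 0.2,
    mu_de: float = 1.0,
    tau: float = 0.25,
    sigma: float = 0.5,
    seed: int = 0,
) -> tuple[list[tuple[ExpressionMatrix, dict[str, str]]], FixtureTruth]:
    """Case-control expression datasets with planted DE effects.

    The first ``frac_de`` fraction of genes are differentially expressed:
    dataset i adds a study-level effect theta_gi ~ N(mu_de, tau^2) to the
    case means of gene g; every cell carries N(0, sigma^2) noise on the log2
    scale. Emulates a small collection of comparable case-control studies
    (e.g., germ-free vs conventional gut tissue).
    """
    if not (0 < frac_de < 1):
        raise ValueError("frac_de must be in (0, 1)")
    if min(n_datasets, n_genes, n_per_group) < 1 or sigma < 0 or tau < 0:
        raise ValueError("invalid generator parameters")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    n_de = int(round(frac_de * n_genes))
    de_genes = {g: mu_de for g in genes[:n_de]}
    base = rng.uniform(4.0, 10.0, size=n_genes)  # baseline log2 expression
    collection = []
    for d in range(n_datasets):
        theta = np.zeros(n_genes)
        theta[:n_de] = rng.normal(mu_de, tau, size=n_de)
        cols = [f"D{d}_case{j}" for j in range(n_per_group)] + [
            f"D{d}_ctrl{j}" for j in range(n_per_group)
        ]
        labels = {c: ("case" if "case" in c else "control") for c in cols}
        x = np.empty((n_genes, 2 * n_per_group))
        x[:, :n_per_group] = (base + theta)[:, None] + rng.normal(
            0, sigma, size=(n_genes, n_per_group)
        )
        x[:, n_per_group:] = base[:, None] + rng.normal(
            0, sigma, size=(n_genes, n_per_group)
        )
        df = pd.DataFrame(x, index=genes, columns=cols)
        df.columns.name = f"DS{d}"
        collection.append((ExpressionMatrix(df, sample_conditions=labels), labels))
    truth = FixtureTruth(seed=seed, de_genes=de_genes, true_tau=tau)
    return collection, truth


def gen_mock_repository(
    root_path: str | Path,
    spec: dict | None = None,
    seed: int = 0,
) -> FixtureTruth:
    """Write a mock repository tree the pipeline can run end-to-end.

    Layout per dataset: data/<source>/<dataset_id>/{raw.tsv, metadata.json};
    identifier maps under maps/<source>.tsv; interaction networks under
    networks/<source>/<dataset_id>.tsv; curated overrides under
    <source>/etc/manual_curation/<dataset_id>.json. Metadata titles embed
    searchable keywords so selection screens work end-to-end.
    """
    spec = spec or {}
    source = spec.get("source", "mockgeo")
    n_datasets = spec.get("n_datasets", 3)
    n_genes = spec.get("n_genes", 30)
    n_samples = spec.get("n_samples", 10)
    taxonomy_id = spec.get("taxonomy_id", 10090)
    keywords = spec.get(
        "keywords", ["germ-free colon", "conventional colon", "prostate cancer"]
    )
    curated_ids = set(spec.get("curated_ids", []))
    root = Path(root_path)
    rng = np.random.default_rng(seed)
    truth = FixtureTruth(seed=seed)

    maps_dir = root / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    # probe->gene map: two probes per gene for the first few genes
    genes = _gene_names(n_genes)
    with open(maps_dir / f"{source}.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# probe\tgene\n")
        for i, g in enumerate(genes):
            fh.write(f"p{i}a\t{g}\n")
            if i < 5:
                fh.write(f"p{i}b\t{g}\n")
            fh.write(f"{g}\t{g}\n")  # networks already carry target-namespace ids

    for d in range(n_datasets):
        ds_id = f"DS{d:03d}"
        ds_dir = root / "data" / source / ds_id
        ds_dir.mkdir(parents=True, exist_ok=True)
        m, mtruth = gen_expression_dataset(
            n_genes=n_genes,
            n_samples=n_samples,
            n_modules=2,
            module_size=min(5, n_genes // 2),
            rho=0.8,
            missing_rate=0.05,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        # expression on a positive raw scale, probe-level ids
        raw = m.data * 0.5 + 8.0
        probe_rows = {}
        for i, g in enumerate(genes):
            probe_rows[f"p{i}a"] = raw.loc[g]
            if i < 5:
                probe_rows[f"p{i}b"] = raw.loc[g] + rng.normal(0, 0.05, size=n_samples)
        raw_df = pd.DataFrame(probe_rows).T
        raw_df.columns = m.sample_ids
        write_expression_table(ExpressionMatrix(raw_df), ds_dir / "raw.tsv")
        truth.module_assignments.update(
            {f"{ds_id}:{g}": mod for g, mod in mtruth.module_assignments.items()}
        )
        title = keywords[d % len(keywords)]
        record = MetadataRecord(
            dataset_id=ds_id,
            source=source,
            pairs={
                "taxonomy_id": taxonomy_id,
                "platform": f"MOCK{d % 2}",
                "title": f"{title} profiling study {ds_id}",
                "experiment_type": "expression profiling",
                "n_samples": n_samples,
            },
        )
        write_metadata(record, ds_dir / "metadata.json")
        if ds_id in curated_ids:
            cur_dir = root / source / "etc" / "manual_curation"
            cur_dir.mkdir(parents=True, exist_ok=True)
            override = MetadataRecord(
                dataset_id=ds_id,
                source=source,
                pairs={"title": f"curated: {title} ({ds_id})", "curator": "manual"},
            )
            write_metadata(override, cur_dir / f"{ds_id}.json")

        net_dir = root / "networks" / source
        net_dir.mkdir(parents=True, exist_ok=True)
        net, ntruth = gen_interaction_network(
            n_genes=n_genes,
            n_clusters=2,
            cluster_size=min(5, n_genes // 2),
            p_in=0.9,
            p_out=0.05,
            seed=int(rng.integers(0, 2**31 - 1)),
            net_type="physical",
        )
        # physical networks are binary presence/absence edge lists
        binary = WeightedNetwork(
            universe=net.universe,
            edges={k: 1.0 for k in net.edges},
            net_type="physical",
            dataset_id=ds_id,
        )
        write_edge_list(binary, net_dir / f"{ds_id}.tsv")
        truth.network_clusters.update(
            {f"{ds_id}:{g}": c for g, c in ntruth.network_clusters.items()}
        )

    (root / "truth.json").write_text(truth.to_json() + "\n", encoding="utf-8")
    return truth
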