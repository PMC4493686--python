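# funcnet

Reproducible integration of heterogeneous gene data: expression matrices and
interaction networks from different sources are standardized onto a shared
gene namespace, normalized, combined into a single functional network on a
common confidence scale, queried for high-confidence subgraphs around genes
of interest, and meta-analyzed for differential expression across datasets.
It is aimed at systems-biology analyses that pool many public expression and
interaction datasets for one organism or disease, where the bookkeeping
(identifier mapping, normalization recipes, provenance, partial rebuilds) is
as error-prone as the statistics.

## What it computes

**Expression normalization.** Each gene's expression vector is transformed to
z-scores, z = (x − μ_g)/σ_g (mean 0, sd 1 across samples; sample sd, n−1
denominator). Missing values are then imputed from the gene's 10 nearest
neighbor genes: for a missing cell (g, j), neighbor distances are relative
Euclidean distances d_h = √(Σ_c (x_gc − x_hc)²/m_gh) over the m_gh shared
observed samples, and the imputed value is the weighted average
Σ_h w_h x_hj with w_h ∝ 1/(d_h + ε).

**Network integration.** Per dataset, a complete co-expression network is
built from pairwise Pearson correlations, Fisher-transformed
(t = atanh r) and standardized within the dataset to z-scores. Sparse binary
evidence (physical or regulatory edge lists) is placed at a fixed
high-confidence constant (default 2.0) on the same scale. The integrated
functional network averages each pair's z-score over the networks that score
it.

**Seeded subgraph extraction.** A query set Q is expanded by k genes, each
chosen greedily to maximize score(v) = Σ_{u∈S} w(u, v) against the growing
set S, yielding a subgraph of |Q| + k genes connected with high confidence
to the query.

**Random-effects meta-analysis.** Per-dataset log2 fold changes y_i with
Welch variances v_i are pooled per gene under y_i ~ N(μ, v_i + τ²), with τ²
estimated by REML (default) or DerSimonian–Laird; p-values come from
z = μ̂/se(μ̂), the false discovery rate is controlled by Benjamini–Hochberg,
and gene-set enrichment is tested by permutation (default 1,000) of
same-size gene sets within up/down strata.

Everything runs from a checksum-based incremental pipeline: a stage re-runs
only when an input file's MD5 digest or its configuration changed, and
metadata (nested key-value records, curated overrides, provenance logs)
travels with every artifact.

## Worked example

```python
import pathlib
from funcnet import fixtures
from funcnet.pipeline import PipelineConfig, run_pipeline
from funcnet.networks import read_edge_list, extract_subgraph, QuerySpec
from funcnet.meta_analysis import RandomEffectsMeta

ws = pathlib.Path("workspace")
fixtures.gen_mock_repository(ws, {"n_datasets": 3}, seed=1)
cfg = PipelineConfig(recipe="log2::zscore::knn10::coexpr")
report = run_pipeline(cfg, ws)
print(f"executed {len(report.executed)} nodes, failed {len(report.failed)}")

net = read_edge_list(ws / "integrated" / "functional.tsv", net_type="functional")
sub = extract_subgraph(net, QuerySpec(tuple(sorted(net.universe)[:5]), 5))
print(f"subgraph: {len(sub.nodes)} nodes = {len(sub.seed_nodes)} seeds + "
      f"{len(sub.added_nodes)} added")
print("added (score at addition):",
      ", ".join(f"{g} ({sub.add_scores[g]:.2f})" for g in sub.added_nodes))

res = RandomEffectsMeta([0.42, 0.61, 0.29, 0.95, 0.50],
                        [0.04, 0.06, 0.03, 0.09, 0.05]).fit("REML")
print(res.summary().round(4).to_string())
```

prints

```
executed 16 nodes, failed 0
subgraph: 10 nodes = 5 seeds + 5 added
added (score at addition): G23 (3.02), G17 (3.78), G14 (2.94), G21 (2.33), G25 (2.27)
        estimate      se  ci_low  ci_high  tau2       Q       z    p  k method
pooled    0.4796  0.0971  0.2893   0.6698   0.0  4.0374  4.9402  0.0  5   REML
```

The 16 executed nodes are the metadata/mapping/normalization/co-expression
chain for three mock datasets plus the final integration; re-running
`run_pipeline` immediately afterwards executes 0 nodes. The subgraph query
expands 5 seed genes by the 5 genes best connected to the growing set (each
shown with its total connection weight at the moment it was added — on the
z scale, values near 3 are strong). The pooled summary reads: common effect
0.48 (95% CI 0.29–0.67), no detectable between-study variance (τ² = 0,
Q = 4.04 on 4 df), z = 4.94 across 5 studies.

A command-line surface mirrors the library:
`funcnet init`, `funcnet generate-fixtures`, `funcnet build`, `funcnet plan`,
`funcnet integrate --in a.tsv --in b.tsv --out combined.tsv`,
`funcnet query --net combined.tsv --genes q.txt --k 10 --out subgraph/`.

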