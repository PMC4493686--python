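# Methods

This note documents the models and procedures funcnet implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical details that affect results.

## Metadata, selection, and provenance

Dataset metadata is an unordered collection of nested key-value pairs,
serialized as JSON (UTF-8, one object per dataset) for diffability and
lossless round-tripping. Curated overrides, stored at
`<source>/etc/manual_curation/<dataset_id>.json`, are merged over the
automatic record with the curated value winning at the deepest key level:
nested mappings merge key-wise, scalars and lists are replaced whole. This
deep-merge rule was a genuinely open choice (whole-record replacement would
also be defensible); it was picked because it lets a curator correct one
field without retyping the record, and it is marked in the result by the
reserved key `_curation_applied` so downstream users can tell. The merge is
idempotent.

Dataset selection conjoins taxonomy membership, include/exclude id lists, a
minimum sample count, and case-insensitive regex searches against
string-valued fields at dotted key paths (e.g. `title ~ "germ-?free"`). A
missing key path fails the pattern rather than erroring, because screens
typically run over heterogeneous records.

Provenance is an append-only log of steps, each carrying the command, the
tool version, and MD5 digests of all input files. MD5 is used as a change
detector, not a security primitive; any content change flips the digest,
which is the property the incremental planner needs.

## Identifier standardization

Mapping tables are user-supplied two-column TSVs onto a target namespace
(e.g. a UniRef90-style shared identifier). Many-to-one maps are allowed;
many-to-many maps are rejected at parse time so the pipeline stays
deterministic — ambiguity must be resolved upstream. Expression rows mapping
to the same target merge by element-wise mean over non-missing values
(unbiased if probes are exchangeable replicates); a merged cell is missing
only when all contributors are. Network edges remap with parallel edges
collapsed to the maximum weight (keep the strongest evidence) and
merge-induced self-edges dropped. Every mapping emits a report whose
`success` flag compares the mapped fraction with a configurable threshold
(default 0.5).

## Expression processing

Processing order is fixed: optional log2(x + 1) → per-gene z-score → kNN
imputation → co-expression. Differential-expression effects are computed on
the log2, mapped, **non**-z-scored matrix, because z-scoring destroys
fold-change units.

*Z-scoring* uses the sample standard deviation (n−1). Genes with fewer than
3 observed values are dropped and counted; zero-variance genes are set to
all-zero and flagged rather than dropped, so they stay addressable in
networks.

*Imputation* (defaults k = 10, ε = 1e−6, min_shared = 3): for a missing
cell (g, j), candidates are genes observed at sample j sharing at least
`min_shared` observed samples with g. The distance is the root-mean-square
difference over shared observed samples — dividing by the number of shared
samples makes genes with different missingness patterns comparable, which is
the reading adopted for "relative" Euclidean distance. Weights are
1/(d + ε), normalized to sum to 1; ε keeps an exact-duplicate neighbor
(d = 0) finite and dominant. With no admissible candidate the gene's
observed mean is used and the cell is flagged `fallback_used`. Distances are
computed once from observed entries only; imputation is single-pass, not
iterated.

*Co-expression*: Pearson r over all samples for every unordered pair,
clamped to |r| ≤ 1 − 1e−12, Fisher-transformed (atanh), then standardized
across all pairs of the dataset to mean 0, sd 1. The within-dataset
standardization is what makes edge weights from different datasets and data
types commensurable ("normalized co-expression z-scores"). The similarity
measure is config-extensible; Pearson + Fisher is the default realization,
documented as such rather than claimed to be bit-compatible with any other
toolkit.

## Network integration and seeded queries

Continuous networks are z-standardized across their own edges; binary
networks (all weights identical — the typical physical/regulatory edge list)
get a fixed confidence constant, default 2.0, aligning presence-only
evidence with the ">2 is high confidence" convention on the z scale. The
constant is configurable.

Integration averages each pair over the networks that *score* it (a complete
co-expression network scores every pair of its universe; a sparse edge list
scores only its explicit edges). Averaging over scoreable networks — rather
than dividing by the total network count — avoids diluting sparse physical
evidence with implicit zeros; the alternative (`average_mode="all"`) is
available. The per-edge mean uses exact summation (`math.fsum`), so the
result is invariant to the order networks are supplied.

Seeded subgraph extraction is a greedy expansion: starting from the query
genes present in the universe, k times add the candidate v maximizing
score(v) = Σ_{u∈S} w(u, v), with unscored pairs contributing 0 (the neutral
confidence on the z scale) and ties broken lexicographically for
determinism. Exactly min(k, |V| − |S|) genes are added, so the output size
is |Q ∩ V| + min(k, |V| − |Q ∩ V|) by construction. Greedy sum-of-weights
expansion is this package's realization of high-confidence neighborhood
retrieval; probabilistic graph-search formulations exist, but the greedy
form is deterministic, testable against an exhaustive per-step oracle, and
satisfies the same contract (k best-connected additions).

## Random-effects meta-analysis

Per-dataset effects are plain Welch estimates per gene:
y = mean(case) − mean(control), v = s²_case/n_case + s²_ctrl/n_ctrl, 95% CI
y ± 1.96√v, with at least two samples per group required. Zero variances
(possible on tiny fixtures) are floored at 1e−8 so pooling stays defined.
Empirical-Bayes moderation of per-gene variances is deliberately not
implemented; effects here are unshrunken, which is conservative for genes
with few samples.

Pooling assumes y_i ~ N(μ, v_i + τ²). The DerSimonian–Laird estimator is the
closed form: with w_i = 1/v_i, ȳ = Σw_i y_i/Σw_i, Q = Σw_i(y_i − ȳ)²,
C = Σw_i − Σw_i²/Σw_i, τ² = max(0, (Q − (k−1))/C); when Q ≤ k − 1 it reduces
to fixed-effect inverse-variance pooling. REML (the default) maximizes the
restricted log-likelihood
−½[Σ ln(v_i+τ²) + ln Σ(v_i+τ²)⁻¹ + Σ(y_i−μ̂(τ²))²/(v_i+τ²)] by bounded
scalar search on [0, 10·max(var(y), max v_i)] to tolerance 1e−8, with an
explicit boundary check at τ² = 0 (the bounded minimizer never lands exactly
on the edge). Bounded search was chosen over Fisher scoring for robustness
on desk-scale inputs; DL is retained both as an option and as the
closed-form cross-check. Either way μ̂ = Σy_i/(v_i+τ²) / Σ1/(v_i+τ²),
se = √(1/Σ1/(v_i+τ²)), z = μ̂/se, two-sided normal p. A single study passes
through with τ² = 0 and is flagged `k_studies = 1`.

Benjamini–Hochberg adjustment is the standard step-up,
q_(i) = min_{j≥i} m·p_(j)/j, clipped at 1, returned in input order; it is
permutation-invariant and monotone in p (cross-checked against statsmodels).

Gene-set enrichment splits the tested universe by the sign of μ̂ into up and
down strata. For each set and direction the statistic is the mean of −ln p
over set members in the stratum, and the null is B (default 1,000) random
same-size gene subsets drawn from the same stratum, giving
p_perm = (1 + #{null ≥ observed})/(B + 1) — never 0, floor 1/(B+1). Sets
with fewer than 3 members in the universe are skipped; a set with no member
in a stratum reports p_perm = 1 for that direction. The statistic and the
within-stratum gene-label permutation scheme are this package's documented
choices; other enrichment statistics exist and are not claimed to be
equivalent.

## Synthetic data

The generators produce everything the pipeline consumes, with planted truth:

- *Expression with modules*: Gaussian equi-correlated factor model
  (x = √ρ·f_m + √(1−ρ)·ε per module gene), so the expected within-module
  correlation is exactly ρ — a closed form the tests exploit. A per-gene
  random affine distortion (scale 0.5–2, shift ±1) gives z-scoring real
  work; missingness is MCAR.
- *Networks*: weighted stochastic block model (within-cluster edges with
  probability p_in and weight N(w_in, 0.5²); cross edges p_out, N(w_out, 0.5²)).
- *Case-control collections*: differentially expressed genes receive
  study-level effects θ_gi ~ N(μ_de, τ²) added to case means on the log2
  scale, with N(0, σ²) measurement noise — a direct instantiation of the
  random-effects model, emulating a small collection of comparable
  case-control studies (default 6 datasets, 4 samples per arm).
- *Mock repositories*: full on-disk trees (raw probe-level matrices,
  metadata with searchable titles, probe→gene maps, binary physical edge
  lists, curated overrides) for end-to-end pipeline tests.

What the fixtures do **not** emulate: platform-specific intensity
distributions, probe-level artifacts, batch effects, informative
missingness, scale-free network topology, or repository wire formats. Tests
passing on these fixtures demonstrate the algorithms' contracts
(normalization invariants, imputation accuracy relative to gene-mean,
planted-structure recovery, parameter recovery, FDR arithmetic, calibrated
permutation p-values, incremental-build correctness) — not that any
particular biological result would be obtained on real repository data.

## Pipeline and incremental builds

Each stage instance (per-dataset metadata merge, mapping, normalization,
co-expression; global integration, query, meta-analysis, enrichment) is a
DAG node with declared input files and a configuration hash. After a node
runs, the MD5 digests of its inputs and its config hash are recorded; the
planner marks a node stale iff an output is missing, the config hash
changed, or a recorded digest differs from the file's current digest, then
closes downstream. A corrupted state file simply makes everything stale. All
writers are deterministic (sorted rows, `%.10g` floats, '.' decimal
separator, LF endings, UTF-8), which is what makes an incremental run
byte-identical to a from-scratch run — each node reads its inputs from disk,
never from memory carried across nodes. A failing node halts only its
downstream subtree. `write_outputs` refuses to overwrite a file it does not
own.

Recipes are `::`-separated step strings over the vocabulary `log2`,
`zscore`, `knn<k>`, `coexpr`, validated for canonical order (imputation
requires the standardized scale; co-expression requires a complete matrix).

## Problem sizes used in the validation suite

The test and acceptance workloads run on desk-scale inputs chosen to make
the statistical checks sharp while staying quick: subgraph-size checks on
150–250-gene clustered networks; imputation accuracy on 50 replicates of
60×20 matrices (ρ = 0.9 modules, 5% MCAR); greedy-search optimality against
exhaustive evaluation on 100 graphs of ≤15 nodes; cluster recovery on 50
seeded 100-gene block models; REML recovery on 200 replicates of 20 studies
(μ = 0.5, τ = 0.25, v_i ~ U(0.01, 0.05)); enrichment calibration at
B = 1,000 over 200 null sets; incremental-build equivalence on 3-dataset
mock repositories.

## Known limitations

- No probe-level microarray preprocessing (RMA/MAS5); inputs are summarized
  matrices.
- No empirical-Bayes moderation of per-gene variances.
- No Bayesian or discriminative weighting of evidence sources during
  integration; all scoreable networks count equally.
- Identifier maps are taken as given; no ortholog inference or
  sequence-based clustering.
- The enrichment procedure tests enrichment of small p-values within a
  direction stratum; it does not implement competitive rank-based statistics
  (e.g. weighted KS running sums).
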