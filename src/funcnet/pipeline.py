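"""Dependency-aware pipeline: configuration, build planning, orchestration.

A workspace is a directory tree holding raw inputs
(``data/<source>/<dataset_id>/raw.tsv`` + ``metadata.json``, identifier maps
under ``maps/``, interaction edge lists under ``networks/``) and the derived
artifacts the pipeline writes next to them. Each processing stage is a node
in a DAG; the planner compares MD5 digests of every node's inputs and a hash
of its configuration against the state recorded after the last run, and
marks a node stale only when an input changed, its configuration changed, or
an output is missing — plus the downstream closure. Re-running an untouched
workspace executes nothing; outputs are deterministic, so an incremental run
is byte-identical to a from-scratch run.

The per-dataset processing recipe is a ``::``-separated step string, e.g.
``"log2::zscore::knn10::coexpr"``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml

from . import metadata as md
from .expression import (
    CoexpressionConfig,
    ExpressionMatrix,
    ImputationConfig,
    build_coexpression_network,
    impute_knn,
    parse_expression_table,
    transform_log2,
    write_expression_table,
    zscore_rows,
)
from .genemap import map_expression, map_network, parse_gene_map
from .meta_analysis import enrich_gene_sets, meta_analyze, parse_gmt, per_dataset_effects
from .networks import (
    QuerySpec,
    extract_subgraph,
    integrate,
    read_edge_list,
    standardize_edge_weights,
    write_edge_list,
    write_subgraph,
)

__all__ = [
    "PipelineConfig",
    "BuildPlan",
    "PlanNode",
    "RunReport",
    "parse_recipe",
    "plan_build",
    "run_pipeline",
    "write_outputs",
    "load_config",
]

STATE_FILE = ".funcnet/state.json"
PROVENANCE_FILE = ".funcnet/provenance.json"

RECIPE_ORDER = ("log2", "zscore", "knn", "coexpr")


def parse_recipe(s: str) -> list[tuple[str, dict[str, Any]]]:
    """Parse a ``::``-separated recipe into ordered (step, params) pairs.

    Vocabulary: ``log2``, ``zscore``, ``knn<k>`` (e.g. ``knn10``),
    ``coexpr``. Steps must appear in canonical order; unknown or repeated
    tokens are errors.
    """
    steps: list[tuple[str, dict[str, Any]]] = []
    last_rank = -1
    for token in s.split("::"):
        token = token.strip()
        if token in ("log2", "zscore", "coexpr"):
            name, params = token, {}
        elif token.startswith("knn") and token[3:].isdigit() and int(token[3:]) >= 1:
            name, params = "knn", {"k_impute": int(token[3:])}
        else:
            raise ValueError(f"unknown recipe token {token!r}")
        rank = RECIPE_ORDER.index(name)
        if rank <= last_rank:
            raise ValueError(f"recipe step {token!r} out of order in {s!r}")
        last_rank = rank
        steps.append((name, params))
    if not steps:
        raise ValueError("empty recipe")
    return steps


@dataclass
class SourceConfig:
    enabled: bool = True
    include_ids: list[str] = field(default_factory=list)
    exclude_ids: list[str] = field(default_factory=list)


@dataclass
class PipelineConfig:
    """Workspace-level configuration for a full pipeline run."""

    target_namespace: str = "GENE"
    taxa: list[int] | None = None
    sources: dict[str, SourceConfig] = field(default_factory=dict)
    recipe: str = "log2::zscore::knn10::coexpr"
    selection: md.SelectionCriteria = field(default_factory=md.SelectionCriteria)
    binary_confidence: float = 2.0
    average_mode: str = "scoreable"
    query_genes: list[str] = field(default_factory=list)
    query_k: int = 10
    meta_method: str = "REML"
    meta_B: int = 1000
    meta_fdr: float = 0.05
    gmt_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        parse_recipe(self.recipe)  # validates
        if self.average_mode not in ("scoreable", "all"):
            raise ValueError(f"unknown average_mode {self.average_mode!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML/JSON config file with actionable messages."""
    obj = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(obj, dict):
        raise ValueError(f"{path}: config must be a mapping")
    sources = {
        name: SourceConfig(**sc) for name, sc in (obj.pop("sources", {}) or {}).items()
    }
    sel = obj.pop("selection", {}) or {}
    criteria = md.SelectionCriteria(
        taxa=frozenset(sel["taxa"]) if sel.get("taxa") else None,
        include_ids=frozenset(sel["include_ids"]) if sel.get("include_ids") else None,
        exclude_ids=frozenset(sel["exclude_ids"]) if sel.get("exclude_ids") else None,
        patterns=tuple((p["key_path"], p["regex"]) for p in sel.get("patterns", [])),
        min_samples=sel.get("min_samples"),
    )
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(obj) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(sources=sources, selection=criteria, **obj)


# --- build planning ---------------------------------------------------------

@dataclass
class PlanNode:
    name: str
    stage: str
    inputs: list[Path]
    outputs: list[Path]
    config_hash: str
    deps: list[str]
    run: Callable[[], list[str]]  # returns warnings
    status: str = "fresh"  # fresh | stale
    reasons: list[str] = field(default_factory=list)


@dataclass
class BuildPlan:
    nodes: list[PlanNode]

    def stale(self) -> list[PlanNode]:
        return [n for n in self.nodes if n.status == "stale"]

    def node(self, name: str) -> PlanNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)


@dataclass
class RunReport:
    executed: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    failed: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _config_hash(obj: Any) -> str:
    return hashlib.md5(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _load_state(workspace: Path) -> dict[str, Any]:
    path = workspace / STATE_FILE
    if not path.exists():
        return {}
    try:
        state = json.loads(path.read_text(encoding="utf-8"))
        return state if isinstance(state, dict) else {}
    except (json.JSONDecodeError, OSError):
        return {}  # corrupted provenance: every node replans as missing-output


def _save_state(workspace: Path, state: dict[str, Any]) -> None:
    path = workspace / STATE_FILE
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(state, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _merged_metadata(workspace: Path, source: str, ds_id: str) -> md.MetadataRecord:
    rec, _ = md.read_metadata(workspace / "data" / source / ds_id / "metadata.json")
    override_path = workspace / source / "etc" / "manual_curation" / f"{ds_id}.json"
    if override_path.exists():
        curated, _ = md.read_metadata(override_path)
        rec = md.merge_metadata(rec, curated)
    return rec


def _discover(workspace: Path, cfg: PipelineConfig) -> list[tuple[str, str]]:
    """(source, dataset_id) pairs passing source config and selection."""
    found: list[tuple[str, str]] = []
    data_root = workspace / "data"
    if not data_root.exists():
        return found
    for src_dir in sorted(data_root.iterdir()):
        source = src_dir.name
        sc = cfg.sources.get(source, SourceConfig())
        if not sc.enabled:
            continue
        records = []
        for ds_dir in sorted(src_dir.iterdir()):
            if not (ds_dir / "raw.tsv").exists():
                continue
            ds_id = ds_dir.name
            if sc.include_ids and ds_id not in sc.include_ids:
                continue
            if ds_id in sc.exclude_ids:
                continue
            records.append(_merged_metadata(workspace, source, ds_id))
        if not records:
            continue
        criteria = cfg.selection
        if cfg.taxa and criteria.taxa is None:
            criteria = replace(criteria, taxa=frozenset(cfg.taxa))
        selected = md.select_datasets(records, criteria)
        found.extend((source, ds_id) for ds_id in selected)
    return found


def plan_build(cfg: PipelineConfig, workspace: str | Path) -> BuildPlan:
    """Pure planning: build the stage DAG and mark stale nodes.

    A node is stale iff an output is missing, its configuration hash changed,
    or a recorded input digest differs from the file's current digest; stale
    status propagates to all downstream nodes.
    """
    ws = Path(workspace)
    state = _load_state(ws)
    datasets = _discover(ws, cfg)
    recipe = parse_recipe(cfg.recipe)
    step_names = [name for name, _ in recipe]
    nodes: list[PlanNode] = []

    coexpr_outputs: list[Path] = []
    netmap_outputs: list[Path] = []
    integrate_deps: list[str] = []
    meta_inputs: list[Path] = []
    meta_deps: list[str] = []
    meta_sets: list[tuple[str, str]] = []

    for source, ds_id in datasets:
        ds_dir = ws / "data" / source / ds_id
        raw = ds_dir / "raw.tsv"
        meta_in = ds_dir / "metadata.json"
        override = ws / source / "etc" / "manual_curation" / f"{ds_id}.json"
        map_path = ws / "maps" / f"{source}.tsv"

        meta_out = ds_dir / "metadata_merged.json"
        meta_node = f"metadata:{source}/{ds_id}"
        meta_inputs_paths = [meta_in] + ([override] if override.exists() else [])
        nodes.append(
            PlanNode(
                name=meta_node,
                stage="metadata",
                inputs=meta_inputs_paths,
                outputs=[meta_out],
                config_hash=_config_hash({}),
                deps=[],
                run=_make_metadata_exec(ws, source, ds_id, meta_out),
            )
        )

        mapped = ds_dir / "mapped.tsv"
        map_node = f"map:{source}/{ds_id}"
        nodes.append(
            PlanNode(
                name=map_node,
                stage="map",
                inputs=[raw, map_path],
                outputs=[mapped],
                config_hash=_config_hash({"target_namespace": cfg.target_namespace}),
                deps=[],
                run=_make_map_exec(ws, raw, map_path, mapped, source, ds_id),
            )
        )

        normalized = ds_dir / "normalized.tsv"
        norm_node = f"normalize:{source}/{ds_id}"
        nodes.append(
            PlanNode(
                name=norm_node,
                stage="normalize",
                inputs=[mapped],
                outputs=[normalized],
                config_hash=_config_hash({"recipe": cfg.recipe}),
                deps=[map_node],
                run=_make_norm_exec(mapped, normalized, recipe),
            )
        )

        if "coexpr" in step_names:
            coexpr = ds_dir / "coexpr.tsv"
            coexpr_node = f"coexpr:{source}/{ds_id}"
            nodes.append(
                PlanNode(
                    name=coexpr_node,
                    stage="coexpr",
                    inputs=[normalized],
                    outputs=[coexpr],
                    config_hash=_config_hash({}),
                    deps=[norm_node],
                    run=_make_coexpr_exec(normalized, coexpr, ds_id),
                )
            )
            coexpr_outputs.append(coexpr)
            integrate_deps.append(coexpr_node)

        net_in = ws / "networks" / source / f"{ds_id}.tsv"
        if net_in.exists():
            netmapped = ds_dir / "network_mapped.tsv"
            netmap_node = f"netmap:{source}/{ds_id}"
            nodes.append(
                PlanNode(
                    name=netmap_node,
                    stage="netmap",
                    inputs=[net_in, map_path],
                    outputs=[netmapped],
                    config_hash=_config_hash({"target_namespace": cfg.target_namespace}),
                    deps=[],
                    run=_make_netmap_exec(net_in, map_path, netmapped),
                )
            )
            netmap_outputs.append(netmapped)
            integrate_deps.append(netmap_node)

        rec = _merged_metadata(ws, source, ds_id)
        if rec.get_path("sample_conditions"):
            meta_inputs.append(mapped)
            meta_deps.append(map_node)
            meta_sets.append((source, ds_id))

    if coexpr_outputs or netmap_outputs:
        integrated = ws / "integrated" / "functional.tsv"
        nodes.append(
            PlanNode(
                name="integrate",
                stage="integrate",
                inputs=coexpr_outputs + netmap_outputs,
                outputs=[integrated],
                config_hash=_config_hash(
                    {
                        "binary_confidence": cfg.binary_confidence,
                        "average_mode": cfg.average_mode,
                    }
                ),
                deps=integrate_deps,
                run=_make_integrate_exec(coexpr_outputs, netmap_outputs, integrated, cfg),
            )
        )
        if cfg.query_genes:
            qdir = ws / "query"
            nodes.append(
                PlanNode(
                    name="query",
                    stage="query",
                    inputs=[integrated],
                    outputs=[qdir / "nodes.tsv", qdir / "edges.tsv"],
                    config_hash=_config_hash(
                        {"genes": sorted(cfg.query_genes), "k": cfg.query_k}
                    ),
                    deps=["integrate"],
                    run=_make_query_exec(integrated, cfg, qdir),
                )
            )

    if meta_inputs:
        meta_out = ws / "meta" / "results.tsv"
        nodes.append(
            PlanNode(
                name="meta",
                stage="meta",
                inputs=list(meta_inputs),
                outputs=[meta_out],
                config_hash=_config_hash(
                    {"method": cfg.meta_method, "recipe_log2": "log2" in step_names}
                ),
                deps=list(meta_deps),
                run=_make_meta_exec(ws, meta_sets, "log2" in step_names, cfg, meta_out),
            )
        )
        if cfg.gmt_path:
            enr_out = ws / "meta" / "enrichment.tsv"
            nodes.append(
                PlanNode(
                    name="enrich",
                    stage="enrich",
                    inputs=[meta_out, Path(cfg.gmt_path)],
                    outputs=[enr_out],
                    config_hash=_config_hash({"B": cfg.meta_B, "seed": cfg.seed}),
                    deps=["meta"],
                    run=_make_enrich_exec(meta_out, cfg, enr_out),
                )
            )

    # staleness: own inputs/config/outputs, then downstream closure
    stale_names: set[str] = set()
    for node in nodes:
        reasons: list[str] = []
        recorded = state.get(node.name)
        for out in node.outputs:
            if not out.exists():
                reasons.append("missing-output")
                break
        if recorded is None:
            if "missing-output" not in reasons:
                reasons.append("missing-output")
        else:
            if recorded.get("config_hash") != node.config_hash:
                reasons.append("config-changed")
            rec_inputs = recorded.get("inputs", {})
            cur_paths = [str(p) for p in node.inputs]
            if set(rec_inputs) != set(cur_paths):
                reasons.append("input-changed")
            else:
                for p in node.inputs:
                    if not p.exists() or md.md5_file(p) != rec_inputs[str(p)]:
                        reasons.append("input-changed")
                        break
        if reasons:
            node.status = "stale"
            node.reasons = reasons
            stale_names.add(node.name)
    changed = True
    while changed:
        changed = False
        for node in nodes:
            if node.status == "fresh" and any(d in stale_names for d in node.deps):
                node.status = "stale"
                node.reasons = ["input-changed"]
                stale_names.add(node.name)
                changed = True
    return BuildPlan(nodes=nodes)


# --- stage executors (each reads inputs from disk, writes outputs) ----------

def _make_metadata_exec(ws: Path, source: str, ds_id: str, out: Path):
    def run() -> list[str]:
        rec = _merged_metadata(ws, source, ds_id)
        md.write_metadata(rec, out)
        return []

    return run


def _make_map_exec(ws: Path, raw: Path, map_path: Path, out: Path, source: str, ds_id: str):
    def run() -> list[str]:
        m = parse_expression_table(raw)
        gm = parse_gene_map(map_path)
        mapped, report = map_expression(m, gm)
        write_expression_table(mapped, out)
        warnings = []
        if not report.success:
            warnings.append(
                f"{source}/{ds_id}: gene mapping below success threshold "
                f"({report.n_mapped}/{report.n_input} mapped)"
            )
        return warnings

    return run


def _make_norm_exec(mapped: Path, out: Path, recipe):
    def run() -> list[str]:
        m = parse_expression_table(mapped)
        for name, params in recipe:
            if name == "log2":
                m = transform_log2(m)
            elif name == "zscore":
                m, _ = zscore_rows(m)
            elif name == "knn":
                m, _ = impute_knn(m, ImputationConfig(**params))
        write_expression_table(m, out)
        return []

    return run


def _make_coexpr_exec(normalized: Path, out: Path, ds_id: str):
    def run() -> list[str]:
        m = parse_expression_table(normalized)
        net = build_coexpression_network(m, CoexpressionConfig(), dataset_id=ds_id)
        write_edge_list(net, out)
        return []

    return run


def _make_netmap_exec(net_in: Path, map_path: Path, out: Path):
    def run() -> list[str]:
        net = read_edge_list(net_in, net_type="physical")
        gm = parse_gene_map(map_path)
        mapped, _ = map_network(net, gm)
        write_edge_list(mapped, out)
        return []

    return run


def _make_integrate_exec(coexpr_outputs, netmap_outputs, out: Path, cfg: PipelineConfig):
    def run() -> list[str]:
        nets = []
        for p in coexpr_outputs:
            nets.append(read_edge_list(p, net_type="coexpression"))
        for p in netmap_outputs:
            nets.append(read_edge_list(p, net_type="physical"))
        standardized = [
            standardize_edge_weights(n, binary_confidence=cfg.binary_confidence)
            for n in nets
        ]
        combined = integrate(standardized, mode=cfg.average_mode)
        out.parent.mkdir(parents=True, exist_ok=True)
        write_edge_list(combined, out)
        return []

    return run


def _make_query_exec(integrated: Path, cfg: PipelineConfig, out_dir: Path):
    def run() -> list[str]:
        net = read_edge_list(integrated, net_type="functional")
        spec = QuerySpec(tuple(cfg.query_genes), cfg.query_k)
        sub = extract_subgraph(net, spec)
        write_subgraph(sub, out_dir)
        missing = [g for g in cfg.query_genes if g not in net.universe]
        return [f"query genes not in network: {missing}"] if missing else []

    return run


def _make_meta_exec(ws: Path, meta_sets, apply_log2: bool, cfg: PipelineConfig, out: Path):
    def run() -> list[str]:
        effects = []
        for source, ds_id in meta_sets:
            ds_dir = ws / "data" / source / ds_id
            m = parse_expression_table(ds_dir / "mapped.tsv")
            rec = _merged_metadata(ws, source, ds_id)
            labels = {str(k): str(v) for k, v in rec.get_path("sample_conditions").items()}
            if apply_log2:
                m = transform_log2(m)
            m.data.columns.name = ds_id
            effects.extend(per_dataset_effects(m, labels))
        table = meta_analyze(effects, method=cfg.meta_method)
        out.parent.mkdir(parents=True, exist_ok=True)
        write_outputs(table, out, overwrite=True)
        return []

    return run


def _make_enrich_exec(meta_out: Path, cfg: PipelineConfig, out: Path):
    def run() -> list[str]:
        table = pd.read_csv(meta_out, sep="\t", index_col=0)
        sets = parse_gmt(cfg.gmt_path)
        results = enrich_gene_sets(table, sets, B=cfg.meta_B, seed=cfg.seed)
        df = pd.DataFrame(
            {
                "set_name": [r.set_name for r in results],
                "direction": [r.direction for r in results],
                "observed_stat": [r.observed_stat for r in results],
                "n_permutations": [r.n_permutations for r in results],
                "p_perm": [r.p_perm for r in results],
            }
        ).sort_values(["set_name", "direction"], kind="stable")
        out.parent.mkdir(parents=True, exist_ok=True)
        with open(out, "w", encoding="utf-8", newline="\n") as fh:
            df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.10g")
        return []

    return run


def run_pipeline(cfg: PipelineConfig, workspace: str | Path) -> RunReport:
    """Execute stale nodes in topological order; record state and provenance.

    A failing node halts only its downstream subtree; fresh nodes are
    skipped. After each successful node the input digests, configuration
    hash, and outputs are recorded so the next plan can prove freshness.
    """
    ws = Path(workspace)
    plan = plan_build(cfg, ws)
    state = _load_state(ws)
    report = RunReport()
    prov_path = ws / PROVENANCE_FILE
    log = md.ProvenanceLog()
    if prov_path.exists():
        try:
            obj = json.loads(prov_path.read_text(encoding="utf-8"))
            log = md._log_from_obj(obj)
        except (json.JSONDecodeError, OSError):
            pass

    failed_upstream: set[str] = set()
    by_name = {n.name: n for n in plan.nodes}
    done: set[str] = set()
    # topological order via repeated sweeps (small DAGs)
    pending = [n for n in plan.nodes]
    while pending:
        progressed = False
        for node in list(pending):
            if any(d not in done and d in by_name for d in node.deps):
                continue
            pending.remove(node)
            progressed = True
            done.add(node.name)
            if any(d in failed_upstream for d in node.deps):
                failed_upstream.add(node.name)
                report.skipped.append(node.name)
                continue
            if node.status == "fresh":
                report.skipped.append(node.name)
                continue
            try:
                for out in node.outputs:
                    out.parent.mkdir(parents=True, exist_ok=True)
                warnings = node.run()
                report.warnings.extend(warnings)
            except Exception as exc:  # halt downstream subtree only
                report.failed[node.name] = str(exc)
                failed_upstream.add(node.name)
                log = md.record_step(
                    log, node.name, f"funcnet stage {node.stage}", node.inputs,
                    status="failed", detail=str(exc),
                )
                continue
            report.executed.append(node.name)
            log = md.record_step(log, node.name, f"funcnet stage {node.stage}", node.inputs)
            state[node.name] = {
                "config_hash": node.config_hash,
                "inputs": {str(p): md.md5_file(p) for p in node.inputs if p.exists()},
                "outputs": [str(p) for p in node.outputs],
                "output_digests": {
                    str(p): md.md5_file(p) for p in node.outputs if p.exists()
                },
            }
        if not progressed:
            raise RuntimeError("dependency cycle in build plan")
    _save_state(ws, state)
    prov_path.parent.mkdir(parents=True, exist_ok=True)
    prov_path.write_text(
        json.dumps(md._log_to_obj(log), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    _write_indexes(ws, cfg)
    return report


def _write_indexes(ws: Path, cfg: PipelineConfig) -> None:
    """Taxa- and publication-keyed index files over processed datasets."""
    by_taxon: dict[str, list[str]] = {}
    by_pub: dict[str, list[str]] = {}
    for source, ds_id in _discover(ws, cfg):
        rec = _merged_metadata(ws, source, ds_id)
        tax = rec.get_path("taxonomy_id")
        if tax is not None:
            by_taxon.setdefault(str(tax), []).append(f"{source}/{ds_id}")
        pub = rec.get_path("publication_id")
        if pub is not None:
            by_pub.setdefault(str(pub), []).append(f"{source}/{ds_id}")
    for sub, index in (("by_taxon", by_taxon), ("by_publication", by_pub)):
        if not index:
            continue
        idx_dir = ws / "index" / sub
        idx_dir.mkdir(parents=True, exist_ok=True)
        for key, items in sorted(index.items()):
            (idx_dir / f"{key}.txt").write_text(
                "\n".join(sorted(items)) + "\n", encoding="utf-8"
            )


def write_outputs(artifact, path: str | Path, overwrite: bool = False) -> None:
    """Write a matrix, network, subgraph, or results table deterministically.

    Rows are sorted, TSV, LF endings, '.' decimals, trailing newline. An
    existing file is never silently overwritten unless ``overwrite`` is set.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite existing file {path}")
    from .expression import ExpressionMatrix as _EM
    from .networks import Subgraph as _SG, WeightedNetwork as _WN

    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(artifact, _EM):
        write_expression_table(artifact, path)
    elif isinstance(artifact, _WN):
        write_edge_list(artifact, path)
    elif isinstance(artifact, _SG):
        write_subgraph(artifact, path)
    elif isinstance(artifact, pd.DataFrame):
        df = artifact.sort_index()
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            df.to_csv(fh, sep="\t", lineterminator="\n", float_format="%.10g")
    else:
        raise TypeError(f"cannot write artifact of type {type(artifact).__name__}")
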