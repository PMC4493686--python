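"""Standardize probe/gene identifiers onto a target namespace.

Mapping tables are user-supplied two-column TSVs (source id TAB target id),
many-to-one allowed, many-to-many rejected. Expression rows mapping to the
same target are merged by element-wise mean over non-missing values; network
edges are remapped with parallel edges collapsed to the maximum weight and
merge-induced self-edges dropped. Every operation returns a MappingReport
recording the standardization success status.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .networks import WeightedNetwork, edge_key

__all__ = [
    "GeneMap",
    "MappingReport",
    "parse_gene_map",
    "map_expression",
    "map_network",
]

DEFAULT_SUCCESS_THRESHOLD = 0.5


@dataclass(frozen=True)
class GeneMap:
    """Function from source ids to target ids (many-to-one allowed)."""

    entries: dict[str, str]
    target_namespace: str = ""

    def __post_init__(self) -> None:
        for s, t in self.entries.items():
            if not s or not t:
                raise ValueError("empty id in gene map")


@dataclass(frozen=True)
class MappingReport:
    n_input: int
    n_mapped: int
    n_unmapped: int
    n_merged_groups: int
    success: bool

    def __post_init__(self) -> None:
        if self.n_input != self.n_mapped + self.n_unmapped:
            raise ValueError("mapping report does not conserve inputs")


def parse_gene_map(path: str | Path, target_namespace: str = "") -> GeneMap:
    """Parse a 2-column TSV; '#' comment lines allowed.

    Identical duplicate rows are deduplicated; a source id mapped to two
    different targets is an error (resolve ambiguity upstream).
    """
    entries: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            src, tgt = parts
            if src in entries and entries[src] != tgt:
                raise ValueError(
                    f"{path}: conflicting mapping for source id {src!r}: "
                    f"{entries[src]!r} vs {tgt!r}"
                )
            entries[src] = tgt
    return GeneMap(entries=entries, target_namespace=target_namespace)


def _report(n_input: int, n_mapped: int, n_groups: int, threshold: float) -> MappingReport:
    return MappingReport(
        n_input=n_input,
        n_mapped=n_mapped,
        n_unmapped=n_input - n_mapped,
        n_merged_groups=n_groups,
        success=(n_mapped / n_input >= threshold) if n_input else False,
    )


def map_expression(
    m: ExpressionMatrix,
    gm: GeneMap,
    success_threshold: float = DEFAULT_SUCCESS_THRESHOLD,
) -> tuple[ExpressionMatrix, MappingReport]:
    """Remap row ids; drop unmapped rows; merge same-target rows by mean.

    A merged cell is missing only where every contributing row is missing.
    Output rows are sorted lexicographically by target id.
    """
    if m.shape[0] == 0:
        raise ValueError("empty expression matrix")
    mapped_rows = [g for g in m.gene_ids if g in gm.entries]
    n_input = m.shape[0]
    if not mapped_rows:
        raise ValueError("no rows mapped to the target namespace")
    sub = m.data.loc[mapped_rows]
    targets = pd.Index([gm.entries[g] for g in mapped_rows], name=sub.index.name)
    grouped = sub.groupby(targets).mean()  # skips NaN; all-NaN stays NaN
    n_groups = int((targets.value_counts() > 1).sum())
    out = ExpressionMatrix(grouped.sort_index(), sample_conditions=m.sample_conditions)
    return out, _report(n_input, len(mapped_rows), n_groups, success_threshold)


def map_network(
    net: WeightedNetwork,
    gm: GeneMap,
    success_threshold: float = DEFAULT_SUCCESS_THRESHOLD,
) -> tuple[WeightedNetwork, MappingReport]:
    """Remap edge endpoints; drop unmapped edges and merge-induced self-edges.

    Parallel edges arising from the merge collapse to the maximum weight
    (keep the strongest evidence).
    """
    if not net.edges:
        raise ValueError("empty network")
    edges: dict[tuple[str, str], float] = {}
    n_input = len(net.edges)
    n_mapped = 0
    n_collapsed = 0
    for (u, v), w in net.edges.items():
        tu, tv = gm.entries.get(u), gm.entries.get(v)
        if tu is None or tv is None:
            continue
        n_mapped += 1
        if tu == tv:
            continue  # merge-induced self-edge
        key = edge_key(tu, tv)
        if key in edges:
            n_collapsed += 1
            edges[key] = max(edges[key], w)
        else:
            edges[key] = w
    if not edges:
        raise ValueError("no edges survived mapping")
    universe = frozenset(gm.entries[g] for g in net.universe if g in gm.entries)
    out = WeightedNetwork(
        universe=universe,
        edges=edges,
        net_type=net.net_type,
        dataset_id=net.dataset_id,
        complete=False,
    )
    return out, _report(n_input, n_mapped, n_collapsed, success_threshold)
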