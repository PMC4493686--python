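"""Dataset metadata, curated-override merging, selection, and provenance.

Every dataset carries an unordered collection of nested key-value pairs
(taxonomy, platform, publication, experiment type, sample count, ...) plus an
append-only provenance log of the commands that produced its files, each with
MD5 digests of the inputs so downstream stages can decide whether they are
stale. Curated metadata supplied by hand can be merged over the automatically
gathered record; the curated value wins at the deepest key level.
"""

from __future__ import annotations

import copy
import hashlib
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping

__all__ = [
    "MetadataRecord",
    "ProvenanceStep",
    "ProvenanceLog",
    "SelectionCriteria",
    "merge_metadata",
    "select_datasets",
    "record_step",
    "md5_file",
    "read_metadata",
    "write_metadata",
]

TOOL_VERSION = "funcnet-0.1.0"

#: reserved top-level key marking that a curated override was applied
CURATION_KEY = "_curation_applied"


@dataclass(frozen=True)
class MetadataRecord:
    """Nested key-value annotations for one dataset.

    ``pairs`` holds arbitrary finite-depth mappings of non-empty string keys
    to strings, numbers, lists, or nested mappings, and round-trips losslessly
    through JSON.
    """

    dataset_id: str
    source: str
    pairs: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise ValueError("dataset_id must be non-empty")
        _check_pairs(self.pairs, path="pairs")

    def get_path(self, key_path: str) -> Any:
        """Return the value at a dotted key path, or None if absent."""
        node: Any = self.pairs
        for key in key_path.split("."):
            if not isinstance(node, Mapping) or key not in node:
                return None
            node = node[key]
        return node


def _check_pairs(node: Any, path: str, depth: int = 0) -> None:
    if depth > 64:
        raise ValueError(f"metadata nesting too deep at {path}")
    if isinstance(node, Mapping):
        for key, value in node.items():
            if not isinstance(key, str) or not key:
                raise ValueError(f"metadata keys must be non-empty strings at {path}")
            _check_pairs(value, f"{path}.{key}", depth + 1)


@dataclass(frozen=True)
class ProvenanceStep:
    step_name: str
    tool_version: str
    command: str
    input_checksums: dict[str, str]
    status: str = "ok"  # ok | warning | failed
    detail: str = ""


@dataclass(frozen=True)
class ProvenanceLog:
    """Append-only log of processing steps with input checksums."""

    steps: tuple[ProvenanceStep, ...] = ()

    def append(self, step: ProvenanceStep) -> "ProvenanceLog":
        return ProvenanceLog(self.steps + (step,))

    def __len__(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class SelectionCriteria:
    """Filters for choosing datasets from a metadata collection.

    All given criteria must hold simultaneously: taxonomy membership,
    include/exclude id lists, minimum sample count, and case-insensitive
    regex searches against string values at dotted key paths.
    """

    taxa: frozenset[int] | None = None
    include_ids: frozenset[str] | None = None
    exclude_ids: frozenset[str] | None = None
    patterns: tuple[tuple[str, str], ...] = ()  # (key_path, regex)
    min_samples: int | None = None

    def __post_init__(self) -> None:
        if self.include_ids and self.exclude_ids and self.include_ids & self.exclude_ids:
            raise ValueError("include_ids and exclude_ids must be disjoint")
        for key_path, pattern in self.patterns:
            try:
                re.compile(pattern)
            except re.error as exc:
                raise ValueError(f"invalid regex for key_path {key_path!r}: {pattern!r} ({exc})") from exc


def merge_metadata(auto: MetadataRecord, curated: MetadataRecord) -> MetadataRecord:
    """Merge a curated override into an automatic record; curated wins.

    Nested mappings merge key-wise at every depth; scalars and lists are
    replaced whole. The result carries ``_curation_applied: true``.
    """
    if auto.dataset_id != curated.dataset_id:
        raise ValueError(
            f"dataset_id mismatch: auto={auto.dataset_id!r} vs curated={curated.dataset_id!r}"
        )
    merged = _deep_merge(auto.pairs, curated.pairs)
    merged[CURATION_KEY] = True
    return replace(auto, pairs=merged)


def _deep_merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out: dict[str, Any] = copy.deepcopy(dict(base))
    for key, value in override.items():
        if key in out and isinstance(out[key], Mapping) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def _stringify(value: Any) -> str | None:
    """Canonical string view for regex search; None for unsearchable types."""
    if isinstance(value, str):
        return value
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        return repr(value)
    return None


def select_datasets(
    records: Iterable[MetadataRecord], criteria: SelectionCriteria
) -> list[str]:
    """Return dataset ids, in input order, passing every criterion.

    A pattern whose key path is missing (or non-scalar) simply fails; it is
    not an error, so screens like "germ-free" run over heterogeneous records.
    """
    records = list(records)
    if not records:
        raise ValueError("no metadata records to select from")
    compiled = [
        (kp, re.compile(rx, re.IGNORECASE)) for kp, rx in criteria.patterns
    ]
    selected: list[str] = []
    for rec in records:
        if criteria.exclude_ids and rec.dataset_id in criteria.exclude_ids:
            continue
        if criteria.include_ids is not None and rec.dataset_id not in criteria.include_ids:
            continue
        if criteria.taxa is not None:
            tax = rec.get_path("taxonomy_id")
            if tax is None or int(tax) not in criteria.taxa:
                continue
        if criteria.min_samples is not None:
            n = rec.get_path("n_samples")
            if n is None or int(n) < criteria.min_samples:
                continue
        ok = True
        for key_path, rx in compiled:
            text = _stringify(rec.get_path(key_path))
            if text is None or rx.search(text) is None:
                ok = False
                break
        if ok:
            selected.append(rec.dataset_id)
    return selected


def md5_file(path: str | Path) -> str:
    """Lowercase hex MD5 digest of a file's bytes (provenance, not security)."""
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def record_step(
    log: ProvenanceLog,
    step_name: str,
    command: str,
    input_paths: Iterable[str | Path],
    status: str = "ok",
    detail: str = "",
) -> ProvenanceLog:
    """Append a step with fresh digests of all inputs; value semantics.

    Unreadable inputs do not raise: a ``failed`` step is appended instead so
    the log records the attempt.
    """
    checksums: dict[str, str] = {}
    step_status, step_detail = status, detail
    for p in input_paths:
        try:
            checksums[str(p)] = md5_file(p)
        except OSError as exc:
            step_status, step_detail = "failed", f"unreadable input {p}: {exc}"
    step = ProvenanceStep(
        step_name=step_name,
        tool_version=TOOL_VERSION,
        command=command,
        input_checksums=checksums,
        status=step_status,
        detail=step_detail,
    )
    return log.append(step)


# --- JSON (de)serialization -------------------------------------------------

def _log_to_obj(log: ProvenanceLog) -> list[dict[str, Any]]:
    return [
        {
            "step_name": s.step_name,
            "tool_version": s.tool_version,
            "command": s.command,
            "input_checksums": dict(s.input_checksums),
            "status": s.status,
            "detail": s.detail,
        }
        for s in log.steps
    ]


def _log_from_obj(obj: list[dict[str, Any]]) -> ProvenanceLog:
    return ProvenanceLog(
        tuple(
            ProvenanceStep(
                step_name=d["step_name"],
                tool_version=d["tool_version"],
                command=d["command"],
                input_checksums=dict(d["input_checksums"]),
                status=d.get("status", "ok"),
                detail=d.get("detail", ""),
            )
            for d in obj
        )
    )


def write_metadata(
    record: MetadataRecord, path: str | Path, provenance: ProvenanceLog | None = None
) -> None:
    obj: dict[str, Any] = {
        "dataset_id": record.dataset_id,
        "source": record.source,
        "pairs": record.pairs,
    }
    if provenance is not None:
        obj["provenance"] = _log_to_obj(provenance)
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def read_metadata(path: str | Path) -> tuple[MetadataRecord, ProvenanceLog]:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    rec = MetadataRecord(
        dataset_id=obj["dataset_id"], source=obj.get("source", ""), pairs=obj.get("pairs", {})
    )
    log = _log_from_obj(obj.get("provenance", []))
    return rec, log
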