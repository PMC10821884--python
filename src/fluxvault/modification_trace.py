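"""Traceability core: modification files as layers over immutable models.

A modification file is an ordered YAML record of model-altering actions
(reaction knockouts and bound changes) with author, UTC date, root model and
an optional parent file.  Loading a child prepends the parent's entries
(recursively — ancestors first), which gives temporal traceability: every
intermediate state of a model is recoverable from authorship, dates and the
parent chain, without ever copying or rewriting the model file itself.

Conflicts between loaded files are resolved by *last-loaded-wins*: an entry
in the n-th loaded file targeting element ``e`` overrides every entry
targeting ``e`` from the n−1 previously loaded files (and, within one
expanded file, the later entry wins).

Saving a session records only what is genuinely new: the parent of the saved
file is the last file loaded, and entries from earlier loaded files are
written out explicitly only if the parent's expanded lineage does not already
contain them.  Loading the saved file alone therefore reconstructs the whole
session state — the storage-saving property of change-record files.

Entry identity for comparison and diffs is ``(target, operation, payload)``;
author and date are bookkeeping, not part of a modification's meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterable, Sequence

import yaml

from .errors import (
    ConflictError,
    ConsistencyError,
    FormatError,
    LineageError,
    MissingReferenceError,
    NotFoundError,
)

__all__ = [
    "OPERATIONS",
    "ModificationEntry",
    "ModificationFile",
    "EffectiveState",
    "parse_modification_file",
    "serialize_modification_file",
    "resolve_lineage",
    "resolve_effective_state",
    "diff_modification_files",
    "save_modification_file",
]

OPERATIONS = ("knockout", "set_bounds")


@dataclass(frozen=True)
class ModificationEntry:
    """One model-altering action targeting element ``e`` of the root model."""

    target: str
    operation: str
    payload: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.operation not in OPERATIONS:
            raise FormatError(f"unknown operation {self.operation!r}")
        if self.operation == "set_bounds":
            if self.payload is None or len(self.payload) != 2:
                raise FormatError("set_bounds requires a (lower, upper) payload")
            lo, hi = self.payload
            if lo > hi:
                raise FormatError(f"set_bounds payload {self.payload} has lower > upper")
        elif self.payload is not None:
            raise FormatError("knockout takes no payload")


@dataclass(frozen=True)
class ModificationFile:
    file_name: str
    author: str
    date: str  # ISO 8601 UTC
    root_model: str
    parent: str | None
    entries: tuple[ModificationEntry, ...]


@dataclass(frozen=True)
class Provenance:
    entry: ModificationEntry
    file_name: str
    load_index: int


class EffectiveState:
    """Winning entry per target after lineage expansion and override resolution."""

    def __init__(self) -> None:
        self._winners: dict[str, Provenance] = {}

    def record(self, entry: ModificationEntry, file_name: str, load_index: int) -> None:
        self._winners[entry.target] = Provenance(entry, file_name, load_index)

    def winner(self, target: str) -> Provenance:
        if target not in self._winners:
            raise NotFoundError(f"no effective modification targets {target!r}")
        return self._winners[target]

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(self._winners)

    def items(self):
        return self._winners.items()

    def entries(self) -> list[ModificationEntry]:
        return [p.entry for p in self._winners.values()]

    def as_mapping(self) -> dict[str, ModificationEntry]:
        return {t: p.entry for t, p in self._winners.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EffectiveState):
            return NotImplemented
        return self.as_mapping() == other.as_mapping()

    def __len__(self) -> int:
        return len(self._winners)


# -- YAML serialization ----------------------------------------------------

_MANDATORY = ("author", "date", "root_model", "modifications")


def _entry_to_yaml(entry: ModificationEntry) -> dict:
    doc: dict = {"target": entry.target, "operation": entry.operation}
    if entry.operation == "set_bounds":
        doc["bounds"] = [float(entry.payload[0]), float(entry.payload[1])]
    return doc


def _entry_from_yaml(doc: dict) -> ModificationEntry:
    if not isinstance(doc, dict) or "target" not in doc or "operation" not in doc:
        raise FormatError(f"malformed modification entry: {doc!r}")
    payload = None
    if "bounds" in doc:
        bounds = doc["bounds"]
        if not isinstance(bounds, (list, tuple)) or len(bounds) != 2:
            raise FormatError(f"malformed bounds payload: {bounds!r}")
        payload = (float(bounds[0]), float(bounds[1]))
    return ModificationEntry(str(doc["target"]), str(doc["operation"]), payload)


def parse_modification_file(yaml_bytes: bytes, file_name: str) -> ModificationFile:
    """Parse a YAML modification file; entry order is preserved."""
    try:
        doc = yaml.safe_load(yaml_bytes)
    except yaml.YAMLError as exc:
        raise FormatError(f"invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError("modification file must be a YAML mapping")
    missing = [k for k in _MANDATORY if k not in doc]
    if missing:
        raise FormatError(f"modification file missing mandatory fields: {missing}")
    entries = tuple(_entry_from_yaml(e) for e in (doc["modifications"] or []))
    parent = doc.get("parent")
    return ModificationFile(
        file_name=file_name,
        author=str(doc["author"]),
        date=str(doc["date"]),
        root_model=str(doc["root_model"]),
        parent=str(parent) if parent is not None else None,
        entries=entries,
    )


def serialize_modification_file(mod: ModificationFile) -> bytes:
    doc = {
        "author": mod.author,
        "date": mod.date,
        "root_model": mod.root_model,
        "parent": mod.parent,
        "modifications": [_entry_to_yaml(e) for e in mod.entries],
    }
    return yaml.safe_dump(doc, sort_keys=False).encode()


# -- lineage and override resolution --------------------------------------


def _load(store, file_name: str) -> ModificationFile:
    try:
        raw = store.get_modification_bytes(file_name)
    except NotFoundError as exc:
        raise MissingReferenceError(
            f"parent modification file {file_name!r} absent from store"
        ) from exc
    return parse_modification_file(raw, file_name)


def _dedup(entries: Iterable[ModificationEntry]) -> tuple[ModificationEntry, ...]:
    """Collapse exact duplicates, keeping first occurrence (order preserved)."""
    seen: set[ModificationEntry] = set()
    out = []
    for e in entries:
        if e not in seen:
            seen.add(e)
            out.append(e)
    return tuple(out)


def resolve_lineage(mod: ModificationFile, store) -> tuple[ModificationEntry, ...]:
    """Expand the parent chain: ancestors' entries first, then the file's own.

    Exact duplicate entries are collapsed.  A cyclic parent chain (including a
    file naming itself) raises :class:`LineageError`; a parent missing from
    the store raises :class:`MissingReferenceError`.
    """
    chain: list[ModificationFile] = []
    seen = {mod.file_name}
    current = mod
    while current.parent is not None:
        if current.parent in seen:
            raise LineageError(
                f"cyclic parent chain at {current.parent!r} (via {mod.file_name!r})"
            )
        seen.add(current.parent)
        current = _load(store, current.parent)
        chain.append(current)
    entries: list[ModificationEntry] = []
    for ancestor in reversed(chain):
        entries.extend(ancestor.entries)
    entries.extend(mod.entries)
    return _dedup(entries)


def resolve_effective_state(
    files_in_load_order: Sequence[ModificationFile], store
) -> EffectiveState:
    """Apply last-loaded-wins override resolution over lineage-expanded files.

    All files must share one root model.  For every target the entry from the
    highest load index wins; within one expanded file the later entry wins.
    """
    roots = {f.root_model for f in files_in_load_order}
    if len(roots) > 1:
        raise ConsistencyError(f"mixed root models in load sequence: {sorted(roots)}")
    state = EffectiveState()
    for n, mod in enumerate(files_in_load_order):
        for entry in resolve_lineage(mod, store):
            state.record(entry, mod.file_name, n)
    return state


def diff_modification_files(
    a: ModificationFile, b: ModificationFile, store
) -> tuple[list[ModificationEntry], list[ModificationEntry], list[ModificationEntry]]:
    """Differential traceability: partition lineage-expanded entry lists.

    Returns ``(only_in_a, common, only_in_b)``; partitions are disjoint and
    jointly exhaustive over the two expanded lists, in expansion order.
    """
    ea, eb = resolve_lineage(a, store), resolve_lineage(b, store)
    set_a, set_b = set(ea), set(eb)
    only_a = [e for e in ea if e not in set_b]
    common = [e for e in ea if e in set_b]
    only_b = [e for e in eb if e not in set_a]
    return only_a, common, only_b


def _now_utc() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def save_modification_file(
    loaded_files_in_order: Sequence[ModificationFile],
    session_entries: Sequence[ModificationEntry],
    author: str,
    store,
    file_name: str,
    root_model: str | None = None,
    date: str | None = None,
) -> ModificationFile:
    """Persist the session as a new modification file.

    The parent is the last file loaded (or none).  Entries from the n−1
    earlier loaded files that the parent's expanded lineage does not share are
    "new" and recorded explicitly, in load order, ahead of the session's own
    entries — so the saved file alone reproduces the session state.
    """
    if loaded_files_in_order:
        parent = loaded_files_in_order[-1]
        parent_name: str | None = parent.file_name
        root = parent.root_model
        parent_set = set(resolve_lineage(parent, store))
        carried = _dedup(
            e
            for f in loaded_files_in_order[:-1]
            for e in resolve_lineage(f, store)
            if e not in parent_set
        )
    else:
        parent_name, root, carried = None, root_model, ()
    if root is None:
        raise FormatError("root_model required when no files are loaded")
    mod = ModificationFile(
        file_name=file_name,
        author=author,
        date=date or _now_utc(),
        root_model=root,
        parent=parent_name,
        entries=tuple(carried) + tuple(session_entries),
    )
    store.add_modification_bytes(root, file_name, serialize_modification_file(mod))
    return mod
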