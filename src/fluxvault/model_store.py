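"""Registry of metabolic model files and cross-database ID translation tables.

Model files are the authoritative mathematical description of a network and
are never modified after registration: the store keeps the original SBML
bytes on disk, indexes parsed metadata in JSON, and guarantees that every
registered model has at least one view file (a default grid view is generated
at registration time).  User alterations live in separate modification files
(see :mod:`fluxvault.modification_trace`); simulations read the model through
the parsed record, never by rewriting it.

The store also holds local copies of identifier translation tables between
database namespaces (e.g. BiGG vs. MetaNetX), loaded from two-column TSV
files.  Lookups never touch a remote database.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import libsbml
import pandas as pd

from .errors import ConfigError, ConflictError, FormatError, NotFoundError

__all__ = [
    "Species",
    "Reaction",
    "ModelRecord",
    "IDTranslationTable",
    "ModelStore",
    "parse_sbml",
]


@dataclass(frozen=True)
class Species:
    species_id: str
    name: str
    compartment: str


@dataclass(frozen=True)
class Reaction:
    """One reaction: signed stoichiometry (negative = consumed) and flux bounds.

    Bounds are in the conventional FBA units of mmol gDW^-1 h^-1; ``subsystem``
    is optional pathway metadata (e.g. "Citric Acid Cycle") used by metadata
    grouping.
    """

    reaction_id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    subsystem: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise FormatError(
                f"reaction {self.reaction_id!r}: lower bound {self.lower_bound} "
                f"exceeds upper bound {self.upper_bound}"
            )


@dataclass(frozen=True)
class ModelRecord:
    """A parsed, immutable metabolic model."""

    model_id: str
    source_db: str
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    objective: Mapping[str, float]

    def __post_init__(self) -> None:
        rxn_ids = {r.reaction_id for r in self.reactions}
        sp_ids = {s.species_id for s in self.species}
        for rid in self.objective:
            if rid not in rxn_ids:
                raise FormatError(f"objective references unknown reaction {rid!r}")
        for r in self.reactions:
            unknown = set(r.stoichiometry) - sp_ids
            if unknown:
                raise FormatError(
                    f"reaction {r.reaction_id!r} references unknown species {sorted(unknown)}"
                )

    @property
    def species_ids(self) -> frozenset[str]:
        return frozenset(s.species_id for s in self.species)

    @property
    def reaction_ids(self) -> frozenset[str]:
        return frozenset(r.reaction_id for r in self.reactions)

    def reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.reaction_id == reaction_id:
                return r
        raise NotFoundError(f"reaction {reaction_id!r} not in model {self.model_id!r}")


def _read_subsystems(model: libsbml.Model) -> dict[str, str]:
    """Map reaction id -> group name from the SBML groups package, if present."""
    plug = model.getPlugin("groups")
    out: dict[str, str] = {}
    if plug is None:
        return out
    for i in range(plug.getNumGroups()):
        group = plug.getGroup(i)
        label = group.getName() or group.getId()
        for j in range(group.getNumMembers()):
            member = group.getMember(j)
            ref = member.getIdRef()
            if ref:
                out[ref] = label
    return out


def parse_sbml(model_bytes: bytes, model_id: str, source_db: str = "local") -> ModelRecord:
    """Parse an SBML Level 3 document carrying fbc bounds and an objective.

    Models without an active fbc objective or without bounds on every reaction
    are rejected: guessing an objective silently would change what a flux
    balance analysis computes.
    """
    doc = libsbml.readSBMLFromString(model_bytes.decode("utf-8", errors="replace"))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"SBML parse error: {first.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise FormatError("document contains no SBML model")

    species = tuple(
        Species(
            species_id=model.getSpecies(i).getId(),
            name=model.getSpecies(i).getName() or model.getSpecies(i).getId(),
            compartment=model.getSpecies(i).getCompartment() or "",
        )
        for i in range(model.getNumSpecies())
        if not model.getSpecies(i).getBoundaryCondition()
    )
    boundary = {
        model.getSpecies(i).getId()
        for i in range(model.getNumSpecies())
        if model.getSpecies(i).getBoundaryCondition()
    }

    subsystems = _read_subsystems(model)

    reactions = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        fbc = rxn.getPlugin("fbc")
        if fbc is None or not fbc.isSetLowerFluxBound() or not fbc.isSetUpperFluxBound():
            raise FormatError(
                f"reaction {rxn.getId()!r} lacks fbc flux bounds; boundless SBML rejected"
            )
        lb_param = model.getParameter(fbc.getLowerFluxBound())
        ub_param = model.getParameter(fbc.getUpperFluxBound())
        if lb_param is None or ub_param is None:
            raise FormatError(f"reaction {rxn.getId()!r}: bound parameter missing")
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        reactions.append(
            Reaction(
                reaction_id=rxn.getId(),
                stoichiometry=stoich,
                lower_bound=lb_param.getValue(),
                upper_bound=ub_param.getValue(),
                subsystem=subsystems.get(rxn.getId()),
                name=rxn.getName() or "",
            )
        )

    mplug = model.getPlugin("fbc")
    if mplug is None or mplug.getNumObjectives() == 0:
        raise FormatError("model has no fbc objective; refusing to guess one")
    active = mplug.getActiveObjective() or mplug.getObjective(0)
    # FBA maximizes c.v; a "minimize" objective is stored with flipped signs
    sense = -1.0 if active.getType() == "minimize" else 1.0
    objective: dict[str, float] = {}
    for i in range(active.getNumFluxObjectives()):
        fo = active.getFluxObjective(i)
        objective[fo.getReaction()] = sense * fo.getCoefficient()
    if not objective:
        raise FormatError("model objective is empty; refusing to guess one")

    return ModelRecord(
        model_id=model_id,
        source_db=source_db,
        species=species,
        reactions=tuple(reactions),
        objective=objective,
    )


@dataclass
class IDTranslationTable:
    """Direction-specific multi-map between two database namespaces."""

    from_db: str
    to_db: str
    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, vals in self.entries.items():
            if not vals:
                raise FormatError(f"translation entry {key!r} maps to an empty set")

    @classmethod
    def from_tsv(cls, path: str | Path, from_db: str, to_db: str) -> "IDTranslationTable":
        """Load a two-column (from_id, to_id) tab-separated file."""
        frame = pd.read_csv(path, sep="\t", header=None, names=["from_id", "to_id"],
                            dtype=str, comment="#").dropna()
        grouped = frame.groupby("from_id")["to_id"].agg(frozenset)
        return cls(from_db=from_db, to_db=to_db, entries=grouped.to_dict())

    def lookup(self, identifier: str) -> list[str]:
        if identifier not in self.entries:
            raise NotFoundError(
                f"identifier {identifier!r} has no {self.from_db}->{self.to_db} translation"
            )
        return sorted(self.entries[identifier])


class ModelStore:
    """Directory-backed registry of models, views, modification files and tables.

    Layout under ``root``::

        index.json          model_id -> {source_db, sbml file, views, mods}
        models/<id>.xml     original SBML bytes, written once, never rewritten
        views/<name>.cyjs   view files (CyJson)
        mods/<name>.yaml    modification files
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)
        (self.root / "models").mkdir(parents=True, exist_ok=True)
        (self.root / "views").mkdir(exist_ok=True)
        (self.root / "mods").mkdir(exist_ok=True)
        self._index_path = self.root / "index.json"
        if self._index_path.exists():
            self._index = json.loads(self._index_path.read_text())
        else:
            self._index = {}
        self._tables: dict[tuple[str, str], IDTranslationTable] = {}
        self._cache: dict[str, ModelRecord] = {}

    # -- persistence ------------------------------------------------------

    def _flush(self) -> None:
        self._index_path.write_text(json.dumps(self._index, indent=1, sort_keys=True))

    # -- models -----------------------------------------------------------

    def register_model(
        self, model_bytes: bytes, model_id: str, source_db: str = "local"
    ) -> ModelRecord:
        """Store an SBML model immutably and auto-generate its default view."""
        if model_id in self._index:
            raise ConflictError(f"model id {model_id!r} already registered")
        record = parse_sbml(model_bytes, model_id, source_db)
        sbml_path = self.root / "models" / f"{model_id}.xml"
        sbml_path.write_bytes(model_bytes)
        self._index[model_id] = {
            "source_db": source_db,
            "sbml": sbml_path.name,
            "views": [],
            "mods": [],
        }
        self._cache[model_id] = record
        # circular import kept local: view generation needs the record type
        from .view_layer import default_grid_layout, serialize_view

        default = default_grid_layout(record)
        self.add_view(model_id, default.view_name, serialize_view(default))
        self._flush()
        return record

    def get_model(self, model_id: str) -> ModelRecord:
        if model_id not in self._index:
            raise NotFoundError(f"model {model_id!r} not registered")
        if model_id not in self._cache:
            meta = self._index[model_id]
            raw = (self.root / "models" / meta["sbml"]).read_bytes()
            self._cache[model_id] = parse_sbml(raw, model_id, meta["source_db"])
        return self._cache[model_id]

    def get_model_bytes(self, model_id: str) -> bytes:
        if model_id not in self._index:
            raise NotFoundError(f"model {model_id!r} not registered")
        return (self.root / "models" / self._index[model_id]["sbml"]).read_bytes()

    def list_models(self) -> list[tuple[str, str, int, int]]:
        """(model_id, source_db, n_views, n_modification_files), sorted by id."""
        return [
            (mid, meta["source_db"], len(meta["views"]), len(meta["mods"]))
            for mid, meta in sorted(self._index.items())
        ]

    # -- views ------------------------------------------------------------

    def add_view(self, model_id: str, view_name: str, view_bytes: bytes) -> None:
        if model_id not in self._index:
            raise NotFoundError(f"model {model_id!r} not registered")
        path = self.root / "views" / f"{view_name}.cyjs"
        if view_name not in self._index[model_id]["views"]:
            self._index[model_id]["views"].append(view_name)
        path.write_bytes(view_bytes)
        self._flush()

    def list_views(self, model_id: str) -> list[str]:
        if model_id not in self._index:
            raise NotFoundError(f"model {model_id!r} not registered")
        return sorted(self._index[model_id]["views"])

    def get_view_bytes(self, view_name: str) -> bytes:
        path = self.root / "views" / f"{view_name}.cyjs"
        if not path.exists():
            raise NotFoundError(f"view {view_name!r} not in store")
        return path.read_bytes()

    # -- modification files (byte-level; semantics live in modification_trace)

    def add_modification_bytes(self, model_id: str, file_name: str, data: bytes) -> None:
        if model_id not in self._index:
            raise NotFoundError(f"model {model_id!r} not registered")
        if file_name in self._index[model_id]["mods"]:
            raise ConflictError(f"modification file {file_name!r} already exists")
        (self.root / "mods" / f"{file_name}.yaml").write_bytes(data)
        self._index[model_id]["mods"].append(file_name)
        self._flush()

    def list_modification_files(self, model_id: str) -> list[str]:
        if model_id not in self._index:
            raise NotFoundError(f"model {model_id!r} not registered")
        return sorted(self._index[model_id]["mods"])

    def get_modification_bytes(self, file_name: str) -> bytes:
        path = self.root / "mods" / f"{file_name}.yaml"
        if not path.exists():
            raise NotFoundError(f"modification file {file_name!r} not in store")
        return path.read_bytes()

    # -- translation tables -----------------------------------------------

    def register_translation_table(self, table: IDTranslationTable) -> None:
        self._tables[(table.from_db, table.to_db)] = table

    def load_translation_table(self, path: str | Path, from_db: str, to_db: str) -> None:
        self.register_translation_table(IDTranslationTable.from_tsv(path, from_db, to_db))

    def translate_id(self, identifier: str, from_db: str, to_db: str) -> list[str]:
        """Translate one identifier across namespaces; sorted, never empty."""
        key = (from_db, to_db)
        if key not in self._tables:
            raise ConfigError(f"no translation table registered for {from_db}->{to_db}")
        return self._tables[key].lookup(identifier)
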