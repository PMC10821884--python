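"""Deterministic toy-network generators: every module testable with no download.

Generated models are SBML Level 3 with fbc bounds and an objective, each
paired with a full-coverage CyJson view, and are feasible by construction
(the zero flux vector always satisfies the bounds).  Topologies:

``chain``     linear pathway: uptake exchange → internal conversions → outlet.
``parallel``  n alternative routes between one substrate/product pair —
              the minimal network in which a knockout visibly reroutes flux.
``branched``  one substrate split across n product branches, each with an
              outlet; only the first branch is rewarded by the objective.
``random``    a chain backbone plus seeded random shortcut reactions, some
              reversible.

The first species sits in compartment ``e`` (extracellular) and the rest in
``c`` (cytosol); internal reactions carry a subsystem label via the SBML
groups package while exchanges carry none — exercising both branches of
metadata grouping.  Same seed → byte-identical SBML and CyJson output.
"""

from __future__ import annotations

from dataclasses import dataclass

import libsbml
import numpy as np

from .errors import ConfigError
from .model_store import parse_sbml
from .modification_trace import (
    ModificationEntry,
    ModificationFile,
    serialize_modification_file,
)
from .view_layer import default_grid_layout, serialize_view

__all__ = ["FixtureSpec", "generate_toy_model", "generate_lineage_fixture"]

TOPOLOGIES = ("chain", "parallel", "branched", "random")
DEFAULT_BOUND_SCALE = 10.0  # uptake capacity, mmol gDW^-1 h^-1


@dataclass(frozen=True)
class FixtureSpec:
    topology: str = "chain"
    n_reactions: int = 3
    seed: int = 0
    bound_scale: float = DEFAULT_BOUND_SCALE


# -- SBML assembly ---------------------------------------------------------


def _new_document() -> tuple[libsbml.SBMLDocument, libsbml.Model]:
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    ns.addPackageNamespace("groups", 1)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    doc.setPackageRequired("groups", False)
    model = doc.createModel()
    model.setId("toy")
    mplug = model.getPlugin("fbc")
    mplug.setStrict(True)
    for cid in ("e", "c"):
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
        comp.setSize(1.0)
    return doc, model


def _add_species(model: libsbml.Model, sid: str, compartment: str) -> None:
    sp = model.createSpecies()
    sp.setId(sid)
    sp.setName(sid)
    sp.setCompartment(compartment)
    sp.setHasOnlySubstanceUnits(False)
    sp.setBoundaryCondition(False)
    sp.setConstant(False)
    sp.setInitialConcentration(0.0)


def _bound_param(model: libsbml.Model, pid: str, value: float) -> str:
    param = model.createParameter()
    param.setId(pid)
    param.setValue(value)
    param.setConstant(True)
    return pid


def _add_reaction(
    model: libsbml.Model,
    rid: str,
    stoich: dict[str, float],
    lb: float,
    ub: float,
) -> None:
    rxn = model.createReaction()
    rxn.setId(rid)
    rxn.setName(rid)
    rxn.setFast(False)
    rxn.setReversible(lb < 0)
    for sid, coeff in stoich.items():
        if coeff < 0:
            ref = rxn.createReactant()
            ref.setStoichiometry(-coeff)
        else:
            ref = rxn.createProduct()
            ref.setStoichiometry(coeff)
        ref.setSpecies(sid)
        ref.setConstant(True)
    fbc = rxn.getPlugin("fbc")
    fbc.setLowerFluxBound(_bound_param(model, f"{rid}_lb", lb))
    fbc.setUpperFluxBound(_bound_param(model, f"{rid}_ub", ub))


def _set_objective(model: libsbml.Model, reaction_id: str) -> None:
    mplug = model.getPlugin("fbc")
    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(reaction_id)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")


def _add_subsystem(model: libsbml.Model, name: str, reaction_ids: list[str]) -> None:
    if not reaction_ids:
        return
    gplug = model.getPlugin("groups")
    group = gplug.createGroup()
    group.setId(f"g_{name}")
    group.setName(name)
    group.setKind("partonomy")
    for rid in reaction_ids:
        member = group.createMember()
        member.setIdRef(rid)


def _topology(spec: FixtureSpec) -> tuple[dict, dict, str, list[str]]:
    """Return (species: id->compartment, reactions: id->(stoich, lb, ub),
    objective reaction, subsystem reaction ids)."""
    scale, n = spec.bound_scale, spec.n_reactions
    big = 1000.0
    if spec.topology == "chain":
        # EX_A (uptake of A, lb=-scale) -> R1..R_{n-2} conversions -> EX_out
        if n == 1:
            return {"A": "e"}, {"EX_A": ({"A": 1.0}, 0.0, scale)}, "EX_A", []
        n_int = n - 2
        species = {"A": "e"}
        species.update({f"M{i}": "c" for i in range(1, n_int + 1)})
        names = ["A"] + [f"M{i}" for i in range(1, n_int + 1)]
        reactions = {"EX_A": ({"A": -1.0}, -scale, 0.0)}
        internal = []
        for i in range(n_int):
            rid = f"R{i + 1}"
            reactions[rid] = ({names[i]: -1.0, names[i + 1]: 1.0}, 0.0, big)
            internal.append(rid)
        outlet = f"EX_{names[-1]}" if f"EX_{names[-1]}" not in reactions else "EX_out"
        reactions[outlet] = ({names[-1]: -1.0}, 0.0, big)
        objective = internal[0] if internal else outlet
        return species, reactions, objective, internal
    if spec.topology == "parallel":
        # n alternative routes A -> B
        species = {"A": "e", "B": "c"}
        reactions = {"EX_A": ({"A": -1.0}, -scale, 0.0)}
        internal = []
        for i in range(n):
            rid = f"R{i + 1}"
            reactions[rid] = ({"A": -1.0, "B": 1.0}, 0.0, big)
            internal.append(rid)
        reactions["EX_B"] = ({"B": -1.0}, 0.0, big)
        return species, reactions, "EX_B", internal
    if spec.topology == "branched":
        species = {"A": "e"}
        species.update({f"P{i}": "c" for i in range(1, n + 1)})
        reactions = {"EX_A": ({"A": -1.0}, -scale, 0.0)}
        internal = []
        for i in range(1, n + 1):
            rid = f"R{i}"
            reactions[rid] = ({"A": -1.0, f"P{i}": 1.0}, 0.0, big)
            internal.append(rid)
            reactions[f"EX_P{i}"] = ({f"P{i}": -1.0}, 0.0, big)
        return species, reactions, "EX_P1", internal
    if spec.topology == "random":
        rng = np.random.default_rng(spec.seed)
        n_int = max(1, n - 2)  # internal reactions; inlet/outlet make up the rest
        n_sp = max(2, n_int // 2 + 1)
        species = {"A": "e"}
        species.update({f"M{i}": "c" for i in range(1, n_sp)})
        names = list(species)
        reactions = {"EX_A": ({"A": -1.0}, -scale, 0.0)}
        internal = []
        # chain backbone guarantees a route from inlet to outlet
        for i in range(n_sp - 1):
            rid = f"R{i + 1}"
            reactions[rid] = ({names[i]: -1.0, names[i + 1]: 1.0}, 0.0, big)
            internal.append(rid)
        # seeded shortcuts, possibly reversible
        k = 0
        while len(internal) < n_int:
            i, j = sorted(rng.choice(n_sp, size=2, replace=False))
            rid = f"S{k + 1}"
            k += 1
            lb = -float(rng.integers(1, scale + 1)) if rng.random() < 0.5 else 0.0
            ub = float(rng.integers(1, scale + 1)) * 10
            reactions[rid] = ({names[i]: -1.0, names[j]: 1.0}, lb, ub)
            internal.append(rid)
        reactions[f"EX_{names[-1]}"] = ({names[-1]: -1.0}, 0.0, big)
        return species, reactions, f"EX_{names[-1]}", internal
    raise ConfigError(f"unsupported topology {spec.topology!r}")


def generate_toy_model(spec: FixtureSpec) -> tuple[bytes, bytes]:
    """Build (SBML bytes, CyJson bytes) for the given fixture spec."""
    if spec.n_reactions < 1:
        raise ConfigError("n_reactions must be >= 1")
    species, reactions, objective, internal = _topology(spec)
    doc, model = _new_document()
    model.setId(f"{spec.topology}{spec.n_reactions}")
    for sid, comp in species.items():
        _add_species(model, sid, comp)
    for rid, (stoich, lb, ub) in reactions.items():
        _add_reaction(model, rid, stoich, lb, ub)
    _set_objective(model, objective)
    _add_subsystem(model, f"{spec.topology}_core", internal)
    sbml_bytes = libsbml.writeSBMLToString(doc).encode()

    record = parse_sbml(sbml_bytes, model.getId())
    view = default_grid_layout(record)
    return sbml_bytes, serialize_view(view)


def synthetic_glucose_pts_model() -> tuple[bytes, bytes]:
    """Synthetic stand-in for a glucose-fed central-metabolism model.

    A deliberately tiny network reproducing the mechanism that pins the
    periplasmic glucose PTS transport flux at the uptake bound in genome-scale
    *E. coli* models: glucose enters at up to 10 mmol gDW⁻¹ h⁻¹, the PTS
    transporter converts it to G6P at yield 1, and an alternative transporter
    exists at lower yield, so the optimum routes everything through the PTS
    (flux exactly 10).  Knocking out ``GLCptspp`` reroutes all uptake through
    the alternative.  This is a synthetic fixture, not a curated model.
    """
    doc, model = _new_document()
    model.setId("glc_pts_synthetic")
    _add_species(model, "glc__D_e", "e")
    _add_species(model, "g6p_c", "c")
    _add_reaction(model, "EX_glc__D_e", {"glc__D_e": -1.0}, -10.0, 1000.0)
    _add_reaction(model, "GLCptspp", {"glc__D_e": -1.0, "g6p_c": 1.0}, 0.0, 1000.0)
    _add_reaction(model, "GLCt_alt", {"glc__D_e": -1.0, "g6p_c": 0.9}, 0.0, 1000.0)
    _add_reaction(model, "BIOMASS", {"g6p_c": -1.0}, 0.0, 1000.0)
    _set_objective(model, "BIOMASS")
    _add_subsystem(model, "Transport", ["GLCptspp", "GLCt_alt"])
    sbml_bytes = libsbml.writeSBMLToString(doc).encode()
    record = parse_sbml(sbml_bytes, model.getId())
    return sbml_bytes, serialize_view(default_grid_layout(record))


# -- modification lineages -------------------------------------------------


def generate_lineage_fixture(
    depth: int,
    entries_per_file: int,
    seed: int,
    store=None,
    root_model: str | None = None,
) -> list[ModificationFile]:
    """A parent chain of modification files over a generated chain model.

    Targets are drawn reproducibly and without replacement, so the deepest
    child's lineage expansion has exactly ``depth * entries_per_file``
    entries.  If ``store`` is given, the model (unless ``root_model`` names an
    already-registered one) and every file are persisted so lineage
    resolution can run against them.
    """
    if depth < 1:
        raise ConfigError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    n_targets = depth * entries_per_file
    spec = FixtureSpec(topology="chain", n_reactions=n_targets + 2, seed=seed)
    if root_model is None:
        sbml, _ = generate_toy_model(spec)
        root_model = f"lineage_root_{seed}"
        if store is not None:
            store.register_model(sbml, root_model)
        record = parse_sbml(sbml, root_model)
        targets = [r.reaction_id for r in record.reactions]
    elif store is not None:
        targets = sorted(store.get_model(root_model).reaction_ids)
    else:
        raise ConfigError("root_model without a store is ambiguous")
    picked = [targets[i] for i in rng.permutation(len(targets))[:n_targets]]

    files: list[ModificationFile] = []
    for d in range(depth):
        entries = []
        for e in range(entries_per_file):
            target = picked[d * entries_per_file + e]
            if rng.random() < 0.5:
                entries.append(ModificationEntry(target, "knockout"))
            else:
                lo = float(rng.integers(0, 5))
                hi = lo + float(rng.integers(0, 10))
                entries.append(ModificationEntry(target, "set_bounds", (lo, hi)))
        mod = ModificationFile(
            file_name=f"lineage_{seed}_d{d}",
            author="fixture",
            date=f"2024-01-{d + 1:02d}T00:00:00Z",
            root_model=root_model,
            parent=files[-1].file_name if files else None,
            entries=tuple(entries),
        )
        files.append(mod)
        if store is not None:
            store.add_modification_bytes(
                root_model, mod.file_name, serialize_modification_file(mod)
            )
    return files
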