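# fluxvault

A small server-side system for **centralized, traceable management of
constraint-based metabolic models**. It is aimed at groups who share and
iterate on genome-scale models (e.g. from BiGG or MetaNetX) from multiple
clients — visualization front-ends, notebooks, scripts — and need three
guarantees the usual "copy the SBML around" workflow does not give:

1. **Integrity** — a registered model file is immutable; every user action is
   recorded elsewhere.
2. **Traceability** — who changed what, when, and relative to which previous
   state, is always recoverable (temporal traceability), and any two states
   can be compared entry-by-entry (differential traceability).
3. **Remote simulation** — flux balance analysis runs on the server, next to
   the data, and clients receive a compact flux report.

## The data model

fluxvault manages three kinds of files:

- **Model files** (SBML Level 3 with the `fbc` package): the authoritative
  network — species, reactions with stoichiometry and flux bounds
  (mmol gDW⁻¹ h⁻¹), and an objective. Stored byte-for-byte, never rewritten.
- **View files** (Cytoscape CyJson, `.cyjs`): spatial projections — node
  positions and edge endpoints — of all or part of a model. Every model has
  at least one view (a deterministic grid layout is generated at registration
  if no curated view exists). Metabolite nodes group by compartment and
  reaction edges by subsystem for display.
- **Modification files** (YAML): ordered lists of model-altering entries
  (`knockout`, `set_bounds`) with `author`, `date`, `root_model` and an
  optional `parent`. Loading a child prepends its parent's entries
  recursively (ancestors first). Conflicts between loaded files resolve by
  **last-loaded-wins**: the entry from the highest load index targeting an
  element `e` overrides earlier ones. Saving a session writes a new file
  whose parent is the last file loaded, carrying over only the entries the
  parent does not already contain — so the saved file alone reproduces the
  whole session.

Cross-database identifier translation (e.g. BiGG ↔ MetaNetX) is served from
locally loaded two-column TSV tables; no remote database API is queried.

## The simulation

FBA in its standard form: with stoichiometric matrix **S** (species ×
reactions), flux vector **v** and objective coefficients **c**,

```
maximize cᵀv   subject to   S·v = 0,   lb ≤ v ≤ ub
```

solved as an explicit LP (HiGHS via SciPy). A knockout pins a reaction's
bounds to (0, 0); `set_bounds` replaces them. Modifications are applied from
the override-resolved effective state whether or not the targeted reactions
appear in any view. The engine also computes the render scalars a client
maps onto edges: a blue→red interpolation parameter
`t = (v − v_min)/(v_max − v_min)`, an edge width clamped to a user range,
and a particle emission rate proportional to |v|.

## The HTTP API

Queries follow the convention `/<queryName>[/<param>...]`:
`listModels`, `listViews/<model>`, `importViewFile/<view>`,
`listModificationFiles/<model>`, `saveModificationFile/<name>` (POST, YAML
body), `solveFBA/<model>[/<mod_file>...]` — extra path segments are
modification files and **URL order is load order** — plus `/commands`, the
server's self-description. A client unlocks a module by the *action-schema
handshake*: the module's required command set must be a subset of
`/commands`.

## Worked example

```pycon
>>> from fluxvault import *
>>> sbml, cyjs = generate_toy_model(FixtureSpec("chain", 3, 0))
>>> record = parse_sbml(sbml, "toy3")   # EX_A (−10,0) → R1 → EX_M1, max R1
>>> sol = solve_fba(build_problem(record))
>>> sol.status, sol.objective_value, sol.fluxes
('optimal', 10.0, {'EX_A': -10.0, 'R1': 10.0, 'EX_M1': 10.0})
```

The uptake bound of −10 on the exchange `EX_A` is the only active
constraint, so the pathway carries 10 mmol gDW⁻¹ h⁻¹ end to end and the
objective (the internal conversion `R1`) is 10. Knocking out `R1` via a
modification file drives the whole solution to zero:

```console
$ fluxvault --store s trace save --author alice --name ko1 \
      --root-model toy3 --entry "knockout:R1"
saved ko1 (parent: -, 1 entries)
$ fluxvault --store s fba toy3 --mods ko1
{
 "status": "optimal",
 "objective_value": 0.0,
 ...
}
```

On the synthetic glucose-transport fixture
(`synthetic_glucose_pts_model()`), the default uptake capacity of 10 pins
the PTS transporter flux at exactly 10; knocking it out reroutes all uptake
through the lower-yield alternative transporter (flux 10, objective drops
10 → 9). For the same experiment on the real genome-scale *E. coli* model,
download iJO1366 from BiGG and run `python scripts/ijo1366_demo.py
iJO1366.xml`.

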