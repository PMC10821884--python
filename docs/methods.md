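# Methods

## Scope and model of operation

fluxvault separates three concerns that are usually conflated in shared
modelling workflows: the *model* (the mathematics), the *view* (where things
sit on a canvas), and the *modifications* (what users changed). The store
holds each as its own file type and enforces one direction of dependency:
views and modifications reference models; nothing references back, and the
model bytes are write-once. All server state is a plain directory with a
JSON index — models are desk-scale local copies of database content, and a
filesystem plus index is auditable in a way an opaque database engine is
not.

## File formats and parsing

**Models** are SBML Level 3 with the flux-balance-constraints (`fbc`)
package; bounds come from the per-reaction `fbc` bound parameters and the
objective from the active `fbc` objective (a `minimize` objective is stored
with flipped signs so the engine always maximizes). Models without an
objective or with any unbounded reaction are rejected rather than repaired:
silently guessing either would change what an FBA means. Subsystem labels
are read from the SBML `groups` package, compartments from the species;
both are extracted once at registration so metadata grouping never
re-parses. Parsing goes through libsbml; species flagged as boundary
conditions are excluded from the mass-balance rows, matching the usual
exchange-reaction convention.

**Views** are Cytoscape `.cyjs`: nodes under `elements.nodes[].data.id` with
`position.x/y`, edges under `elements.edges[].data.source/.target`.
Coordinates are kept exactly as read (screen convention, y downward).
Validation is two-level and read-only: an edge endpoint missing from the
document is a structure error; a node or edge element that does not resolve
in the referenced model is a consistency error. A node's class is inferred
from membership (species → metabolite, reaction → reaction) since CyJson
mandates no class field. An edge whose document id is not a model element
falls back to its adjacent reaction node — curated exports rarely carry an
explicit `model_element_id`.

**Modification files** are YAML with fixed keys `author`, `date` (ISO 8601
UTC, so temporal ordering is lexicographic), `root_model`, `parent`
(optional), `modifications[]`. The operation vocabulary is `knockout` and
`set_bounds` — the two model-altering actions the system demonstrates — and
unknown operations are rejected at parse time so a newer client cannot
silently write entries an older server would misapply.

## Traceability semantics

*Lineage expansion* is ancestors-first concatenation, computed iteratively
with a visited set so a cyclic parent chain (including self-parenting) is
reported rather than looping. Exact duplicate entries are collapsed (first
occurrence kept): this makes diff partitions well-defined and is harmless to
override resolution, which only cares about the relative order of distinct
entries.

*Override resolution* applies each loaded file's expanded entries in load
order; per target, the last write wins — across files (higher load index)
and within a file (later entry). Entry identity everywhere is
`(target, operation, payload)`; author and date are bookkeeping, not
meaning, so re-recording the same change under a new author does not create
a spurious difference.

*Save* records the session with the last-loaded file as parent. Entries from
the earlier loaded files are written explicitly only when the parent's
expanded lineage does not already contain them. The resulting closure
property — loading just the saved file reproduces the session's effective
state — is what lets a chain of small change-records stand in for full model
copies; it is asserted directly in the tests and the acceptance script.

## The LP

The FBA problem is assembled as a dense `S` (species × reactions) with box
bounds and solved by HiGHS through `scipy.optimize.linprog`, with primal and
dual feasibility tolerances of 1e-9 (genome-scale problems need explicit
tolerances; the default is kept in one module constant). Reversible
reactions stay single signed columns — no splitting — so reported fluxes
carry sign. Infeasible and unbounded are *results*, not errors: the HTTP
layer returns them as status 200 with the LP status in the body, and only a
genuine solver failure raises.

Degeneracy: the optimal objective of an FBA is unique but the optimal flux
vector generally is not. The engine reports one optimal vertex; v_min/v_max
are extrema of that vertex and therefore solver-dependent, while the
objective value is not. Callers can restrict the extrema to the reactions of
a view (`restrict_to`), since a renderer colors only the mapped pathway.
Tests compare objective values only, against two independent oracles: the
cobrapy package and an exhaustive basic-solution (vertex) enumeration that
is written separately from the engine and only feasible for ≤ 8 reactions.

Visual scalars: color `t = (v − v_min)/(v_max − v_min)` clamped to [0, 1],
with t = 0.5 when the extrema coincide (a flat solution has no meaningful
gradient, so the midpoint of the color ramp is the least misleading choice);
width maps |v| linearly onto [w_min, w_max] with the largest magnitude at
w_max and is clamped; particle rate is `rate_per_flux · |v|`, zero on
zero-flux edges. `t` is invariant under affine rescaling of the flux vector
by construction.

## Synthetic data

The fixture generator emits SBML/fbc + CyJson pairs for four topologies
(chain, parallel, branched, random) with an uptake bound of 10
mmol gDW⁻¹ h⁻¹ — the conventional glucose uptake capacity of *E. coli*
growth simulations — and internal capacity 1000 (effectively unconstrained).
Every generated network has an exchange inlet and outlet, so non-trivial
optima exist, and all lower bounds are ≤ 0 ≤ upper bounds, so the zero
vector is always feasible. Same seed, same bytes. The 3-reaction chain is
hand-solvable (objective 10, v = (−10, 10, 10)); the 2-route parallel
network is the minimal case where a knockout visibly reroutes flux.

`synthetic_glucose_pts_model()` is a four-reaction stand-in for the
glucose-fed central metabolism of a genome-scale *E. coli* model: glucose
enters at up to 10, the PTS transporter converts it at yield 1, and an
alternative transporter exists at yield 0.9, so the optimum puts the full
uptake — flux exactly 10 — through the PTS, and knocking the PTS out
reroutes everything through the alternative (objective 10 → 9). It
reproduces the *mechanism* that pins the PTS flux at the uptake bound in the
real iJO1366 model; it does not reproduce genome-scale properties (realistic
flux extrema, thousands of alternate optima, cofactor coupling), so passing
tests on it say nothing quantitative about real networks beyond that
mechanism. The real-data experiment is available as
`scripts/ijo1366_demo.py` against a user-downloaded BiGG file. Lineage
fixtures draw modification targets without replacement from a generated
chain model, so a depth-d chain with k entries per file expands to exactly
d·k entries — which is what makes the concatenation oracle exact.

## HTTP layer

The request core is a transport-independent function from
`(method, path, body)` to `(status, media type, payload)`; a thin WSGI
adapter and the stdlib reference server host it. Reads are GET with path
parameters; `saveModificationFile` is a POST whose body is the YAML document
itself (a save cannot be a pure path). For `solveFBA`, modification files are
extra path segments and URL order is load order, making the override rule
reproducible over HTTP. `/commands` is generated from the route table, so
the handshake self-consistency property (the server unlocks its own
modules) holds by construction. No authentication: access control belongs to
the collaboration session layer, not the data server. Wire names of the
queries are a server decision declared via `/commands`, so clients adapt by
handshake rather than hard-coding.

## Problem sizes in the test suite

Unit and property tests run on fixtures of 3–8 reactions; the LP oracle
comparison covers 100 seeded fixtures across the four topologies, the
lineage oracle trees of depth ≤ 5, and the handshake 50 random schemas —
sizes at which the exhaustive oracles are exact and the whole suite stays
interactive. Known limitations: no flux-variability or parsimonious FBA, a
single view format (CyJson), a fixed two-operation modification vocabulary,
and directory-level (not cryptographic) integrity.
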