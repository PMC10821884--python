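"""Worked example on the genome-scale E. coli model iJO1366 (real data).

The model is not shipped with the package; download it once from the BiGG
models repository (http://bigg.ucsd.edu/models/iJO1366, SBML/fbc) and run

    python scripts/ijo1366_demo.py path/to/iJO1366.xml [--view map.cyjs]

The script registers the model in a throwaway store, solves the default FBA,
and prints the periplasmic D-glucose PTS transport flux (reaction GLCptspp —
expected to sit at the default glucose uptake capacity of 10
mmol gDW⁻¹ h⁻¹), the objective value, and the flux extrema (optionally
restricted to the reactions of a supplied CyJson map view; note the extrema
belong to one optimal vertex and are solver-dependent, unlike the objective).
It then knocks out the transporter and reports the rerouted solution.
"""

from __future__ import annotations

import argparse
import tempfile
from pathlib import Path

from fluxvault import (
    EffectiveState,
    ModelStore,
    ModificationEntry,
    build_problem,
    parse_view,
    solve_fba,
)

PTS_REACTION = "GLCptspp"  # periplasmic D-glucose PTS transport (BiGG id)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("sbml", type=Path, help="iJO1366 SBML (fbc) file")
    parser.add_argument("--view", type=Path, default=None,
                        help="CyJson map view; restricts reported flux extrema")
    args = parser.parse_args()

    with tempfile.TemporaryDirectory() as d:
        store = ModelStore(Path(d) / "store")
        record = store.register_model(args.sbml.read_bytes(), "iJO1366", "BiGG")
        print(f"registered iJO1366: {len(record.reactions)} reactions, "
              f"{len(record.species)} species")

        restrict = None
        if args.view is not None:
            view = parse_view(args.view.read_bytes(), record, args.view.stem)
            restrict = sorted({e.model_element_id for e in view.edges})
            print(f"map view covers {len(restrict)} reactions")

        sol = solve_fba(build_problem(record), restrict_to=restrict)
        print(f"status: {sol.status}")
        print(f"objective value: {sol.objective_value:.6f}")
        print(f"{PTS_REACTION} flux: {sol.fluxes.get(PTS_REACTION, float('nan')):.6f}")
        print(f"flux extrema (reported set): v_min={sol.v_min:.3f} v_max={sol.v_max:.3f}")

        state = EffectiveState()
        state.record(ModificationEntry(PTS_REACTION, "knockout"), "demo_ko", 0)
        ko = solve_fba(build_problem(record, state), restrict_to=restrict)
        print(f"after {PTS_REACTION} knockout: status={ko.status}, "
              f"objective={ko.objective_value:.6f}, "
              f"{PTS_REACTION} flux={ko.fluxes.get(PTS_REACTION, float('nan')):.6f}")


if __name__ == "__main__":
    main()
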