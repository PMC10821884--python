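"""Shared fixtures: a temp store, toy models, and an independent LP oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from fluxvault import FixtureSpec, ModelStore, generate_toy_model, parse_sbml


@pytest.fixture
def store(tmp_path):
    return ModelStore(tmp_path / "store")


@pytest.fixture
def chain3():
    """The 3-reaction chain fixture: EX_A (-10,0) -> R1 -> EX_M1; maximize R1."""
    sbml, cyjs = generate_toy_model(FixtureSpec("chain", 3, 0))
    return sbml, cyjs


@pytest.fixture
def chain3_record(chain3):
    return parse_sbml(chain3[0], "toy3")


@pytest.fixture
def chain3_registered(store, chain3):
    record = store.register_model(chain3[0], "toy3")
    return store, record


def brute_force_lp(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, c: np.ndarray):
    """Vertex enumeration oracle for max c.x s.t. S x = 0, lb <= x <= ub.

    Enumerates basic solutions: choose rank(S) basic variables with linearly
    independent columns, pin the rest at a bound, solve the square-ish system
    and keep feasible solutions.  Exponential — for tiny problems only.
    """
    n = S.shape[1]
    r = int(np.linalg.matrix_rank(S)) if S.size else 0
    best = None
    for basic in itertools.combinations(range(n), r):
        SF = S[:, basic]
        if np.linalg.matrix_rank(SF) < r:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for choice in itertools.product((0, 1), repeat=len(nonbasic)):
            x = np.zeros(n)
            for j, pick in zip(nonbasic, choice):
                x[j] = lb[j] if pick == 0 else ub[j]
            rhs = -S[:, nonbasic] @ x[nonbasic] if nonbasic else np.zeros(S.shape[0])
            xf, *_ = np.linalg.lstsq(SF, rhs, rcond=None)
            x[list(basic)] = xf
            if np.max(np.abs(S @ x)) > 1e-7:
                continue
            if np.any(x < lb - 1e-7) or np.any(x > ub + 1e-7):
                continue
            val = float(c @ x)
            if best is None or val > best:
                best = val
    return best
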