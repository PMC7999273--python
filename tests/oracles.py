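"""Independent oracles for the test suite.

Two routes that never touch the package's scipy/HiGHS solver path:

* :func:`vertex_optimum` — brute-force enumeration of the basic feasible
  solutions (vertices) of tiny flux polytopes ``{S v = 0, lb <= v <= ub}``,
  usable for networks of up to ~10 reactions;
* cobrapy with the GLPK backend (:func:`cobra_fba`, :func:`cobra_fva`,
  :func:`cobra_pfba_total_flux`) for the full toy network.
"""

from __future__ import annotations

import itertools

import numpy as np

from diazofba.io import to_cobra
from diazofba.model import MetabolicModel


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, tol: float = 1e-9):
    """All vertices of {S v = 0, lb <= v <= ub} by active-bound enumeration.

    A vertex of the polytope has at least ``n - rank(S)`` variables at a
    bound; every choice of fixed variables and bound sides is solved exactly
    and kept when feasible.  Exponential -- tiny systems only.
    """
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank
    vertices = []
    for fixed_idx in itertools.combinations(range(n), k):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        A = S[:, free_idx]
        for sides in itertools.product((0, 1), repeat=k):
            v_fixed = np.array(
                [lb[j] if s == 0 else ub[j] for j, s in zip(fixed_idx, sides)]
            )
            if not np.all(np.isfinite(v_fixed)):
                continue
            b = -S[:, fixed_idx] @ v_fixed
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            v = np.zeros(n)
            v[list(fixed_idx)] = v_fixed
            v[free_idx] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            vertices.append(v)
    return vertices


def vertex_optimum(model: MetabolicModel, objective: str, sense: str = "max") -> float:
    """LP optimum by vertex enumeration (bounded tiny models only)."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    verts = enumerate_vertices(S, lb, ub)
    assert verts, "vertex enumeration found no feasible vertex"
    j = model.reaction_index()[objective]
    values = [v[j] for v in verts]
    return max(values) if sense == "max" else min(values)


def vertex_range(model: MetabolicModel, target: str) -> tuple[float, float]:
    return (
        vertex_optimum(model, target, "min"),
        vertex_optimum(model, target, "max"),
    )


# ---------------------------------------------------------------------------
# cobrapy / GLPK


def _glpk(model: MetabolicModel):
    cm = to_cobra(model)
    cm.solver = "glpk"
    return cm


def cobra_fba(model: MetabolicModel) -> float:
    return float(_glpk(model).slim_optimize())


def cobra_fva(model: MetabolicModel, targets: list[str], fraction: float = 1.0):
    from cobra.flux_analysis import flux_variability_analysis

    df = flux_variability_analysis(_glpk(model), targets, fraction_of_optimum=fraction)
    return {r: (float(df.loc[r, "minimum"]), float(df.loc[r, "maximum"])) for r in targets}


def cobra_pfba_total_flux(model: MetabolicModel) -> float:
    from cobra.flux_analysis import pfba as cobra_pfba

    sol = cobra_pfba(_glpk(model))
    return float(sum(abs(v) for v in sol.fluxes))
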