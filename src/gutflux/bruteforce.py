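"""Reference FVA by exhaustive vertex enumeration.

A deliberately independent cross-check for the HiGHS-based engine in
:mod:`gutflux.core`: the flux polytope ``{v : S v = 0, G v <= h,
lb <= v <= ub}`` is parameterised on the null space of ``S`` and every vertex
is enumerated by solving each square subsystem of active inequality rows.
Because all variables carry finite bounds the polytope is bounded, so every
linear functional attains its extrema at a vertex and per-reaction flux
minima/maxima follow by inspection of the vertex list.

Exponential in the null-space dimension; intended for models with at most a
dozen reactions.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .core import MetabolicModel

__all__ = ["enumerate_vertices", "fva_bruteforce"]

_FEAS_TOL = 1e-7


def _dense_arrays(model: MetabolicModel):
    """Assemble S, bounds and coupling rows with its own loop (kept separate
    from :func:`gutflux.core.build_stoichiometric_matrix` on purpose)."""
    met_keys = sorted(model.metabolites)
    rxn_ids = sorted(model.reactions)
    row_of = {k: i for i, k in enumerate(met_keys)}
    S = np.zeros((len(met_keys), len(rxn_ids)))
    lb = np.empty(len(rxn_ids))
    ub = np.empty(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        for key, coef in rxn.stoichiometry.items():
            S[row_of[key], j] = coef
        lb[j], ub[j] = rxn.lb, rxn.ub
    rows, rhs = [], []
    col_of = {r: j for j, r in enumerate(rxn_ids)}
    for cpl in model.couplings:
        for sign in (1.0, -1.0):
            row = np.zeros(len(rxn_ids))
            row[col_of[cpl.coupled_reaction]] = sign
            row[col_of[cpl.anchor_reaction]] += -cpl.factor
            rows.append(row)
            rhs.append(cpl.slack)
    G = np.array(rows) if rows else np.zeros((0, len(rxn_ids)))
    h = np.array(rhs) if rhs else np.zeros(0)
    return S, G, h, lb, ub, rxn_ids


def enumerate_vertices(model: MetabolicModel) -> tuple[np.ndarray, list[str]]:
    """Return ``(V, reaction_ids)`` where each row of ``V`` is a vertex flux
    vector of the model's feasible polytope (empty array if infeasible).

    Requires finite bounds on every reaction.
    """
    S, G, h, lb, ub, rxn_ids = _dense_arrays(model)
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("vertex enumeration requires finite flux bounds")
    n = len(rxn_ids)

    # v = N z, with N an orthonormal null-space basis of S
    if S.size:
        _, sv, Vt = np.linalg.svd(S, full_matrices=True)
        rank = int(np.sum(sv > 1e-10 * max(1.0, sv[0] if sv.size else 1.0)))
        N = Vt[rank:].T  # n x d
    else:
        N = np.eye(n)
    d = N.shape[1]

    # inequalities in z: A z <= b  (bounds both ways, plus coupling rows)
    A = np.vstack([N, -N, G @ N])
    b = np.concatenate([ub, -lb, h])

    if d == 0:
        v = np.zeros(n)
        if np.all(A @ np.zeros(0) <= b + _FEAS_TOL):
            return v[None, :], rxn_ids
        return np.zeros((0, n)), rxn_ids

    scale = np.maximum(1.0, np.abs(b))
    verts = []
    for idx in combinations(range(A.shape[0]), d):
        Asub = A[list(idx)]
        bsub = b[list(idx)]
        if abs(np.linalg.det(Asub)) < 1e-10:
            continue
        z = np.linalg.solve(Asub, bsub)
        if np.all(A @ z <= b + _FEAS_TOL * scale):
            verts.append(N @ z)
    if not verts:
        return np.zeros((0, n)), rxn_ids
    return np.array(verts), rxn_ids


def fva_bruteforce(
    model: MetabolicModel, reaction_ids: list[str] | None = None
) -> dict[str, tuple[float, float]]:
    """Per-reaction flux min/max over the enumerated vertex set.

    Raises ``RuntimeError`` if the polytope is empty.
    """
    V, rxn_ids = enumerate_vertices(model)
    if V.shape[0] == 0:
        raise RuntimeError(f"model {model.id!r}: feasible polytope is empty")
    if reaction_ids is None:
        reaction_ids = rxn_ids
    col = {r: j for j, r in enumerate(rxn_ids)}
    return {
        rid: (float(V[:, col[rid]].min()), float(V[:, col[rid]].max()))
        for rid in reaction_ids
    }
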