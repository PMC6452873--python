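"""Independent brute-force oracles used to validate the LP engine and statistics.

These deliberately avoid the code paths they check: the LP oracle
enumerates basic feasible solutions (vertices) of the flux polytope by
direct linear algebra instead of calling a solver, the GPR oracle
evaluates rules through Python's own boolean operators, and the Fisher
oracle enumerates hypergeometric probabilities with scipy's pmf.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import hypergeom

from undermet.model import MetabolicModel


def stoich_matrix(model: MetabolicModel):
    mets = [m.id for m in model.metabolites]
    met_index = {m: i for i, m in enumerate(mets)}
    rxns = [r.id for r in model.reactions]
    S = np.zeros((len(mets), len(rxns)))
    for j, r in enumerate(model.reactions):
        for met, coef in r.stoichiometry.items():
            S[met_index[met], j] = coef
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return S, lb, ub, rxns


def enumerate_vertices(S, lb, ub, b=None, tol=1e-8):
    """All basic feasible solutions of {Sv = b, lb <= v <= ub}.

    Enumerates every choice of basis columns (size = rank S) with the
    nonbasic variables pinned at a bound; keeps solutions that satisfy the
    equalities and bounds.  Exponential — only for toy systems (n <= ~8).
    """
    m, n = S.shape
    if b is None:
        b = np.zeros(m)
    r = np.linalg.matrix_rank(S) if S.size else 0
    vertices = []
    for basis in itertools.combinations(range(n), r):
        B = S[:, basis]
        if np.linalg.matrix_rank(B) < r:
            continue
        nonbasis = [j for j in range(n) if j not in basis]
        for corners in itertools.product(*[(lb[j], ub[j]) for j in nonbasis]):
            rhs = b - (S[:, nonbasis] @ np.array(corners) if nonbasis else 0.0)
            xB, res, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            v = np.zeros(n)
            v[list(basis)] = xB
            v[nonbasis] = corners
            if np.max(np.abs(S @ v - b)) > tol:
                continue
            if (v < lb - tol).any() or (v > ub + tol).any():
                continue
            vertices.append(np.clip(v, lb, ub))
    return vertices


def oracle_fba_optimum(model: MetabolicModel):
    """Max biomass flux by vertex enumeration; None if infeasible."""
    S, lb, ub, rxns = stoich_matrix(model)
    j = rxns.index(model.objective_id)
    vertices = enumerate_vertices(S, lb, ub)
    if not vertices:
        return None
    return max(v[j] for v in vertices)


def oracle_optimal_vertices(model: MetabolicModel, tol=1e-8):
    """Vertices of the optimal face: objective pinned at the vertex optimum."""
    S, lb, ub, rxns = stoich_matrix(model)
    j = rxns.index(model.objective_id)
    opt = oracle_fba_optimum(model)
    if opt is None:
        return None, []
    row = np.zeros(S.shape[1])
    row[j] = 1.0
    S_aug = np.vstack([S, row])
    b_aug = np.concatenate([np.zeros(S.shape[0]), [opt]])
    return opt, enumerate_vertices(S_aug, lb, ub, b=b_aug, tol=tol)


def oracle_eval_gpr(expr: str, inactive: set[str]) -> bool:
    """Evaluate a GPR rule with Python's own and/or, as an independent check."""
    import re

    if not expr.strip():
        return True

    def sub(match):
        tok = match.group(0)
        if tok.lower() in ("and", "or"):
            return tok.lower()
        return str(tok not in inactive)

    py = re.sub(r"[A-Za-z0-9_.\-]+", sub, expr)
    return bool(eval(py))  # noqa: S307 - test oracle on generated input


def oracle_fisher_two_sided(a, b, c, d, rel_tol=1e-12):
    """Two-sided Fisher p by float hypergeometric enumeration (scipy pmf)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, c1, r1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    xs = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(xs, n, c1, r1)
    return float(pmf[pmf <= p_obs * (1 + rel_tol)].sum())
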