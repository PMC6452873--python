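"""Constraint-based LP analyses: FBA, parsimonious FBA, FVA, deletions, scans.

The steady-state assumption S·v = 0 with box bounds l ≤ v ≤ u defines the
flux polytope; every analysis here is a linear program over it.  The module
owns the LP construction (stoichiometric matrix assembly and the
forward/backward flux split used by pFBA) and delegates solving to scipy's
HiGHS bindings, so the backend is swappable without touching any analysis.

Conventions
-----------
* the objective is always the model's biomass reaction, maximized;
* fluxes smaller than ``ZERO_TOL`` (1e-9) in magnitude are reported as
  exactly 0 to stabilize downstream comparisons;
* pFBA fixes the objective via the inequality c·v ≥ fraction·opt rather
  than an equality, avoiding spurious infeasibility at tight tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, knock_out_genes

ZERO_TOL = 1e-9


class SolverError(RuntimeError):
    """The LP backend failed in a way that is not plain infeasibility."""


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def sum_abs_flux(self) -> float:
        return float(sum(abs(v) for v in self.fluxes.values()))


@dataclass
class FVAInterval:
    reaction_id: str
    min_flux: float
    max_flux: float
    fraction: float


@dataclass
class ScanResult:
    reaction_id: str
    points: list[tuple[float, float | None]]  # (fixed flux, optimum or None)


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

class _LP:
    """Stoichiometric LP data: S (m×n sparse), bounds, objective index."""

    def __init__(self, model: MetabolicModel):
        self.rxn_ids = [r.id for r in model.reactions]
        self.rxn_index = {rid: j for j, rid in enumerate(self.rxn_ids)}
        met_index = {m.id: i for i, m in enumerate(model.metabolites)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(model.reactions):
            for met, coef in rxn.stoichiometry.items():
                rows.append(met_index[met])
                cols.append(j)
                vals.append(coef)
        self.S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_index), len(self.rxn_ids))
        )
        self.lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        self.ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        self.obj_j = self.rxn_index[model.objective_id]

    @property
    def n(self) -> int:
        return len(self.rxn_ids)


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                  method="highs")
    status = _STATUS.get(res.status, "unknown")
    if status in ("iteration limit", "numerical", "unknown"):
        raise SolverError(f"LP backend failed: {res.message} (status {res.status})")
    return status, res


def _clean(x: float) -> float:
    return 0.0 if abs(x) < ZERO_TOL else float(x)


def fba(model: MetabolicModel) -> FluxSolution:
    """Maximize biomass flux subject to S·v = 0 and the flux bounds."""
    lp = _LP(model)
    c = np.zeros(lp.n)
    c[lp.obj_j] = -1.0  # linprog minimizes
    status, res = _solve(c, A_eq=lp.S, b_eq=np.zeros(lp.S.shape[0]),
                         bounds=np.column_stack([lp.lb, lp.ub]))
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"))
    fluxes = {rid: _clean(v) for rid, v in zip(lp.rxn_ids, res.x)}
    return FluxSolution(status="optimal",
                        objective_value=_clean(res.x[lp.obj_j]),
                        fluxes=fluxes)


def pfba(model: MetabolicModel, fraction: float = 1.0) -> FluxSolution:
    """Parsimonious FBA: minimize Σ|v| among fluxes at ≥ fraction of the optimum.

    Each flux is split into nonnegative forward and backward parts; the sum
    of parts is minimized subject to the original steady-state constraints
    plus c·v ≥ fraction·opt.  The returned objective value is the realized
    biomass flux (≥ fraction·opt by construction).
    """
    base = fba(model)
    if not base.optimal:
        raise SolverError(f"pFBA requires an optimal base FBA (got {base.status})")
    lp = _LP(model)
    n = lp.n
    # split: v = p - q, p,q >= 0
    p_lb, p_ub = np.maximum(lp.lb, 0.0), np.maximum(lp.ub, 0.0)
    q_lb, q_ub = np.maximum(-lp.ub, 0.0), np.maximum(-lp.lb, 0.0)
    bounds = np.column_stack([np.concatenate([p_lb, q_lb]),
                              np.concatenate([p_ub, q_ub])])
    A_eq = sparse.hstack([lp.S, -lp.S], format="csr")
    c_min = np.ones(2 * n)
    # objective floor: -(v_obj) <= -fraction*opt
    a = np.zeros(2 * n)
    a[lp.obj_j] = -1.0
    a[n + lp.obj_j] = 1.0
    A_ub = a.reshape(1, -1)
    b_ub = np.array([-fraction * base.objective_value])
    status, res = _solve(c_min, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
                         b_eq=np.zeros(lp.S.shape[0]), bounds=bounds)
    if status != "optimal":
        raise SolverError(
            f"pFBA flux-minimization LP was {status}; check fraction/tolerances"
        )
    v = res.x[:n] - res.x[n:]
    fluxes = {rid: _clean(x) for rid, x in zip(lp.rxn_ids, v)}
    return FluxSolution(status="optimal",
                        objective_value=_clean(v[lp.obj_j]),
                        fluxes=fluxes)


def fva(
    model: MetabolicModel,
    reaction_ids: list[str] | None = None,
    fraction: float = 0.99,
) -> list[FVAInterval]:
    """Flux variability analysis at a fraction of the optimal biomass flux.

    For each reaction, the minimum and maximum attainable flux subject to
    the steady state, the bounds, and biomass ≥ fraction·optimum.  The
    conventional cutoff in deletion-impact analyses is 99%.
    """
    base = fba(model)
    if not base.optimal:
        raise SolverError(f"FVA requires an optimal base FBA (got {base.status})")
    lp = _LP(model)
    if reaction_ids is None:
        reaction_ids = list(lp.rxn_ids)
    a = np.zeros(lp.n)
    a[lp.obj_j] = -1.0
    A_ub = a.reshape(1, -1)
    b_ub = np.array([-fraction * base.objective_value])
    bounds = np.column_stack([lp.lb, lp.ub])
    b_eq = np.zeros(lp.S.shape[0])
    out = []
    for rid in reaction_ids:
        j = lp.rxn_index[rid]  # KeyError for unknown reactions
        c = np.zeros(lp.n)
        lo_hi = []
        for sense in (1.0, -1.0):
            c[j] = sense
            status, res = _solve(c, A_ub=A_ub, b_ub=b_ub, A_eq=lp.S, b_eq=b_eq,
                                 bounds=bounds)
            if status != "optimal":
                raise SolverError(f"FVA subproblem for {rid} was {status}")
            lo_hi.append(_clean(res.x[j]))
            c[j] = 0.0
        vmin, vmax = lo_hi
        if vmin > vmax:  # numerical ties at the same vertex
            vmin, vmax = vmax, vmin
        out.append(FVAInterval(reaction_id=rid, min_flux=vmin, max_flux=vmax,
                               fraction=fraction))
    return out


def flux_scan(model: MetabolicModel, reaction_id: str, grid: list[float]) -> ScanResult:
    """Biomass optimum as a function of a reaction's flux fixed across a grid.

    Both bounds of the reaction are pinned to each grid value in turn and
    biomass re-optimized — the robustness/phenotypic-phase-plane style scan.
    Grid points outside the original bounds or otherwise infeasible are
    recorded as ``None``.  The input model is never mutated.
    """
    if not grid:
        raise ValueError("flux_scan grid must be non-empty")
    model.reaction(reaction_id)  # KeyError for unknown
    orig_lb = model.reaction(reaction_id).lower_bound
    orig_ub = model.reaction(reaction_id).upper_bound
    points: list[tuple[float, float | None]] = []
    work = model.copy()
    rxn = work.reaction(reaction_id)
    for v_star in sorted(grid):
        if v_star < orig_lb - ZERO_TOL or v_star > orig_ub + ZERO_TOL:
            points.append((float(v_star), None))
            continue
        rxn.lower_bound = rxn.upper_bound = float(v_star)
        sol = fba(work)
        points.append((float(v_star), sol.objective_value if sol.optimal else None))
    return ScanResult(reaction_id=reaction_id, points=points)


def single_gene_deletions(model: MetabolicModel, genes: list[str]) -> dict[str, float]:
    """FBA optimum after knocking out each gene individually.

    Returns gene id -> objective value (0.0 for an infeasible knockout, which
    for these models only happens when ATP-maintenance-style forced fluxes
    become unsatisfiable).
    """
    out = {}
    for gene in genes:
        sol = fba(knock_out_genes(model, {gene}))
        out[gene] = sol.objective_value if sol.optimal else 0.0
    return out


def group_deletion(model: MetabolicModel, genes: set[str]) -> FluxSolution:
    """FBA after knocking out all genes simultaneously (one combined GPR pass)."""
    return fba(knock_out_genes(model, set(genes)))
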