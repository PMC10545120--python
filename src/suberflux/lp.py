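"""Optimization core: FBA, pFBA, FVA, blocked reactions, MOMA, ratio couplings.

Every operation is an explicit mathematical program over a
:class:`~suberflux.model.MetabolicModel`:

* FBA:   max/min c'v  s.t.  S v = 0,  lb <= v <= ub
* pFBA:  fix the objective flux, then min sum(v+ + v-) with v = v+ - v-
* FVA:   per reaction, min and max v_j over the (objective-constrained) set
* MOMA:  min ||v - v_ref||^2 over the same polytope (QP, via OSQP)

Linear programs are solved with GLPK through optlang; the MOMA quadratic
program is handed to OSQP directly.  Flux-ratio constraints stored on the
model (``v_a * b - v_b * a = 0``) are enforced in every program.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from optlang.glpk_interface import Constraint, Model as LPModel, Objective, Variable

from .model import MetabolicModel, find_boundary_reactions

__all__ = [
    "FluxSolution",
    "FluxInterval",
    "RatioConstraint",
    "fba",
    "pfba",
    "fva",
    "blocked_reactions",
    "moma",
    "add_ratio_constraint",
    "SOLVER_TOL",
    "ASSERT_TOL",
]

SOLVER_TOL = 1e-9   # feasibility/optimality tolerance inside the solver
ASSERT_TOL = 1e-6   # tolerance for assertions on returned solutions


@dataclass(frozen=True)
class RatioConstraint:
    """Couple two fluxes: ``v_a * b == v_b * a`` (e.g. Vc:Vo = 3:1)."""

    rxn_a: str
    rxn_b: str
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ratio components must be positive")


@dataclass
class FluxSolution:
    fluxes: Dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded
    message: str = ""

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def total_absolute_flux(self) -> float:
        return sum(abs(v) for v in self.fluxes.values())


@dataclass(frozen=True)
class FluxInterval:
    reaction_id: str
    vmin: float
    vmax: float


def add_ratio_constraint(model: MetabolicModel, rc: RatioConstraint) -> MetabolicModel:
    """Return a copy of the model with the flux-ratio coupling installed."""
    for rid in (rc.rxn_a, rc.rxn_b):
        if rid not in model.reactions:
            raise KeyError(f"ratio constraint references unknown reaction {rid!r}")
    out = model.copy()
    out.ratio_constraints.append(rc)
    return out


# ------------------------------------------------------------------ LP build

class _LP:
    """A GLPK problem mirroring the model; reused across objective changes."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.rxn_ids = sorted(model.reactions)
        self.lp = LPModel(name=model.id)
        self.vars: Dict[str, Variable] = {}
        for rid in self.rxn_ids:
            rxn = model.reactions[rid]
            self.vars[rid] = Variable(rid, lb=rxn.lower_bound, ub=rxn.upper_bound)
        self.lp.add(list(self.vars.values()))

        constraints = []
        rows: Dict[str, Dict[Variable, float]] = {
            mid: {} for mid in model.metabolites
        }
        for rid in self.rxn_ids:
            for mid, coeff in model.reactions[rid].stoichiometry.items():
                rows[mid][self.vars[rid]] = coeff
        for mid in sorted(rows):
            if rows[mid]:
                constraints.append(Constraint(0, lb=0, ub=0, name=f"m_{mid}"))
        self.lp.add(constraints)
        self.lp.update()
        for con in constraints:
            mid = con.name[2:]
            con.set_linear_coefficients(rows[mid])
        for k, rc in enumerate(model.ratio_constraints):
            con = Constraint(0, lb=0, ub=0, name=f"ratio_{k}")
            self.lp.add([con])
            self.lp.update()
            coeffs: Dict[Variable, float] = {}
            coeffs[self.vars[rc.rxn_a]] = coeffs.get(self.vars[rc.rxn_a], 0.0) + rc.b
            coeffs[self.vars[rc.rxn_b]] = coeffs.get(self.vars[rc.rxn_b], 0.0) - rc.a
            con.set_linear_coefficients(coeffs)
        self._obj_coeffs: Dict[str, float] = {}

    def set_objective(self, coeffs: Mapping[str, float], direction: str) -> None:
        updates = {self.vars[rid]: 0.0 for rid in self._obj_coeffs}
        for rid, c in coeffs.items():
            updates[self.vars[rid]] = c
        self.lp.objective = Objective(0, direction=direction)
        self.lp.update()
        self.lp.objective.set_linear_coefficients(updates)
        self._obj_coeffs = dict(coeffs)

    def optimize(self) -> Tuple[str, float, Dict[str, float]]:
        status = self.lp.optimize()
        if status == "optimal":
            value = self.lp.objective.value
            # glpk can report "optimal" with a non-finite optimum when the
            # objective ray escapes through infinite bounds
            if value is None or not np.isfinite(value):
                return "unbounded", float("nan"), {}
            fluxes = {rid: self.vars[rid].primal for rid in self.rxn_ids}
            return "optimal", value, fluxes
        if status in ("unbounded", "infeasible or unbounded"):
            return "unbounded", float("nan"), {}
        return "infeasible", float("nan"), {}

    def set_bounds(self, rid: str, lb: float, ub: float) -> None:
        var = self.vars[rid]
        # avoid transient lb > ub states inside glpk
        if lb > var.ub:
            var.ub = ub
            var.lb = lb
        else:
            var.lb = lb
            var.ub = ub


def _objective_rxn(model: MetabolicModel, objective_rxn: Optional[str]) -> str:
    rid = objective_rxn or model.biomass_reaction_id
    if rid is None:
        raise ValueError("no objective reaction given and no biomass reaction set")
    if rid not in model.reactions:
        raise KeyError(f"objective reaction {rid!r} not in model")
    return rid


# ---------------------------------------------------------------------- FBA

def fba(
    model: MetabolicModel,
    objective_rxn: Optional[str] = None,
    sense: str = "max",
) -> FluxSolution:
    """Flux balance analysis: optimize one reaction's flux."""
    rid = _objective_rxn(model, objective_rxn)
    lp = _LP(model)
    lp.set_objective({rid: 1.0}, sense)
    status, value, fluxes = lp.optimize()
    if status == "unbounded":
        return FluxSolution(
            {}, float("nan"), "unbounded",
            message=f"objective {rid} is unbounded ({sense}); "
            f"check boundary reaction bounds",
        )
    if status != "optimal":
        return FluxSolution({}, float("nan"), "infeasible")
    return FluxSolution(fluxes, value, "optimal")


# --------------------------------------------------------------------- pFBA

def pfba(
    model: MetabolicModel,
    objective_rxn: Optional[str] = None,
    fix_value: Optional[float] = None,
    sense: str = "max",
) -> FluxSolution:
    """Parsimonious FBA: fix the objective, minimize total absolute flux.

    The objective reaction is fixed at its FBA optimum (or at ``fix_value``),
    then every flux is split as ``v = v+ - v-`` with nonnegative parts and
    ``sum(v+ + v-)`` is minimized.  ``objective_value`` reports the fixed
    objective flux; the parsimony score is available via
    :meth:`FluxSolution.total_absolute_flux`.
    """
    rid = _objective_rxn(model, objective_rxn)
    if fix_value is None:
        base = fba(model, rid, sense)
        if not base.ok:
            return base
        fix_value = base.objective_value

    rxn_ids = sorted(model.reactions)
    lp = LPModel(name=f"pfba_{model.id}")
    fwd: Dict[str, Variable] = {}
    rev: Dict[str, Variable] = {}
    for r in rxn_ids:
        rxn = model.reactions[r]
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if r == rid:
            lb = ub = fix_value
        fwd[r] = Variable(f"f_{r}", lb=max(lb, 0.0), ub=max(ub, 0.0))
        rev[r] = Variable(f"r_{r}", lb=max(-ub, 0.0), ub=max(-lb, 0.0))
    lp.add(list(fwd.values()) + list(rev.values()))

    rows: Dict[str, Dict[Variable, float]] = {m: {} for m in model.metabolites}
    for r in rxn_ids:
        for mid, coeff in model.reactions[r].stoichiometry.items():
            rows[mid][fwd[r]] = coeff
            rows[mid][rev[r]] = -coeff
    cons = [Constraint(0, lb=0, ub=0, name=f"m_{m}") for m in sorted(rows) if rows[m]]
    for k, rc in enumerate(model.ratio_constraints):
        cons.append(Constraint(0, lb=0, ub=0, name=f"ratio_{k}"))
    lp.add(cons)
    lp.update()
    for con in cons:
        if con.name.startswith("m_"):
            con.set_linear_coefficients(rows[con.name[2:]])
        else:
            rc = model.ratio_constraints[int(con.name[6:])]
            coeffs: Dict[Variable, float] = {}
            for var, sgn in ((fwd[rc.rxn_a], 1), (rev[rc.rxn_a], -1)):
                coeffs[var] = coeffs.get(var, 0.0) + sgn * rc.b
            for var, sgn in ((fwd[rc.rxn_b], 1), (rev[rc.rxn_b], -1)):
                coeffs[var] = coeffs.get(var, 0.0) - sgn * rc.a
            con.set_linear_coefficients(coeffs)

    lp.objective = Objective(0, direction="min")
    lp.update()
    lp.objective.set_linear_coefficients(
        {v: 1.0 for v in list(fwd.values()) + list(rev.values())}
    )
    status = lp.optimize()
    if status != "optimal":
        return FluxSolution({}, float("nan"), "infeasible")
    fluxes = {r: fwd[r].primal - rev[r].primal for r in rxn_ids}
    return FluxSolution(fluxes, fix_value, "optimal")


# ---------------------------------------------------------------------- FVA

def fva(
    model: MetabolicModel,
    reactions: Optional[Iterable[str]] = None,
    fraction_of_optimum: Optional[float] = None,
    objective_rxn: Optional[str] = None,
) -> List[FluxInterval]:
    """Flux variability analysis over a reaction subset (sorted-id order)."""
    rxn_ids = sorted(reactions) if reactions is not None else sorted(model.reactions)
    for r in rxn_ids:
        if r not in model.reactions:
            raise KeyError(f"FVA requested for unknown reaction {r!r}")
    lp = _LP(model)
    if fraction_of_optimum is not None:
        rid = _objective_rxn(model, objective_rxn)
        lp.set_objective({rid: 1.0}, "max")
        status, opt, _ = lp.optimize()
        if status != "optimal":
            raise RuntimeError(f"FVA: objective optimization is {status}")
        lp.set_bounds(
            rid, fraction_of_optimum * opt, model.reactions[rid].upper_bound
        )
    out: List[FluxInterval] = []
    for r in rxn_ids:
        bounds = []
        for sense in ("min", "max"):
            lp.set_objective({r: 1.0}, sense)
            status, value, _ = lp.optimize()
            if status == "unbounded":
                value = -np.inf if sense == "min" else np.inf
            elif status != "optimal":
                raise RuntimeError(f"FVA failed for reaction {r}: {status}")
            bounds.append(value)
        out.append(FluxInterval(r, bounds[0], bounds[1]))
    return out


def blocked_reactions(
    model: MetabolicModel,
    tol: float = SOLVER_TOL,
    open_boundaries: bool = True,
) -> set[str]:
    """Reactions unable to carry flux above ``tol`` in either direction.

    With ``open_boundaries`` (default) every boundary reaction is first
    relaxed to (-1000, 1000) so that blockage reflects network structure,
    not the current medium; pass False to use the model's own bounds.
    """
    work = model.copy()
    if open_boundaries:
        for rid in find_boundary_reactions(work):
            rxn = work.reactions[rid]
            rxn.lower_bound, rxn.upper_bound = -1000.0, 1000.0
    intervals = fva(work)
    return {
        iv.reaction_id
        for iv in intervals
        if abs(iv.vmin) < tol and abs(iv.vmax) < tol
    }


# --------------------------------------------------------------------- MOMA

def moma(
    model: MetabolicModel,
    reference: FluxSolution | Mapping[str, float],
    linear: bool = False,
) -> FluxSolution:
    """Minimization of metabolic adjustment against a reference flux state.

    Quadratic by default: ``min sum_j (v_j - v_j_ref)^2`` subject to the
    model's current constraints (solved with OSQP).  ``linear=True`` swaps
    in an L1 distance (an LP relaxation, not the canonical MOMA).
    Reference entries missing for a model reaction are treated as 0.
    """
    ref_map = reference.fluxes if isinstance(reference, FluxSolution) else reference
    rxn_ids = sorted(model.reactions)
    ref = np.array([ref_map.get(r, 0.0) for r in rxn_ids])

    if linear:
        return _moma_l1(model, rxn_ids, ref)

    n = len(rxn_ids)
    mets = sorted({m for r in model.reactions.values() for m in r.stoichiometry})
    midx = {m: i for i, m in enumerate(mets)}
    data, ri, ci = [], [], []
    for j, r in enumerate(rxn_ids):
        for mid, coeff in model.reactions[r].stoichiometry.items():
            data.append(coeff)
            ri.append(midx[mid])
            ci.append(j)
    n_ratio = len(model.ratio_constraints)
    for k, rc in enumerate(model.ratio_constraints):
        ja, jb = rxn_ids.index(rc.rxn_a), rxn_ids.index(rc.rxn_b)
        data += [rc.b, -rc.a]
        ri += [len(mets) + k, len(mets) + k]
        ci += [ja, jb]
    S = sp.csc_matrix((data, (ri, ci)), shape=(len(mets) + n_ratio, n))
    A = sp.vstack([S, sp.identity(n, format="csc")], format="csc")
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    lo = np.concatenate([np.zeros(S.shape[0]), lb])
    hi = np.concatenate([np.zeros(S.shape[0]), ub])

    import osqp

    prob = osqp.OSQP()
    prob.setup(
        P=sp.identity(n, format="csc") * 2.0,
        q=-2.0 * ref,
        A=A,
        l=lo,
        u=hi,
        verbose=False,
        eps_abs=1e-9,
        eps_rel=1e-9,
        max_iter=200_000,
        polishing=True,
    )
    res = prob.solve()
    status = res.info.status
    if "infeasible" in status:
        return FluxSolution({}, float("nan"), "infeasible")
    if "solved" not in status:
        return FluxSolution({}, float("nan"), "infeasible", message=status)
    v = np.asarray(res.x)
    fluxes = {r: float(v[j]) for j, r in enumerate(rxn_ids)}
    distance = float(np.sum((v - ref) ** 2))
    return FluxSolution(fluxes, distance, "optimal")


def _moma_l1(model: MetabolicModel, rxn_ids: List[str], ref: np.ndarray) -> FluxSolution:
    lp = _LP(model)
    aux = {r: Variable(f"d_{r}", lb=0) for r in rxn_ids}
    lp.lp.add(list(aux.values()))
    cons = []
    for j, r in enumerate(rxn_ids):
        cons.append(Constraint(0, lb=-ref[j], name=f"dp_{r}"))  # d >= v - ref
        cons.append(Constraint(0, lb=ref[j], name=f"dn_{r}"))   # d >= ref - v
    lp.lp.add(cons)
    lp.lp.update()
    for j, r in enumerate(rxn_ids):
        v = lp.vars[r]
        d = aux[r]
        lp.lp.constraints[f"dp_{r}"].set_linear_coefficients({d: 1.0, v: -1.0})
        lp.lp.constraints[f"dn_{r}"].set_linear_coefficients({d: 1.0, v: 1.0})
    lp.lp.objective = Objective(0, direction="min")
    lp.lp.update()
    lp.lp.objective.set_linear_coefficients({d: 1.0 for d in aux.values()})
    status = lp.lp.optimize()
    if status != "optimal":
        return FluxSolution({}, float("nan"), "infeasible")
    fluxes = {r: lp.vars[r].primal for r in rxn_ids}
    distance = lp.lp.objective.value
    return FluxSolution(fluxes, distance, "optimal")


# ------------------------------------------------------------------ checks

def steady_state_residual(model: MetabolicModel, sol: FluxSolution) -> float:
    """Max |S.v| over metabolites — should be < 1e-6 for optimal solutions."""
    worst = 0.0
    for mid in model.metabolites:
        total = 0.0
        for rid, rxn in model.reactions.items():
            coeff = rxn.stoichiometry.get(mid)
            if coeff:
                total += coeff * sol.fluxes.get(rid, 0.0)
        worst = max(worst, abs(total))
    return worst
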