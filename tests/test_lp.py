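"""Optimization core against independent oracles (scipy.linprog, closed forms)."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from suberflux.lp import (
    RatioConstraint,
    add_ratio_constraint,
    blocked_reactions,
    fba,
    fva,
    moma,
    pfba,
    steady_state_residual,
)
from suberflux.model import find_boundary_reactions

from conftest import build_model


def _linprog_oracle(model, objective_rxn, sense="max"):
    """Solve the FBA LP with scipy's HiGHS backend, independently."""
    rxn_ids = sorted(model.reactions)
    mets = sorted(model.metabolites)
    S = np.zeros((len(mets), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            S[mets.index(mid), j] = coeff
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_rxn)] = -1.0 if sense == "max" else 1.0
    bounds = [
        (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
        for r in rxn_ids
    ]
    res = linprog(c, A_eq=S, b_eq=np.zeros(len(mets)), bounds=bounds,
                  method="highs")
    assert res.status == 0
    return -res.fun if sense == "max" else res.fun


def test_fba_chain_bottleneck(chain_model):
    sol = fba(chain_model, "DM_B")
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
    assert steady_state_residual(chain_model, sol) < 1e-6


@pytest.mark.parametrize("sense", ["max", "min"])
def test_fba_matches_linprog_on_branched_toy(diamond_model, sense):
    for rid in ("RD", "DM_B"):
        ours = fba(diamond_model, rid, sense)
        oracle = _linprog_oracle(diamond_model, rid, sense)
        assert ours.objective_value == pytest.approx(oracle, abs=1e-7)


def test_fba_infeasible_status(chain_model):
    m = chain_model.copy()
    m.reactions["DM_B"].lower_bound = 50.0  # demands more than uptake allows
    assert fba(m, "DM_B").status == "infeasible"


def test_fba_unbounded_status(diamond_model):
    m = diamond_model.copy()
    m.reactions["EX_A"].lower_bound = -np.inf
    m.reactions["RD"].upper_bound = np.inf
    m.reactions["DM_B"].upper_bound = np.inf
    sol = fba(m, "DM_B")
    assert sol.status == "unbounded"
    assert "unbounded" in sol.message


def test_pfba_routes_through_short_arm(diamond_model):
    m = diamond_model.copy()
    m.reactions["DM_B"].lower_bound = m.reactions["DM_B"].upper_bound = 10.0
    sol = pfba(m, "DM_B")
    assert sol.ok
    assert sol.fluxes["RD"] == pytest.approx(10.0, abs=1e-6)
    assert sol.fluxes["RC1"] == pytest.approx(0.0, abs=1e-6)
    # direct routing: 10 (EX) + 10 (RD) + 10 (DM) vs 40 via the long arm
    assert sol.total_absolute_flux() == pytest.approx(30.0, abs=1e-6)


def test_pfba_zero_objective_all_closed(chain_model):
    m = chain_model.copy()
    m.reactions["EX_A"].lower_bound = 0.0
    sol = pfba(m, "DM_B", fix_value=0.0)
    assert sol.ok
    assert all(abs(v) < 1e-9 for v in sol.fluxes.values())


def test_pfba_objective_equals_fba_optimum(miniplant_model, presets):
    from suberflux.protocols import set_condition

    cond = set_condition(miniplant_model, presets["heterotrophic"])
    ref = fba(cond)
    par = pfba(cond)
    assert par.objective_value == pytest.approx(ref.objective_value, abs=1e-6)
    assert par.fluxes[cond.biomass_reaction_id] == pytest.approx(
        ref.objective_value, abs=1e-6
    )


def _vertex_enumeration_min_l1(model, fixed):
    """Brute-force minimal total |v| over polytope vertices of a tiny model.

    Enumerates all choices of active box bounds spanning the nullspace of
    the equality system; the L1 minimum over a polytope is attained at a
    vertex of the (split-variable) reformulation, which for these toys
    coincides with a vertex of the flux polytope.
    """
    rxn_ids = sorted(model.reactions)
    mets = sorted(model.metabolites)
    n = len(rxn_ids)
    S = np.zeros((len(mets) + len(fixed), n))
    d = np.zeros(len(mets) + len(fixed))
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            S[mets.index(mid), j] = coeff
    for k, (rid, value) in enumerate(sorted(fixed.items())):
        S[len(mets) + k, rxn_ids.index(rid)] = 1.0
        d[len(mets) + k] = value
    rank = np.linalg.matrix_rank(S)
    free = n - rank
    best = np.inf
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    choices = [(j, b) for j in range(n) for b in (lb[j], ub[j])]
    for combo in itertools.combinations(choices, free):
        A = np.vstack([S] + [np.eye(n)[j] for j, _ in combo]) if combo else S
        b = np.concatenate([d, [v for _, v in combo]]) if combo else d
        if np.linalg.matrix_rank(A) < n:
            continue
        v, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ v - b)) > 1e-8:
            continue
        if np.any(v < lb - 1e-8) or np.any(v > ub + 1e-8):
            continue
        best = min(best, np.sum(np.abs(v)))
    return best


def test_pfba_minimality_vs_vertex_enumeration(diamond_model):
    sol = pfba(diamond_model, "DM_B")
    oracle = _vertex_enumeration_min_l1(
        diamond_model, {"DM_B": sol.objective_value}
    )
    assert sol.total_absolute_flux() == pytest.approx(oracle, abs=1e-6)


def test_fva_diamond_arms_span(diamond_model):
    m = diamond_model.copy()
    m.reactions["DM_B"].lower_bound = m.reactions["DM_B"].upper_bound = 10.0
    intervals = {iv.reaction_id: iv for iv in fva(m, ["RD", "RC1"])}
    for rid in ("RD", "RC1"):
        assert intervals[rid].vmin == pytest.approx(0.0, abs=1e-7)
        assert intervals[rid].vmax == pytest.approx(10.0, abs=1e-7)


def test_fva_dead_end_reaction_zero():
    m = build_model(
        {"A": ("c", None), "D": ("c", None)},
        {
            "EX_A": ({"A": -1}, -10, 1000),
            "DEAD": ({"A": -1, "D": 1}, 0, 1000),
            "DM_A": ({"A": -1}, 0, 1000),
        },
    )
    (iv,) = fva(m, ["DEAD"])
    assert iv.vmin == iv.vmax == pytest.approx(0.0, abs=1e-9)


def test_fva_contains_fba_flux(miniplant_model, presets):
    from suberflux.protocols import set_condition

    cond = set_condition(miniplant_model, presets["photoautotrophic"])
    sol = fba(cond)
    subset = ["CBX", "SUCS", "RESP", "LIGHT", "EX_photon", "G3PDH"]
    for iv in fva(cond, subset, fraction_of_optimum=1.0):
        flux = sol.fluxes[iv.reaction_id]
        assert iv.vmin - 1e-6 <= flux <= iv.vmax + 1e-6
        assert iv.vmin <= iv.vmax + 1e-9


def test_blocked_reaction_simple():
    m = build_model(
        {"A": ("c", None), "D": ("c", None)},
        {
            "EX_A": ({"A": -1}, -10, 1000),
            "DEAD": ({"A": -1, "D": 1}, 0, 1000),
            "DM_A": ({"A": -1}, 0, 1000),
        },
    )
    assert blocked_reactions(m) == {"DEAD"}


def test_blocked_orphan_branch(miniplant_orphan):
    model, truth = miniplant_orphan
    assert blocked_reactions(model) == set(truth.orphan_reactions)


def test_blocked_none_on_clean_miniplant(miniplant_model):
    assert blocked_reactions(miniplant_model) == set()


def test_moma_identity_returns_reference(diamond_model):
    ref = pfba(diamond_model, "DM_B")
    sol = moma(diamond_model, ref)
    assert sol.ok
    assert sol.objective_value == pytest.approx(0.0, abs=1e-6)
    for rid, v in ref.fluxes.items():
        assert sol.fluxes[rid] == pytest.approx(v, abs=1e-5)


def test_moma_one_dimensional_projection():
    m = build_model(
        {"A": ("c", None)},
        {"EX_A": ({"A": 1}, 0, 10), "DM_A": ({"A": -1}, 0, 10)},
    )
    reference = {"EX_A": 10.0, "DM_A": 10.0}
    m.reactions["DM_A"].upper_bound = 4.0
    sol = moma(m, reference)
    # closed form: project (10,10) onto {v1=v2<=4} -> (4,4)
    assert sol.fluxes["DM_A"] == pytest.approx(4.0, abs=1e-6)
    assert sol.fluxes["EX_A"] == pytest.approx(4.0, abs=1e-6)
    assert sol.objective_value == pytest.approx(72.0, abs=1e-4)


def test_moma_infeasible_reported():
    m = build_model(
        {"A": ("c", None)},
        {"EX_A": ({"A": 1}, 5, 10), "DM_A": ({"A": -1}, 0, 2)},
    )
    assert moma(m, {"EX_A": 5.0, "DM_A": 5.0}).status == "infeasible"


def test_moma_l1_fallback_projection():
    m = build_model(
        {"A": ("c", None)},
        {"EX_A": ({"A": 1}, 0, 10), "DM_A": ({"A": -1}, 0, 4)},
    )
    sol = moma(m, {"EX_A": 10.0, "DM_A": 10.0}, linear=True)
    assert sol.ok
    assert sol.fluxes["DM_A"] == pytest.approx(4.0, abs=1e-6)


def test_ratio_constraint_splits_diamond(diamond_model):
    m = diamond_model.copy()
    m.reactions["DM_B"].lower_bound = m.reactions["DM_B"].upper_bound = 10.0
    m = add_ratio_constraint(m, RatioConstraint("RD", "RC1", 1, 1))
    sol = fba(m, "DM_B")
    assert sol.fluxes["RD"] == pytest.approx(5.0, abs=1e-6)
    assert sol.fluxes["RC1"] == pytest.approx(5.0, abs=1e-6)


def test_ratio_constraint_never_improves_objective(miniplant_model, presets):
    from suberflux.protocols import set_condition

    cond = set_condition(miniplant_model, presets["photoautotrophic"])
    base = fba(cond).objective_value
    constrained = add_ratio_constraint(cond, RatioConstraint("CBX", "OXY", 3, 1))
    sol = fba(constrained)
    assert sol.objective_value <= base + 1e-9
    assert sol.fluxes["CBX"] == pytest.approx(3 * sol.fluxes["OXY"], abs=1e-6)


def test_ratio_constraint_unknown_reaction(diamond_model):
    with pytest.raises(KeyError):
        add_ratio_constraint(diamond_model, RatioConstraint("RD", "NOPE", 3, 1))


def test_solutions_satisfy_steady_state(miniplant_model, presets):
    from suberflux.protocols import set_condition

    for name in ("photoautotrophic", "heterotrophic"):
        cond = set_condition(miniplant_model, presets[name])
        for sol in (fba(cond), pfba(cond)):
            assert steady_state_residual(cond, sol) < 1e-6
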