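"""FSEOF: flux scanning based on enforced objective flux, with MOMA ranking.

Workflow for finding overexpression targets that boost suberin output:

1. detach the target (e-Suberin) from the biomass reaction and give it a
   dedicated drain;
2. maximize the drain to get the theoretical maximum production, then
   enforce it from 5% to 95% of that maximum while maximizing growth,
   recording pFBA-resolved fluxes — reactions whose flux magnitude rises
   monotonically with enforced production (without changing sign) are
   candidates;
3. keep only candidates whose FVA interval at high enforcement is
   sign-consistent (vmin * vmax > 0);
4. simulate overexpression of each survivor at 1.2x its wild-type flux by
   MOMA against the wild-type (pFBA) reference, on the original model
   where suberin is still a biomass component, and rank by the phenotypic
   fraction  f_ph = (v_sub,OE / v_sub,WT) * (v_bio,OE / v_bio,WT).

Wild-type suberin production is measured as the production flux of the
target species (its biomass demand plus any drain), which is nonzero
whenever the wild type grows — keeping f_ph well-defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lp import FluxSolution, fba, fva, moma, pfba
from .model import MetabolicModel, Reaction

__all__ = [
    "FSEOFConfig",
    "FSEOFTrajectory",
    "OverexpressionResult",
    "detach_target_from_biomass",
    "ensure_target_drain",
    "fseof_scan",
    "fva_direction_filter",
    "overexpress_rank",
    "fseof_pipeline",
    "ranking_to_frame",
]

_TOL = 1e-6


def _default_levels() -> Tuple[float, ...]:
    return tuple(np.linspace(0.05, 0.95, 10))


@dataclass
class FSEOFConfig:
    target_species: str = "e_Suberin_bm"  # the suberin pseudo-metabolite
    target_rxn: str = "DM_eSuberin"       # dedicated drain id
    biomass_rxn: Optional[str] = None     # default: model's biomass reaction
    levels: Tuple[float, ...] = field(default_factory=_default_levels)
    oe_factor: float = 1.2

    def __post_init__(self) -> None:
        lv = tuple(self.levels)
        if not lv or any(not (0 < f < 1) for f in lv) or list(lv) != sorted(set(lv)):
            raise ValueError(
                "enforcement levels must be strictly increasing fractions in (0,1)"
            )
        self.levels = lv
        if self.oe_factor < 1:
            raise ValueError(
                "overexpression factor must be >= 1 (1.0 is the do-nothing "
                "control)"
            )


@dataclass
class FSEOFTrajectory:
    reaction_id: str
    fluxes: Tuple[float, ...]
    increasing: bool


@dataclass
class OverexpressionResult:
    reaction_id: str
    v_suberin_WT: float
    v_suberin_OE: float
    v_biomass_WT: float
    v_biomass_OE: float
    f_ph: float
    flag: str = ""


def _biomass_rxn(model: MetabolicModel, cfg: FSEOFConfig) -> str:
    rid = cfg.biomass_rxn or model.biomass_reaction_id
    if rid is None or rid not in model.reactions:
        raise ValueError("FSEOF requires a biomass reaction")
    return rid


def ensure_target_drain(model: MetabolicModel, cfg: FSEOFConfig) -> MetabolicModel:
    """Return a copy with an open drain for the target species."""
    if cfg.target_species not in model.metabolites:
        raise KeyError(f"target species {cfg.target_species!r} not in model")
    out = model.copy()
    if cfg.target_rxn not in out.reactions:
        out.add_reaction(
            Reaction(cfg.target_rxn, {cfg.target_species: -1.0}, 0.0, 1000.0,
                     name=f"{cfg.target_species} drain")
        )
    return out


def detach_target_from_biomass(
    model: MetabolicModel, cfg: FSEOFConfig
) -> MetabolicModel:
    """Remove the target from biomass and attach its dedicated drain.

    Idempotent; if the biomass reaction does not consume the target, the
    detachment is a no-op with a warning (the drain is still ensured).
    """
    out = ensure_target_drain(model, cfg)
    biomass = out.reactions[_biomass_rxn(out, cfg)]
    coeff = biomass.stoichiometry.get(cfg.target_species, 0.0)
    if coeff < 0:
        del biomass.stoichiometry[cfg.target_species]
    else:
        warnings.warn(
            f"biomass reaction does not consume {cfg.target_species}; "
            "nothing to detach"
        )
    return out


def production_flux(
    model: MetabolicModel, sol: FluxSolution, species: str
) -> float:
    """Total production rate of a species in a solution (mmol.gDW^-1.h^-1)."""
    total = 0.0
    for rid, rxn in model.reactions.items():
        coeff = rxn.stoichiometry.get(species)
        if coeff:
            contrib = coeff * sol.fluxes.get(rid, 0.0)
            if contrib > 0:
                total += contrib
    return total


def fseof_scan(
    model: MetabolicModel, cfg: FSEOFConfig
) -> List[FSEOFTrajectory]:
    """Enforce target production stepwise; return monotone candidates.

    The model should already have the target detached from biomass (see
    :func:`detach_target_from_biomass`).  Fluxes at each level are
    pFBA-resolved to kill degenerate-optimum noise.
    """
    biomass_id = _biomass_rxn(model, cfg)
    if cfg.target_rxn not in model.reactions:
        raise KeyError(f"target drain {cfg.target_rxn!r} missing; detach first")
    vmax_sol = fba(model, cfg.target_rxn)
    if not vmax_sol.ok or vmax_sol.objective_value <= _TOL:
        raise ValueError("target not producible: maximum production is zero")
    vmax = vmax_sol.objective_value

    per_level: List[Dict[str, float]] = []
    for f in cfg.levels:
        enforced = model.copy()
        rxn = enforced.reactions[cfg.target_rxn]
        rxn.lower_bound = rxn.upper_bound = f * vmax
        sol = pfba(enforced, biomass_id)
        if not sol.ok:
            raise RuntimeError(f"enforcement level {f:.2f} infeasible")
        per_level.append(sol.fluxes)

    out: List[FSEOFTrajectory] = []
    excluded = {biomass_id, cfg.target_rxn}
    for rid in sorted(model.reactions):
        if rid in excluded:
            continue
        traj = tuple(lv[rid] for lv in per_level)
        mags = [abs(v) for v in traj]
        increasing = all(
            m2 - m1 > _TOL for m1, m2 in zip(mags, mags[1:])
        ) and not any(
            v1 * v2 < -_TOL * _TOL for v1, v2 in zip(traj, traj[1:])
        )
        if increasing:
            out.append(FSEOFTrajectory(rid, traj, True))
    return out


def fva_direction_filter(
    model: MetabolicModel,
    candidates: Sequence[FSEOFTrajectory],
    cfg: FSEOFConfig,
) -> List[FSEOFTrajectory]:
    """Keep candidates whose flux direction is certain at high enforcement.

    With the target enforced at the top scan level, a candidate survives
    iff its FVA interval excludes zero (vmin * vmax > 0).
    """
    if not candidates:
        return []
    vmax_sol = fba(model, cfg.target_rxn)
    if not vmax_sol.ok:
        raise RuntimeError("target maximization failed in FVA filter")
    enforced = model.copy()
    rxn = enforced.reactions[cfg.target_rxn]
    rxn.lower_bound = rxn.upper_bound = cfg.levels[-1] * vmax_sol.objective_value
    intervals = fva(enforced, [c.reaction_id for c in candidates])
    certain = {
        iv.reaction_id
        for iv in intervals
        if iv.vmin > _TOL or iv.vmax < -_TOL
    }
    return [c for c in candidates if c.reaction_id in certain]


def overexpress_rank(
    model: MetabolicModel,
    filtered: Sequence[FSEOFTrajectory],
    cfg: FSEOFConfig,
) -> List[OverexpressionResult]:
    """MOMA-simulate 1.2x overexpression of each candidate and rank by f_ph.

    ``model`` is the wild-type model (target still in biomass, drain
    open).  Candidates with zero wild-type flux are skipped: scaling zero
    is not an overexpression.
    """
    biomass_id = _biomass_rxn(model, cfg)
    wt_model = ensure_target_drain(model, cfg)
    wt = pfba(wt_model, biomass_id)
    if not wt.ok:
        raise RuntimeError("wild-type pFBA failed")
    v_sub_wt = production_flux(wt_model, wt, cfg.target_species)
    v_bio_wt = wt.fluxes[biomass_id]
    if v_sub_wt <= _TOL or v_bio_wt <= _TOL:
        raise ValueError(
            "wild type produces no target/biomass; f_ph is undefined"
        )

    results: List[OverexpressionResult] = []
    for cand in sorted(filtered, key=lambda c: c.reaction_id):
        rid = cand.reaction_id
        v_wt = wt.fluxes[rid]
        if abs(v_wt) <= _TOL:
            results.append(
                OverexpressionResult(rid, v_sub_wt, float("nan"), v_bio_wt,
                                     float("nan"), 0.0,
                                     flag="skipped: zero wild-type flux")
            )
            continue
        oe_model = wt_model.copy()
        rxn = oe_model.reactions[rid]
        rxn.lower_bound = rxn.upper_bound = cfg.oe_factor * v_wt
        sol = moma(oe_model, wt)
        if not sol.ok:
            results.append(
                OverexpressionResult(rid, v_sub_wt, 0.0, v_bio_wt, 0.0, 0.0,
                                     flag="MOMA infeasible")
            )
            continue
        v_sub_oe = production_flux(oe_model, sol, cfg.target_species)
        v_bio_oe = sol.fluxes[biomass_id]
        f_ph = (v_sub_oe / v_sub_wt) * (v_bio_oe / v_bio_wt)
        results.append(
            OverexpressionResult(rid, v_sub_wt, v_sub_oe, v_bio_wt, v_bio_oe,
                                 f_ph)
        )
    results.sort(key=lambda r: (-r.f_ph, r.reaction_id))
    return results


def fseof_pipeline(
    model: MetabolicModel, cfg: FSEOFConfig
) -> Tuple[List[FSEOFTrajectory], List[FSEOFTrajectory], List[OverexpressionResult]]:
    """Scan, filter and rank in one deterministic pass."""
    detached = detach_target_from_biomass(model, cfg)
    candidates = fseof_scan(detached, cfg)
    filtered = fva_direction_filter(detached, candidates, cfg)
    ranking = overexpress_rank(model, filtered, cfg)
    return candidates, filtered, ranking


def ranking_to_frame(
    model: MetabolicModel, ranking: Sequence[OverexpressionResult]
) -> pd.DataFrame:
    """Tabulate a ranking: rank, reaction, enzyme name, pathway, f_ph."""
    rows = []
    for k, res in enumerate(ranking, start=1):
        rxn = model.reactions.get(res.reaction_id)
        rows.append(
            {
                "rank": k,
                "reaction_id": res.reaction_id,
                "enzyme": rxn.name if rxn else "",
                "pathway": rxn.pathway if rxn else "",
                "f_ph": res.f_ph,
                "flag": res.flag,
            }
        )
    return pd.DataFrame(rows)
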