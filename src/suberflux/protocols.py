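"""Environmental presets, photosynthesis protocols and the validation battery.

A :class:`ConditionPreset` names a trophic regime (photoautotrophic:
photons + CO2 as sole energy/carbon sources; heterotrophic: sucrose;
photorespiratory: photoautotrophic plus a Rubisco carboxylation:
oxygenation flux-ratio coupling, canonically 3:1).  Exchange identifiers
are model-specific and supplied per preset.

The canonical phototrophic protocol fixes biomass formation at
0.11 h^-1 and minimizes photon uptake; the alternative fixes photon
uptake at 100 mmol.gDW^-1.h^-1 and maximizes growth.  Photosynthetic
efficiency indices are computed from exchange fluxes: quantum yield =
CO2 fixed per photon absorbed; assimilation quotient = CO2 fixed per O2
evolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .lp import FluxSolution, RatioConstraint, fba, pfba
from .model import MetabolicModel, find_boundary_reactions

__all__ = [
    "ConditionPreset",
    "PhotosyntheticIndices",
    "ProbeResult",
    "ValidationReport",
    "set_condition",
    "photosynthetic_indices",
    "phototrophic_protocol",
    "vcvo_scan",
    "validate_model",
    "biomass_precursor_gaps",
    "BIOMASS_FIX",
    "PHOTON_FIX",
]

BIOMASS_FIX = 0.11   # h^-1, canonical fixed growth rate (approach 1)
PHOTON_FIX = 100.0   # mmol.gDW^-1.h^-1 fixed photon uptake (approach 2)
_TOL = 1e-6


@dataclass
class ConditionPreset:
    """Named environment: which uptakes are open, and how wide."""

    name: str
    open_uptakes: Dict[str, float]  # exchange id -> max uptake (positive)
    nitrogen_source: str = "nitrate"
    ratio_constraints: List[RatioConstraint] = field(default_factory=list)


@dataclass
class PhotosyntheticIndices:
    quantum_yield: Optional[float]          # mmol CO2 / mmol photon
    assimilation_quotient: Optional[float]  # mmol CO2 / mmol O2


def set_condition(model: MetabolicModel, preset: ConditionPreset) -> MetabolicModel:
    """Close all boundary uptakes except the preset's; install ratio couplings."""
    out = model.copy()
    boundary = set(find_boundary_reactions(out))
    missing = [rid for rid in preset.open_uptakes if rid not in out.reactions]
    if missing:
        raise KeyError(f"preset {preset.name}: missing exchanges {missing}")
    for rid in boundary:
        rxn = out.reactions[rid]
        rxn.lower_bound = 0.0
        rxn.upper_bound = 1000.0
    for rid, bound in preset.open_uptakes.items():
        out.reactions[rid].lower_bound = -abs(bound)
    for rc in preset.ratio_constraints:
        out.ratio_constraints.append(rc)
    return out


def photosynthetic_indices(
    sol: FluxSolution, ids: Mapping[str, str]
) -> PhotosyntheticIndices:
    """Efficiency indices from a solution's exchange fluxes.

    ``ids`` maps ``photon``, ``co2`` and ``o2`` to the model's exchange
    reaction ids.  Uptake is the negative exchange direction; O2 evolution
    the positive one.  Zero denominators yield None (undefined), never 0.
    """
    co2_fixed = -sol.fluxes.get(ids["co2"], 0.0)
    photon_uptake = -sol.fluxes.get(ids["photon"], 0.0)
    o2_evolved = sol.fluxes.get(ids["o2"], 0.0)
    qy = co2_fixed / photon_uptake if photon_uptake > _TOL else None
    aq = co2_fixed / o2_evolved if o2_evolved > _TOL else None
    return PhotosyntheticIndices(qy, aq)


def phototrophic_protocol(
    model: MetabolicModel,
    preset: ConditionPreset,
    photon_exchange: str,
    approach: str = "fix_biomass",
    biomass_fix: float = BIOMASS_FIX,
    photon_fix: float = PHOTON_FIX,
) -> FluxSolution:
    """Run the canonical phototrophic pFBA protocol.

    ``fix_biomass``: growth fixed (default 0.11 h^-1), photon uptake
    minimized.  ``fix_photon``: photon uptake fixed (default 100),
    growth maximized.  Fluxes are pFBA-resolved either way.
    """
    cond = set_condition(model, preset)
    if model.biomass_reaction_id is None:
        raise ValueError("protocol requires a biomass reaction")
    if approach == "fix_biomass":
        rxn = cond.reactions[model.biomass_reaction_id]
        rxn.lower_bound = rxn.upper_bound = biomass_fix
        # minimal uptake = exchange flux closest to zero from below
        return pfba(cond, photon_exchange, sense="max")
    if approach == "fix_photon":
        rxn = cond.reactions[photon_exchange]
        rxn.lower_bound = rxn.upper_bound = -photon_fix
        return pfba(cond, model.biomass_reaction_id, sense="max")
    raise ValueError(f"unknown approach {approach!r}")


def vcvo_scan(
    model: MetabolicModel,
    ratios: Sequence[Tuple[float, float]],
    preset: ConditionPreset,
    carboxylation: str,
    oxygenation: str,
    ids: Mapping[str, str],
    approach: str = "fix_biomass",
    biomass_fix: float = BIOMASS_FIX,
) -> pd.DataFrame:
    """Sweep Rubisco Vc:Vo ratios, reporting growth and efficiency indices."""
    rows = []
    for a, b in ratios:
        if a <= 0 or b <= 0:
            raise ValueError("Vc:Vo ratio components must be positive")
        scan_preset = ConditionPreset(
            name=f"{preset.name}_vcvo_{a}_{b}",
            open_uptakes=dict(preset.open_uptakes),
            nitrogen_source=preset.nitrogen_source,
            ratio_constraints=list(preset.ratio_constraints)
            + [RatioConstraint(carboxylation, oxygenation, a, b)],
        )
        try:
            sol = phototrophic_protocol(
                model, scan_preset, ids["photon"], approach=approach,
                biomass_fix=biomass_fix,
            )
        except Exception:
            sol = FluxSolution({}, float("nan"), "infeasible")
        if not sol.ok:
            rows.append(
                {"vc": a, "vo": b, "status": "infeasible", "growth": 0.0,
                 "quantum_yield": None, "assimilation_quotient": None}
            )
            continue
        idx = photosynthetic_indices(sol, ids)
        growth = (
            sol.fluxes.get(model.biomass_reaction_id, 0.0)
            if model.biomass_reaction_id
            else float("nan")
        )
        rows.append(
            {"vc": a, "vo": b, "status": "optimal", "growth": growth,
             "quantum_yield": idx.quantum_yield,
             "assimilation_quotient": idx.assimilation_quotient}
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- validation

@dataclass
class ProbeResult:
    name: str
    passed: bool
    value: float
    detail: str = ""


@dataclass
class ValidationReport:
    probes: List[ProbeResult]

    @property
    def passed(self) -> bool:
        return all(p.passed for p in self.probes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"probe": p.name, "passed": p.passed, "value": p.value,
                 "detail": p.detail}
                for p in self.probes
            ]
        )

    def __str__(self) -> str:
        lines = [
            f"[{'PASS' if p.passed else 'FAIL'}] {p.name}: {p.value:.6g} {p.detail}"
            for p in self.probes
        ]
        return "\n".join(lines)


def _closed(model: MetabolicModel) -> MetabolicModel:
    out = model.copy()
    for rid in find_boundary_reactions(out):
        rxn = out.reactions[rid]
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return out


def validate_model(
    model: MetabolicModel,
    presets: Mapping[str, ConditionPreset],
    element_sources: Optional[Mapping[str, Sequence[str]]] = None,
    expect_growth: Optional[Mapping[str, bool]] = None,
    atp_drain: Optional[str] = None,
    tol: float = _TOL,
) -> ValidationReport:
    """Run the model-validation battery; all probes are side-effect free.

    Probes: (i) with every uptake closed, neither biomass nor ATP
    hydrolysis can carry flux; (ii) removing any single elemental source
    from a growth preset abolishes growth; (iii) each preset grows (or
    not) as expected; (iv) no stoichiometrically unbalanced
    energy-generating cycle produces ATP from nothing.
    """
    if model.biomass_reaction_id is None:
        raise ValueError("validation requires a biomass reaction")
    probes: List[ProbeResult] = []
    if atp_drain is None and "NGAM" in model.reactions:
        atp_drain = "NGAM"

    closed = _closed(model)
    if atp_drain is not None:
        closed.reactions[atp_drain].lower_bound = 0.0
    growth = fba(closed)
    gval = growth.objective_value if growth.ok else 0.0
    probes.append(
        ProbeResult("zero_input_biomass", abs(gval) <= tol, gval,
                    "max growth, all uptakes closed")
    )
    if atp_drain is not None:
        atp = fba(closed, atp_drain)
        aval = atp.objective_value if atp.ok else 0.0
        probes.append(
            ProbeResult("energy_generating_cycle", abs(aval) <= tol, aval,
                        "max ATP hydrolysis, all uptakes closed")
        )

    for pname in sorted(presets):
        preset = presets[pname]
        cond = set_condition(model, preset)
        sol = fba(cond)
        val = sol.objective_value if sol.ok else 0.0
        expected = True if expect_growth is None else expect_growth.get(pname, True)
        ok = (val > tol) if expected else (abs(val) <= tol)
        probes.append(
            ProbeResult(
                f"growth_{pname}", ok, val,
                f"expected {'growth' if expected else 'no growth'}",
            )
        )
        if element_sources and (expect_growth is None or expect_growth.get(pname, True)):
            for element in sorted(element_sources):
                exchanges = element_sources[element]
                restricted = cond.copy()
                hit = False
                for ex in exchanges:
                    if ex in restricted.reactions:
                        restricted.reactions[ex].lower_bound = max(
                            restricted.reactions[ex].lower_bound, 0.0
                        )
                        hit = True
                if not hit:
                    continue
                sol2 = fba(restricted)
                val2 = sol2.objective_value if sol2.ok else 0.0
                probes.append(
                    ProbeResult(
                        f"no_{element}_{pname}", abs(val2) <= tol, val2,
                        f"growth without {element} source",
                    )
                )
    return ValidationReport(probes)


def biomass_precursor_gaps(model: MetabolicModel, tol: float = _TOL) -> List[str]:
    """Biomass precursors the network cannot produce (probe via drains)."""
    if model.biomass_reaction_id is None:
        return []
    biomass = model.reactions[model.biomass_reaction_id]
    gaps = []
    from .model import Reaction

    for mid in sorted(m for m, c in biomass.stoichiometry.items() if c < 0):
        probe = model.copy()
        probe.add_reaction(Reaction("DM__probe", {mid: -1.0}, 0.0, 1000.0))
        sol = fba(probe, "DM__probe")
        if not sol.ok or sol.objective_value <= tol:
            gaps.append(mid)
    return gaps
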