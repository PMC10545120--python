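"""The "miniplant": a small compartmentalized plant network with known optima.

The generator emulates, at toy scale, the network classes that matter for
cork-oak modelling: photon-driven carbon fixation with distinct Rubisco
carboxylation and oxygenation reactions sharing RuBP, a photorespiratory
salvage that re-releases fixed CO2, starch/sucrose metabolism,
respiration, nitrate/sulfate assimilation, and a suberin-precursor branch
(glycerol-3-phosphate, ferulate via phenylpropanoids, omega-hydroxy fatty
acid via a CYP-like monooxygenase).  All sugars are (CH2O)n so every
enzymatic reaction is elementally balanced by construction; the energy
currency uses a zero-mass pseudo-element so ATP hydrolysis balances too.

Design anchors (recorded in the returned :class:`GroundTruth`):

* one photon yields one ATP, and fixing one CO2 costs exactly
  ``photons_per_co2`` ATP, so the stoichiometric maximum quantum yield is
  exactly ``1/photons_per_co2`` (reachable by minimizing photon uptake at
  a fixed sucrose export, since sucrose synthesis is ATP-neutral);
* maximum growth per condition follows from closed-form photon/sucrose
  budgets per gram of biomass — arithmetic, not an LP — so the optimizer
  can be checked against an independent prediction;
* optional flags plant a dead (orphan) branch, or an ATP-generating
  cycle that the validation battery must catch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .biomass import (
    CurrencyIds,
    EnergyParams,
    MacroComposition,
    MonomerEntry,
    MonomerTable,
    attach_biomass,
)
from .extraction import ExpressionDataset
from .lp import RatioConstraint
from .model import MetabolicModel, Metabolite, Reaction, formula_weight
from .gpr import parse_gpr
from .protocols import ConditionPreset

__all__ = [
    "MiniplantConfig",
    "TissueProfileSpec",
    "GroundTruth",
    "make_miniplant",
    "make_expression",
    "make_tissue_model",
    "miniplant_presets",
    "TISSUE_COMPOSITIONS",
    "MONOMER_TABLE",
]

RESP_ATP_YIELD = 10.0  # ATP per triose respired (upper cap)


def _resp_yield(ppc: float) -> float:
    """Respiratory ATP per triose, capped strictly below the 3*ppc photon
    cost of fixing one, so fixation + respiration never amplifies energy."""
    return max(1.0, min(RESP_ATP_YIELD, 3.0 * ppc - 2.0))

GENE_GROUPS: Dict[str, Tuple[str, ...]] = {
    "photosynthesis": (
        "gLHC1", "gLHC2", "gRBCL", "gRBCS", "gRBCO", "gPRK", "gPGLP",
    ),
    "suberin": ("gACC", "gKAS", "gCYP86A", "gCYP704B"),
    "starch": ("gSS", "gSD"),
    "respiration": ("gCOX", "gAOX"),
    "assimilation": ("gGS", "gCYS", "gG3PD"),
    "phenylpropanoid": ("gPAL", "gC3H"),
    "sucrose": ("gSPS",),
    "orphan": ("gORP1", "gORP2", "gORP3"),
}

# tissue macromolecular compositions (g/gDW); suberin-rich phellogen,
# lignin/carbohydrate-rich inner bark, protein/carbohydrate-rich leaf
TISSUE_COMPOSITIONS: Dict[str, Dict[str, float]] = {
    "leaf": {
        "e-Protein": 0.437, "e-Carbohydrate": 0.407, "e-Lipid": 0.100,
        "e-Lignin": 0.056,
    },
    "innerbark": {
        "e-Carbohydrate": 0.469, "e-Lignin": 0.382, "e-Protein": 0.100,
        "e-Lipid": 0.029, "e-Suberin": 0.020,
    },
    "phellogen": {
        "e-Suberin": 0.362, "e-Carbohydrate": 0.176, "e-Lignin": 0.252,
        "e-Protein": 0.150, "e-Lipid": 0.060,
    },
    "generic": {
        "e-Protein": 0.300, "e-Carbohydrate": 0.400, "e-Lignin": 0.150,
        "e-Lipid": 0.090, "e-Suberin": 0.060,
    },
}

_FORMULAS = {
    "aa_c": "C3H6NO3",
    "aas_c": "C3H6NO3S",
    "sucr_c": "C12H22O11",
    "g3p_c": "C3H6O3P",
    "fer_r": "C9H18O9",
    "fa_r": "C18H36O18",
    "ohfa_r": "C18H36O20",
}

MONOMER_TABLE = MonomerTable(
    {
        "e-Protein": [
            MonomerEntry("aa_c", 0.8, formula_weight(_FORMULAS["aa_c"]), 0),
            MonomerEntry("aas_c", 0.2, formula_weight(_FORMULAS["aas_c"]), 0),
        ],
        "e-Carbohydrate": [
            MonomerEntry("sucr_c", 1.0, formula_weight(_FORMULAS["sucr_c"]), 0),
        ],
        # glycerolipid backbone only: keeps the fatty-acid chain exclusive
        # to the suberin branch, which extraction tests rely on
        "e-Lipid": [
            MonomerEntry("g3p_c", 1.0, formula_weight(_FORMULAS["g3p_c"]), 0),
        ],
        "e-Lignin": [
            MonomerEntry("fer_r", 1.0, formula_weight(_FORMULAS["fer_r"]), 0),
        ],
        "e-Suberin": [
            MonomerEntry("g3p_c", 0.10, formula_weight(_FORMULAS["g3p_c"]), 0),
            MonomerEntry("fer_r", 0.30, formula_weight(_FORMULAS["fer_r"]), 0),
            MonomerEntry("ohfa_r", 0.60, formula_weight(_FORMULAS["ohfa_r"]), 0),
        ],
    }
)


@dataclass
class MiniplantConfig:
    photons_per_co2: int = 8
    include_suberin_branch: bool = True
    include_oxygenation: bool = True
    include_orphan_branch: bool = False
    include_atp_cycle_bug: bool = False
    tissue: str = "generic"  # composition used for the built-in biomass
    photon_bound: float = 100.0   # photoautotrophic photon uptake cap
    sucrose_bound: float = 1.0    # heterotrophic sucrose uptake cap
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photons_per_co2 < 1:
            raise ValueError("photons_per_co2 must be >= 1")


@dataclass
class TissueProfileSpec:
    tissue: str
    silenced_gene_sets: Tuple[str, ...] = ()
    mu: float = 2.0      # log-normal location of active genes
    sigma: float = 1.0   # log-normal scale
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.silenced_gene_sets) - set(GENE_GROUPS)
        if unknown:
            raise ValueError(f"unknown gene groups: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """The generator's own bookkeeping, computed without any solver."""

    config: MiniplantConfig
    max_quantum_yield: float               # 1 / photons_per_co2
    growth_photoautotrophic: float         # closed-form photon budget
    growth_heterotrophic: float            # closed-form sucrose budget
    quantum_yield_at_growth_optimum: float
    assimilation_quotient: float
    photons_per_gram: float
    co2_per_gram: float
    orphan_reactions: Tuple[str, ...]
    suberin_reactions: Tuple[str, ...]     # suberin-branch-exclusive
    photosynthesis_reactions: Tuple[str, ...]
    gene_groups: Dict[str, Tuple[str, ...]]
    reaction_gprs: Dict[str, str]
    exchange_ids: Dict[str, str]
    carboxylation: str = "CBX"
    oxygenation: str = "OXY"
    storable_metabolites: Tuple[str, ...] = (
        "starch_p", "sucr_c", "aa_c", "no3_c",
    )
    shared_pool_metabolites: Tuple[str, ...] = (
        "sucr_e", "aa_e", "aas_e", "no3_e", "h2o_e", "pi_e", "so4_e",
        "co2_e", "o2_e",
    )

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2, default=list)


def _monomer_costs(ppc: int) -> Dict[str, Tuple[float, float, float, float]]:
    """Per-mmol monomer budgets: (trioses, extra ATP, carbons, net O2 out).

    Triose cost already covers fixation ATP in phototrophy (ppc per CO2,
    i.e. 3*ppc per triose); "extra ATP" is the assimilation cost beyond
    carbon.  Net O2: assimilation reactions release O2 (balance), the
    omega-hydroxylase consumes one.
    """
    return {
        "aa_c": (1.0, 6.0, 3.0, 1.5),
        "aas_c": (1.0, 6.0, 3.0, 3.5),
        "sucr_c": (4.0, 0.0, 12.0, 0.0),
        "g3p_c": (1.0, 0.0, 3.0, 0.0),
        "fer_r": (3.0, 2.0, 9.0, 0.0),
        "fa_r": (6.0, 8.0, 18.0, 0.0),
        "ohfa_r": (6.0, 10.0, 18.0, -1.0),
    }


def _per_gram_budgets(
    tissue: str, ppc: int
) -> Tuple[float, float, float, float]:
    """(trioses, extra ATP, carbons, net assimilation O2) per gDW biomass."""
    costs = _monomer_costs(ppc)
    comp = TISSUE_COMPOSITIONS[tissue]
    tp = atp = carbon = o2 = 0.0
    for macro, frac in comp.items():
        for entry in MONOMER_TABLE[macro]:
            mmol = 1000.0 * frac * entry.fraction / entry.molar_mass
            ctp, catp, cc, co2x = costs[entry.metabolite_id]
            tp += mmol * ctp
            atp += mmol * catp
            carbon += mmol * cc
            o2 += mmol * co2x
    return tp, atp, carbon, o2


def make_miniplant(cfg: MiniplantConfig = MiniplantConfig()) -> Tuple[MetabolicModel, GroundTruth]:
    """Build the miniplant model and its analytic ground truth."""
    ppc = float(cfg.photons_per_co2)
    m = MetabolicModel(
        "miniplant",
        {
            "e": "extracellular", "c": "cytosol", "p": "plastid",
            "m": "mitochondrion", "r": "endoplasmic reticulum",
        },
    )

    def met(mid: str, comp: str, formula: Optional[str]) -> None:
        m.add_metabolite(Metabolite(mid, name=mid, compartment=comp, formula=formula))

    for comp in ("e", "c", "p"):
        met(f"co2_{comp}", comp, "CO2")
        met(f"o2_{comp}", comp, "O2")
        met(f"h2o_{comp}", comp, "H2O")
    met("photon_e", "e", None)
    met("photon_p", "p", None)
    for comp in ("e", "c"):
        met(f"no3_{comp}", comp, "NO3")
        met(f"pi_{comp}", comp, "PH2O")
        met(f"so4_{comp}", comp, "SO4")
        met(f"sucr_{comp}", comp, _FORMULAS["sucr_c"])
    met("atp_c", "c", "XP")
    met("adp_c", "c", "X")
    met("rubp_p", "p", "C5H10O5")
    met("tp_p", "p", "C3H6O3")
    met("tp_c", "c", "C3H6O3")
    met("tp_m", "m", "C3H6O3")
    met("pglyc_p", "p", "C2H4O4")
    met("starch_p", "p", "C12H20O10")
    met("aa_c", "c", _FORMULAS["aa_c"])
    met("aas_c", "c", _FORMULAS["aas_c"])
    met("aa_e", "e", _FORMULAS["aa_c"])
    met("aas_e", "e", _FORMULAS["aas_c"])
    met("g3p_c", "c", _FORMULAS["g3p_c"])
    met("fer_r", "r", _FORMULAS["fer_r"])
    if cfg.include_suberin_branch:
        met("fa_r", "r", _FORMULAS["fa_r"])
        met("ohfa_r", "r", _FORMULAS["ohfa_r"])

    def rxn(
        rid: str,
        stoich: Dict[str, float],
        lb: float = 0.0,
        ub: float = 1000.0,
        gpr: str = "",
        name: str = "",
        pathway: Optional[str] = None,
    ) -> None:
        m.add_reaction(
            Reaction(rid, stoich, lb, ub, gpr=parse_gpr(gpr), name=name or rid,
                     pathway=pathway)
        )

    def atpase(stoich: Dict[str, float], n: float) -> Dict[str, float]:
        # hydrolysis of n ATP (negative n: synthesis); water balances the
        # hydrated-phosphate convention
        if n:
            for mid, c in (("atp_c", -n), ("h2o_c", -n), ("adp_c", n),
                           ("pi_c", n)):
                stoich[mid] = stoich.get(mid, 0.0) + c
        return stoich

    # exchanges: permissive default medium; presets restrict it
    for mid in ("photon", "co2", "o2", "h2o", "no3", "pi", "so4", "sucr",
                "aa", "aas"):
        rxn(f"EX_{mid}", {f"{mid}_e": -1.0}, -1000.0, 1000.0,
            name=f"{mid} exchange")

    # transports (no gene association: orphan fillers for the extraction)
    rxn("T_photon", {"photon_e": -1, "photon_p": 1})
    for mid in ("co2", "o2", "h2o"):
        rxn(f"T_{mid}_ec", {f"{mid}_e": -1, f"{mid}_c": 1}, -1000.0)
        rxn(f"T_{mid}_cp", {f"{mid}_c": -1, f"{mid}_p": 1}, -1000.0)
    for mid in ("no3", "pi", "so4"):
        rxn(f"T_{mid}", {f"{mid}_e": -1, f"{mid}_c": 1})
    rxn("T_sucr", {"sucr_c": -1, "sucr_e": 1}, -1000.0)
    rxn("T_aa", {"aa_c": -1, "aa_e": 1}, -1000.0)
    rxn("T_aas", {"aas_c": -1, "aas_e": 1}, -1000.0)
    rxn("T_tp_pc", {"tp_p": -1, "tp_c": 1}, -1000.0)
    rxn("T_tp_cm", {"tp_c": -1, "tp_m": 1}, -1000.0)

    # light reactions: 1 photon phosphorylates 1 ADP
    rxn("LIGHT",
        {"photon_p": -1, "adp_c": -1, "pi_c": -1, "atp_c": 1, "h2o_c": 1},
        gpr="gLHC1 and gLHC2", name="photophosphorylation",
        pathway="Photosynthesis")
    # Rubisco carboxylation: the fixation ATP cost sets the photon price
    rxn("CBX",
        atpase({"rubp_p": -1, "co2_p": -1, "h2o_p": -1, "tp_p": 2, "o2_p": 1},
               ppc),
        gpr="gRBCL and gRBCS", name="Rubisco carboxylation",
        pathway="Carbon fixation")
    if cfg.include_oxygenation:
        rxn("OXY",
            atpase({"rubp_p": -1, "o2_p": -1, "tp_p": 1, "pglyc_p": 1}, ppc),
            gpr="gRBCL and gRBCO", name="Rubisco oxygenation",
            pathway="Photorespiration")
        rxn("SALV",
            atpase({"pglyc_p": -2, "tp_p": 1, "co2_p": 1, "h2o_p": 1,
                    "o2_p": 1}, ppc),
            gpr="gPGLP", name="photorespiratory salvage",
            pathway="Glyoxylate and dicarboxylate metabolism")
    rxn("REGEN", {"tp_p": -5, "rubp_p": 3}, gpr="gPRK",
        name="RuBP regeneration", pathway="Carbon fixation")
    rxn("STS", atpase({"tp_p": -4, "starch_p": 1, "h2o_p": 2}, 1.0),
        gpr="gSS", name="starch synthesis",
        pathway="Starch and sucrose metabolism")
    rxn("STD", {"starch_p": -1, "h2o_p": -2, "tp_p": 4}, gpr="gSD",
        name="starch degradation", pathway="Starch and sucrose metabolism")
    rxn("SUCS", {"tp_c": -4, "sucr_c": 1, "h2o_c": 1}, -1000.0, gpr="gSPS",
        name="sucrose synthesis (reversible)",
        pathway="Starch and sucrose metabolism")
    rxn("RESP",
        atpase({"tp_m": -1, "o2_c": -3, "co2_c": 3, "h2o_c": 3},
               -_resp_yield(ppc)),
        gpr="gCOX or gAOX", name="respiration", pathway="Oxidative phosphorylation")
    rxn("AASYN",
        atpase({"tp_c": -1, "no3_c": -1, "aa_c": 1, "o2_c": 1.5}, 6.0),
        gpr="gGS", name="amino acid synthesis",
        pathway="Amino acid metabolism")
    rxn("AASSYN",
        atpase({"tp_c": -1, "no3_c": -1, "so4_c": -1, "aas_c": 1,
                "o2_c": 3.5}, 6.0),
        gpr="gCYS", name="S-amino acid synthesis",
        pathway="Amino acid metabolism")
    rxn("G3PDH", {"tp_c": -1, "pi_c": -1, "g3p_c": 1, "h2o_c": 1},
        gpr="gG3PD",
        name="glycerol-3-phosphate dehydrogenase",
        pathway="Glycerophospholipid metabolism")
    rxn("FER", atpase({"tp_c": -3, "fer_r": 1}, 2.0), gpr="gPAL and gC3H",
        name="ferulate synthesis (phenylpropanoid)",
        pathway="Phenylpropanoid biosynthesis")
    if cfg.include_suberin_branch:
        rxn("FAS", atpase({"tp_c": -6, "fa_r": 1}, 8.0), gpr="gACC and gKAS",
            name="fatty acid synthesis/elongation",
            pathway="Fatty acid biosynthesis")
        rxn("OHFA", atpase({"fa_r": -1, "o2_c": -1, "ohfa_r": 1}, 2.0),
            gpr="gCYP86A or gCYP704B",
            name="fatty acid omega-hydroxylase",
            pathway="Cutin, suberine and wax biosynthesis")

    orphan: Tuple[str, ...] = ()
    if cfg.include_orphan_branch:
        for mid in ("orphA_c", "orphB_c", "orphC_c"):
            met(mid, "c", "C3H6O3")
        rxn("ORPH1", {"tp_c": -1, "orphA_c": 1}, gpr="gORP1",
            name="orphan branch step 1")
        rxn("ORPH2", {"orphA_c": -1, "orphB_c": 1}, gpr="gORP2",
            name="orphan branch step 2")
        rxn("ORPH3", {"orphB_c": -1, "orphC_c": 1}, gpr="gORP3",
            name="orphan branch step 3")
        orphan = ("ORPH1", "ORPH2", "ORPH3")

    if cfg.include_atp_cycle_bug:
        rxn("BUG_ATP", {"adp_c": -1, "pi_c": -1, "atp_c": 1, "h2o_c": 1},
            name="spurious ATP generation (planted defect)")

    comp_frac = dict(TISSUE_COMPOSITIONS[cfg.tissue])
    if not cfg.include_suberin_branch:
        comp_frac.pop("e-Suberin", None)
        total = sum(comp_frac.values())
        comp_frac = {k: v / total for k, v in comp_frac.items()}
    model = attach_biomass(
        m,
        MacroComposition(cfg.tissue, comp_frac),
        MONOMER_TABLE,
        EnergyParams(gam=0.0, ngam=0.0),
        CurrencyIds(),
        allow_suberin=True,
    )

    tp, extra_atp, carbon, o2_assim = _per_gram_budgets(cfg.tissue, cfg.photons_per_co2)
    photons_per_g = tp * 3.0 * ppc + extra_atp
    growth_photo = cfg.photon_bound / photons_per_g
    growth_het = 4.0 * cfg.sucrose_bound / (
        tp + extra_atp / _resp_yield(ppc)
    )
    truth = GroundTruth(
        config=cfg,
        max_quantum_yield=1.0 / ppc,
        growth_photoautotrophic=growth_photo,
        growth_heterotrophic=growth_het,
        quantum_yield_at_growth_optimum=carbon / photons_per_g,
        assimilation_quotient=carbon / (carbon + o2_assim),
        photons_per_gram=photons_per_g,
        co2_per_gram=carbon,
        orphan_reactions=orphan,
        suberin_reactions=("FAS", "OHFA") if cfg.include_suberin_branch else (),
        photosynthesis_reactions=(
            ("LIGHT", "CBX", "REGEN") + (("OXY", "SALV") if cfg.include_oxygenation else ())
        ),
        gene_groups={k: v for k, v in GENE_GROUPS.items()},
        reaction_gprs={
            rid: model.reactions[rid].gpr.to_string()
            for rid in sorted(model.reactions)
            if model.reactions[rid].gpr
        },
        exchange_ids={
            "photon": "EX_photon", "co2": "EX_co2", "o2": "EX_o2",
            "sucrose": "EX_sucr", "nitrate": "EX_no3",
        },
    )
    return model, truth


def miniplant_presets(
    cfg: MiniplantConfig = MiniplantConfig(),
) -> Dict[str, ConditionPreset]:
    """The three named study conditions for the miniplant."""
    water_minerals = {
        "EX_h2o": 1000.0, "EX_no3": 1000.0, "EX_pi": 1000.0, "EX_so4": 1000.0,
    }
    photo = ConditionPreset(
        "photoautotrophic",
        {"EX_photon": cfg.photon_bound, "EX_co2": 1000.0, **water_minerals},
        nitrogen_source="nitrate",
    )
    hetero = ConditionPreset(
        "heterotrophic",
        {"EX_sucr": cfg.sucrose_bound, "EX_o2": 1000.0, **water_minerals},
        nitrogen_source="nitrate",
    )
    photoresp = ConditionPreset(
        "photorespiratory",
        dict(photo.open_uptakes),
        nitrogen_source="nitrate",
        ratio_constraints=[RatioConstraint("CBX", "OXY", 3.0, 1.0)],
    )
    # inner-bark/phellogen style runs also allow amino-acid uptake at the
    # same unit bound as sucrose
    hetero_aa = ConditionPreset(
        "heterotrophic_aa",
        {**hetero.open_uptakes, "EX_aa": cfg.sucrose_bound,
         "EX_aas": cfg.sucrose_bound},
        nitrogen_source="nitrate",
    )
    return {
        "photoautotrophic": photo,
        "heterotrophic": hetero,
        "photorespiratory": photoresp,
        "heterotrophic_aa": hetero_aa,
    }


def make_expression(
    model: MetabolicModel, spec: TissueProfileSpec
) -> ExpressionDataset:
    """Synthetic expression profile: silenced groups at zero, others log-normal.

    Silenced genes are guaranteed below the dataset median (an error is
    raised in the degenerate case where zeros dominate the median).
    """
    silenced = {
        g for group in spec.silenced_gene_sets for g in GENE_GROUPS[group]
    }
    rng = np.random.default_rng(spec.seed)
    values: Dict[str, float] = {}
    for gene in sorted(model.genes):
        if gene in silenced:
            values[gene] = 0.0
        else:
            values[gene] = float(rng.lognormal(spec.mu, spec.sigma))
    med = float(np.median(list(values.values())))
    if med <= 0:
        raise ValueError(
            "silenced genes dominate the dataset: median is zero, the "
            "threshold cannot separate silenced from active genes"
        )
    return ExpressionDataset(spec.tissue, values)


def extract_miniplant_tissue(
    model: MetabolicModel,
    tissue: str,
    seed: int = 0,
    presets: Optional[Dict[str, ConditionPreset]] = None,
):
    """Full expression-driven extraction of a miniplant tissue model.

    The leaf profile silences the suberin branch and is extracted under
    the photoautotrophic medium; inner bark and phellogen silence
    photosynthesis and are extracted under the heterotrophic medium with
    sucrose and amino-acid uptake (their physiological supply route).
    Parent exchanges are retained so any named preset stays applicable.
    """
    from .extraction import ExtractionConfig, extract_tissue
    from .protocols import set_condition

    if presets is None:
        presets = miniplant_presets()
    tm = make_tissue_model(model, tissue)
    if tissue == "leaf":
        medium = presets["photoautotrophic"]
        silenced: Tuple[str, ...] = ("suberin",)
        # machinery the leaf must keep for the diel/multi-tissue role:
        # respiration (night energy) and the phloem-loading exporters of
        # sucrose and amino acids
        protected = frozenset({"RESP", "T_sucr", "T_tp_cm", "T_aa", "T_aas"})
    else:
        medium = presets["heterotrophic_aa"]
        silenced = ("photosynthesis",)
        protected = frozenset()
    cond = set_condition(tm, medium)
    cond.biomass_reaction_id = tm.biomass_reaction_id
    expr = make_expression(tm, TissueProfileSpec(tissue, silenced, seed=seed))
    return extract_tissue(
        cond, expr,
        ExtractionConfig(protected_reactions=protected, keep_exchanges=True),
    )


def make_tissue_model(
    model: MetabolicModel, tissue: str
) -> MetabolicModel:
    """Swap the miniplant's biomass machinery for a tissue-specific one."""
    if tissue not in TISSUE_COMPOSITIONS:
        raise KeyError(f"unknown tissue {tissue!r}")
    out = model.copy()
    drop = [
        rid for rid in out.reactions
        if rid.startswith(("SYN_", "BIOMASS_", "DM_biomass_")) or rid == "NGAM"
    ]
    out.remove_reactions(drop)
    out.prune_orphan_metabolites()
    return attach_biomass(
        out,
        MacroComposition(tissue, TISSUE_COMPOSITIONS[tissue]),
        MONOMER_TABLE,
        EnergyParams(gam=0.0, ngam=0.0),
        CurrencyIds(),
        allow_suberin=tissue != "leaf",
    )
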