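"""Shared fixtures: toy networks and the synthetic miniplant."""

import pytest

from suberflux.gpr import parse_gpr
from suberflux.model import MetabolicModel, Metabolite, Reaction
from suberflux.synth import MiniplantConfig, make_miniplant, miniplant_presets


def build_model(mets, rxns, model_id="toy", compartments=("c",)):
    """Compact builder: mets = {id: (comp, formula)}, rxns = {id: (stoich, lb, ub)}."""
    m = MetabolicModel(model_id, {c: c for c in compartments})
    for mid, (comp, formula) in mets.items():
        m.add_metabolite(Metabolite(mid, compartment=comp, formula=formula))
    for rid, spec in rxns.items():
        stoich, lb, ub = spec[0], spec[1], spec[2]
        gpr = parse_gpr(spec[3]) if len(spec) > 3 else parse_gpr(None)
        m.add_reaction(Reaction(rid, dict(stoich), lb, ub, gpr=gpr))
    return m


@pytest.fixture
def chain_model():
    """EX_A(<=10 uptake) -> A -> B -> drain: one bottleneck."""
    m = build_model(
        {"A": ("c", "CH2O"), "B": ("c", "CH2O")},
        {
            "EX_A": ({"A": -1}, -10, 1000),
            "R1": ({"A": -1, "B": 1}, 0, 1000),
            "DM_B": ({"B": -1}, 0, 1000),
        },
    )
    m.biomass_reaction_id = "DM_B"
    return m


@pytest.fixture
def diamond_model():
    """A -> B directly (one reaction) or through C (two reactions)."""
    m = build_model(
        {"A": ("c", None), "B": ("c", None), "C": ("c", None)},
        {
            "EX_A": ({"A": -1}, -10, 1000),
            "RD": ({"A": -1, "B": 1}, 0, 1000),
            "RC1": ({"A": -1, "C": 1}, 0, 1000),
            "RC2": ({"C": -1, "B": 1}, 0, 1000),
            "DM_B": ({"B": -1}, 0, 1000),
        },
    )
    m.biomass_reaction_id = "DM_B"
    return m


@pytest.fixture(scope="session")
def miniplant():
    return make_miniplant()


@pytest.fixture(scope="session")
def miniplant_model(miniplant):
    return miniplant[0]


@pytest.fixture(scope="session")
def truth(miniplant):
    return miniplant[1]


@pytest.fixture(scope="session")
def presets():
    return miniplant_presets()


@pytest.fixture(scope="session")
def miniplant_orphan():
    return make_miniplant(MiniplantConfig(include_orphan_branch=True))


@pytest.fixture(scope="session")
def miniplant_buggy():
    return make_miniplant(MiniplantConfig(include_atp_cycle_bug=True))
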