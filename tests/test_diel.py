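"""Diel duplication, common-pool merging and phase constraints."""

import pytest

from suberflux.diel import (
    CommonPoolSpec,
    DielConstraintSet,
    DielSpec,
    apply_diel_constraints,
    couple_phase_biomass,
    duplicate_diel,
    merge_multitissue,
)
from suberflux.lp import fba, pfba
from suberflux.model import component_counts
from suberflux.protocols import set_condition
from suberflux.synth import extract_miniplant_tissue

from conftest import build_model


def _toy(with_biomass=True):
    m = build_model(
        {"A": ("c", None), "B": ("c", None), "S": ("c", None)},
        {
            "EX_A": ({"A": -1}, -10, 1000),
            "R1": ({"A": -1, "B": 1}, 0, 1000),
            "R2": ({"B": -1, "S": 1}, -1000, 1000),
            "DM_B": ({"B": -1}, 0, 1000),
        },
    )
    if with_biomass:
        m.biomass_reaction_id = "DM_B"
    return m


def test_duplication_counts_formula():
    m = _toy()
    spec = DielSpec(storable_metabolites=("S", "B", "A"))
    d = duplicate_diel(m, spec)
    assert len(d.reactions) == 2 * 4 + 3
    assert len(d.metabolites) == 2 * 3
    assert "LNK_S" in d.reactions and "light_R1" in d.reactions


def test_duplication_empty_storables_disconnected_phases():
    m = _toy()
    d = duplicate_diel(m, DielSpec(storable_metabolites=()))
    assert len(d.reactions) == 2 * 4
    light_mets = {mid for mid in d.metabolites if mid.startswith("light_")}
    for rid, rxn in d.reactions.items():
        touches_light = any(mid in light_mets for mid in rxn.stoichiometry)
        touches_dark = any(mid not in light_mets for mid in rxn.stoichiometry)
        assert not (touches_light and touches_dark)


def test_unknown_storable_rejected():
    with pytest.raises(KeyError, match="nope"):
        duplicate_diel(_toy(), DielSpec(storable_metabolites=("nope",)))


def test_namespace_collision_free(miniplant_model):
    leaf = extract_miniplant_tissue(miniplant_model, "leaf", seed=11)
    d = duplicate_diel(leaf, DielSpec(storable_metabolites=("sucr_c",)))
    assert len(d.reactions) == 2 * len(leaf.reactions) + 1
    assert len(set(d.reactions)) == len(d.reactions)


@pytest.fixture(scope="module")
def multitissue(miniplant_model, truth):
    tissues = {
        t: extract_miniplant_tissue(miniplant_model, t, seed=11)
        for t in ("leaf", "innerbark", "phellogen")
    }
    diel = {
        t: duplicate_diel(
            m,
            DielSpec(storable_metabolites=tuple(
                s for s in truth.storable_metabolites if s in m.metabolites
            )),
        )
        for t, m in tissues.items()
    }
    shared = truth.shared_pool_metabolites
    mode = {
        m: ("symport" if m in ("sucr_e", "aa_e", "aas_e") else "diffusion")
        for m in shared
    }
    pools = [
        CommonPoolSpec(1, ("leaf", "innerbark"), shared, mode),
        CommonPoolSpec(2, ("innerbark", "phellogen"), shared, mode),
    ]
    merged = merge_multitissue(
        [(t, diel[t]) for t in ("leaf", "innerbark", "phellogen")], pools
    )
    final = apply_diel_constraints(merged, DielConstraintSet())
    sol = pfba(final)
    assert sol.ok
    return final, sol


def test_multitissue_grows(multitissue):
    final, sol = multitissue
    assert sol.objective_value > 0.1


def test_nitrate_light_dark_ratio_exact(multitissue):
    final, sol = multitissue
    nl = sol.fluxes["innerbark__light_EX_no3"]
    nd = sol.fluxes["innerbark__dark_EX_no3"]
    assert nl < 0 and nd < 0  # both are uptakes
    assert 2 * nl - 3 * nd == pytest.approx(0.0, abs=1e-6)


def test_photon_only_in_leaf_light(multitissue):
    final, sol = multitissue
    assert final.reactions["leaf__dark_EX_photon"].upper_bound == 0.0
    assert final.reactions["leaf__dark_EX_photon"].lower_bound == 0.0
    assert sol.fluxes["leaf__light_EX_photon"] < -1.0
    for t in ("innerbark", "phellogen"):
        for tag in ("light", "dark"):
            rid = f"{t}__{tag}_EX_photon"
            if rid in final.reactions:
                rxn = final.reactions[rid]
                assert rxn.lower_bound == rxn.upper_bound == 0.0


def test_gas_exchange_only_in_leaf(multitissue):
    final, sol = multitissue
    for tag in ("light", "dark"):
        assert f"leaf__{tag}_EX_co2" in final.reactions
        for t in ("innerbark", "phellogen"):
            # shared-pool replacement deleted the tissue exchange; no other
            # boundary route for CO2 may exist in these tissues
            assert f"{t}__{tag}_EX_co2" not in final.reactions


def test_mineral_uptake_only_in_inner_bark(multitissue):
    final, sol = multitissue
    for tag in ("light", "dark"):
        rxn = final.reactions[f"innerbark__{tag}_EX_no3"]
        assert rxn.lower_bound < 0
        for t in ("leaf", "phellogen"):
            assert f"{t}__{tag}_EX_no3" not in final.reactions


def test_pool_species_conserved(multitissue):
    """Pools are pass-through: net production of every pool species is zero."""
    final, sol = multitissue
    for mid, met in final.metabolites.items():
        if met.compartment.startswith("pool"):
            net = sum(
                rxn.stoichiometry.get(mid, 0.0) * sol.fluxes[rid]
                for rid, rxn in final.reactions.items()
            )
            assert net == pytest.approx(0.0, abs=1e-6)


def test_proton_symport_balanced_by_atpase(multitissue):
    final, sol = multitissue
    for pool in (1, 2):
        for tag in ("light", "dark"):
            for tissue in ("leaf", "innerbark", "phellogen"):
                imports = sum(
                    v for rid, v in sol.fluxes.items()
                    if rid.startswith(f"{tissue}__IP{pool}_{tag}_")
                )
                atpase = sol.fluxes.get(f"{tissue}__ATPASE{pool}_{tag}", 0.0)
                assert imports == pytest.approx(atpase, abs=1e-6)


def test_storage_linker_carries_flux_to_dark(multitissue):
    """The dark phase is fed by stored photosynthate from the light phase."""
    final, sol = multitissue
    linkers = [
        sol.fluxes[rid] for rid in final.reactions
        if rid.startswith("leaf__LNK_")
    ]
    assert max(linkers) > 0.1  # light -> dark storage in the leaf


def test_starch_linker_when_only_storable(miniplant_model):
    """With starch as the only store, it must carry the night's energy."""
    from suberflux.synth import make_tissue_model

    leaf = make_tissue_model(miniplant_model, "leaf")
    spec = DielSpec(storable_metabolites=("starch_p",))
    diel = couple_phase_biomass(leaf, duplicate_diel(leaf, spec), spec)
    # photons only by day; gases both phases; minerals always available
    for rid, rxn in diel.reactions.items():
        if rid.endswith("_EX_photon") and rid.startswith("dark_"):
            rxn.lower_bound = rxn.upper_bound = 0.0
        elif rid.startswith(("light_EX_", "dark_EX_")) and rid.endswith(
            ("_sucr", "_aa", "_aas")
        ):
            rxn.lower_bound = 0.0
    sol = pfba(diel)
    assert sol.ok and sol.objective_value > 1e-3
    assert sol.fluxes["LNK_starch_p"] > 1e-3  # stored by day, burnt by night


def test_phase_symmetry_with_photons_in_both_phases(miniplant_model):
    """Symmetric conditions give identical light/dark flux patterns."""
    leaf = extract_miniplant_tissue(miniplant_model, "leaf", seed=11)
    spec = DielSpec(storable_metabolites=("starch_p", "sucr_c"))
    diel = couple_phase_biomass(leaf, duplicate_diel(leaf, spec), spec)
    sol = pfba(diel)
    assert sol.ok
    for rid in leaf.reactions:
        light = sol.fluxes.get(f"light_{rid}", 0.0)
        dark = sol.fluxes.get(f"dark_{rid}", 0.0)
        assert light == pytest.approx(dark, abs=1e-5)


def test_merged_counts_by_construction_formula():
    """Two copies of a toy sharing one metabolite: count the added pieces."""
    t = _toy()
    spec = DielSpec(storable_metabolites=("S",))
    d = duplicate_diel(t, spec)  # 2*4+1 = 9 reactions each
    pools = [CommonPoolSpec(1, ("t1", "t2"), ("A",), {"A": "diffusion"})]
    merged = merge_multitissue(
        [("t1", d), ("t2", d.copy())], pools,
        biomass_species={"t1": "B", "t2": "B"},
    )
    # 2 tissues x 9, minus 2 phases x 2 deleted EX_A, plus 2 phases x 2
    # diffusion transfers, plus the combined biomass drain
    assert len(merged.reactions) == 2 * 9 - 4 + 4 + 1
    # metabolites: 2 x 6 tissue species + per-phase pool species + protons
    assert len(merged.metabolites) == 2 * 6 + 2 + 2
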