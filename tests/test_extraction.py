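"""Reaction scoring, core building and FASTCORE extraction."""

import itertools

import pytest

from suberflux.extraction import (
    ExpressionDataset,
    ExtractionConfig,
    build_core,
    extract_tissue,
    fastcore_extract,
    score_reactions,
)
from suberflux.lp import blocked_reactions, fba
from suberflux.protocols import set_condition
from suberflux.synth import (
    TissueProfileSpec,
    extract_miniplant_tissue,
    make_expression,
    make_tissue_model,
)

from conftest import build_model


def test_score_reactions_min_max(chain_model):
    model = chain_model.copy()
    from suberflux.gpr import parse_gpr

    model.reactions["R1"].gpr = parse_gpr("(g1 and g2) or g3")
    expr = ExpressionDataset("t", {"g1": 2, "g2": 8, "g3": 5})
    scores = score_reactions(model, expr)
    assert scores.scores["R1"] == 5
    assert scores.no_gene == {"EX_A", "DM_B"}
    assert scores.threshold == 5  # median of {2, 8, 5}


def test_build_core_threshold_and_protection():
    from suberflux.extraction import ReactionScoreSet

    scores = ReactionScoreSet(
        {"R1": 1.0, "R2": 5.0, "R3": 9.0}, frozenset(), threshold=5.0
    )
    assert build_core(scores, ExtractionConfig()) == {"R2", "R3"}
    assert build_core(
        scores, ExtractionConfig(protected_reactions=frozenset({"R1"}))
    ) == {"R1", "R2", "R3"}


def test_empty_core_raises():
    from suberflux.extraction import ReactionScoreSet

    scores = ReactionScoreSet({"R1": 1.0}, frozenset(), threshold=5.0)
    with pytest.raises(ValueError, match="empty core"):
        build_core(scores, ExtractionConfig())


def _eight_reaction_toy():
    return build_model(
        {"S": ("c", None), "A": ("c", None), "B": ("c", None),
         "D": ("c", None), "E": ("c", None)},
        {
            "EX_S": ({"S": -1}, -10, 1000),
            "R1": ({"S": -1, "A": 1}, 0, 1000),
            "R2": ({"A": -1, "B": 1}, 0, 1000),
            "R4": ({"B": -1}, 0, 1000),        # the core target drain
            "R5": ({"S": -1, "D": 1}, 0, 1000),  # parallel branch
            "R6": ({"D": -1, "E": 1}, 0, 1000),
            "DM_E": ({"E": -1}, 0, 1000),
            "R7": ({"A": -1, "D": 1}, 0, 1000),  # shortcut between branches
        },
    )


def _consistent_subsets_containing(model, must_have, eps=1e-4):
    """Brute-force: all flux-consistent reaction subsets containing must_have."""
    from suberflux.lp import fva

    rxns = sorted(model.reactions)
    good = []
    for r in range(1, len(rxns) + 1):
        for subset in itertools.combinations(rxns, r):
            if not must_have <= set(subset):
                continue
            sub = model.submodel(subset)
            intervals = fva(sub)
            if all(
                max(abs(iv.vmin), abs(iv.vmax)) >= eps for iv in intervals
            ):
                good.append(set(subset))
        if good:
            break  # smallest cardinality found
    return good


def test_fastcore_recovers_minimal_chain():
    model = _eight_reaction_toy()
    minimal = _consistent_subsets_containing(model, {"R4"})
    sub = fastcore_extract(model, {"R4"})
    assert set(sub.reactions) in minimal
    assert {"R1", "R2", "R4", "EX_S"} <= set(sub.reactions)
    assert "R6" not in sub.reactions and "DM_E" not in sub.reactions


def test_fastcore_identity_when_core_is_everything(miniplant_model):
    core = set(miniplant_model.reactions)
    sub = fastcore_extract(miniplant_model, core)
    assert set(sub.reactions) == core


def test_fastcore_errors_on_inconsistent_core():
    model = build_model(
        {"A": ("c", None), "D": ("c", None)},
        {
            "EX_A": ({"A": -1}, -10, 1000),
            "DEAD": ({"A": -1, "D": 1}, 0, 1000),
            "DM_A": ({"A": -1}, 0, 1000),
        },
    )
    with pytest.raises(ValueError, match="DEAD"):
        fastcore_extract(model, {"DEAD"})


def test_extracted_submodels_are_flux_consistent(miniplant_model):
    leaf = make_tissue_model(miniplant_model, "leaf")
    expr = make_expression(leaf, TissueProfileSpec("leaf", ("suberin",), seed=5))
    sub = extract_tissue(leaf, expr)
    assert blocked_reactions(sub, open_boundaries=False) == set()


def test_silenced_exclusive_reactions_not_in_core(miniplant_model, truth):
    leaf = make_tissue_model(miniplant_model, "leaf")
    expr = make_expression(leaf, TissueProfileSpec("leaf", ("suberin",), seed=1))
    scores = score_reactions(leaf, expr)
    core = build_core(scores, ExtractionConfig())
    assert not (set(truth.suberin_reactions) & core)


def test_retained_reactions_keep_full_gprs(miniplant_model):
    leaf = make_tissue_model(miniplant_model, "leaf")
    expr = make_expression(leaf, TissueProfileSpec("leaf", (), seed=2))
    sub = extract_tissue(leaf, expr)
    for rid, rxn in sub.reactions.items():
        assert rxn.gpr.to_string() == leaf.reactions[rid].gpr.to_string()


def test_extraction_monotone_in_protection(miniplant_model):
    leaf = make_tissue_model(miniplant_model, "leaf")
    expr = make_expression(leaf, TissueProfileSpec("leaf", ("starch",), seed=7))
    base = extract_tissue(leaf, expr)
    bigger = extract_tissue(
        leaf, expr,
        ExtractionConfig(protected_reactions=frozenset({"STS", "STD"})),
    )
    assert set(base.reactions) <= set(bigger.reactions)
    assert {"STS", "STD"} <= set(bigger.reactions)


def test_full_expression_keeps_biomass_feasible(miniplant_model):
    """Limit case: nothing silenced -> extraction keeps a growing model."""
    leaf = make_tissue_model(miniplant_model, "leaf")
    expr = make_expression(leaf, TissueProfileSpec("leaf", (), seed=9))
    sub = extract_tissue(leaf, expr)
    assert fba(sub).objective_value > 1e-3


def test_parameter_recovery_over_20_seeds(miniplant_model, truth):
    """Silenced-exclusive reactions are never wrongly retained."""
    leaf = make_tissue_model(miniplant_model, "leaf")
    wrongly_retained = 0
    for seed in range(20):
        expr = make_expression(
            leaf, TissueProfileSpec("leaf", ("suberin", "starch"), seed=seed)
        )
        sub = extract_tissue(leaf, expr)
        off_exclusive = set(truth.suberin_reactions) | {"STS", "STD"}
        wrongly_retained += len(off_exclusive & set(sub.reactions))
        assert fba(sub).objective_value > 1e-3
    assert wrongly_retained == 0


def test_tissue_contrast_photoautotrophy(miniplant_model, presets):
    """Leaf-like grows on light; phellogen-like only heterotrophically."""
    leaf = extract_miniplant_tissue(miniplant_model, "leaf", seed=11)
    photo = fba(set_condition(leaf, presets["photoautotrophic"]))
    assert photo.objective_value > 1e-3

    phellogen = extract_miniplant_tissue(miniplant_model, "phellogen", seed=11)
    photo_ph = fba(set_condition(phellogen, presets["photoautotrophic"]))
    het_ph = fba(set_condition(phellogen, presets["heterotrophic"]))
    assert abs(photo_ph.objective_value) < 1e-6
    assert het_ph.objective_value > 1e-3


def test_expression_determinism(miniplant_model):
    spec = TissueProfileSpec("leaf", ("suberin",), seed=42)
    a = make_expression(miniplant_model, spec)
    b = make_expression(miniplant_model, spec)
    assert a.values == b.values


def test_silenced_genes_below_median(miniplant_model, truth):
    expr = make_expression(
        miniplant_model, TissueProfileSpec("x", ("photosynthesis",), seed=0)
    )
    med = expr.median()
    for gene in truth.gene_groups["photosynthesis"]:
        assert expr.values[gene] < med
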