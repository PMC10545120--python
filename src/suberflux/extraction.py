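"""Expression-driven tissue-specific model extraction.

Pipeline: score every reaction from gene expression through its GPR
(AND -> min, OR -> max), call reactions scoring at or above the dataset
median "core", and extract a flux-consistent submodel that supports every
core reaction, adding an approximately minimal set of non-core reactions
(the FASTCORE scheme: an LP maximizing the number of core reactions above
a flux threshold eps, alternated with an L1-minimization over non-core
reactions).  The biomass reaction is always protected and feasibility is
verified before the submodel is returned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set

import numpy as np
import pandas as pd
from optlang.glpk_interface import Constraint, Model as LPModel, Objective, Variable

from .lp import fba, blocked_reactions
from .model import MetabolicModel

__all__ = [
    "ExpressionDataset",
    "ReactionScoreSet",
    "ExtractionConfig",
    "score_reactions",
    "build_core",
    "fastcore_extract",
    "extract_tissue",
    "read_expression_tsv",
]

log = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    """Normalized expression values (e.g. TMM/CPM counts) for one tissue."""

    tissue: str
    values: Dict[str, float]

    def __post_init__(self) -> None:
        for gene, val in self.values.items():
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"gene {gene}: expression {val} not admissible")

    def median(self, include_zeros: bool = True) -> float:
        vals = [v for v in self.values.values() if include_zeros or v > 0]
        if not vals:
            raise ValueError(f"dataset {self.tissue}: no values for median")
        return float(np.median(vals))


@dataclass
class ReactionScoreSet:
    """Per-reaction expression scores; None marks unmeasured GPRs."""

    scores: Dict[str, Optional[float]]
    no_gene: FrozenSet[str]
    threshold: float


@dataclass
class ExtractionConfig:
    epsilon: float = 1e-4
    protected_reactions: FrozenSet[str] = frozenset()
    keep_all_genes: bool = True
    include_zeros_in_median: bool = True
    threshold: Optional[float] = None  # overrides the median when set
    # retain every parent boundary reaction in the output (at parent
    # bounds) so named condition presets remain applicable afterwards
    keep_exchanges: bool = False

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        self.protected_reactions = frozenset(self.protected_reactions)


def score_reactions(
    model: MetabolicModel,
    expr: ExpressionDataset,
    rule: str = "min-max",
) -> ReactionScoreSet:
    """GPR-aggregate gene expression into reaction scores.

    ``min-max`` (default): AND -> min, OR -> max; unmeasured genes are
    ignored inside OR and poison AND.  ``sum`` adds isoenzyme scores at OR
    nodes instead of taking the max (non-default alternative).
    """
    if rule not in ("min-max", "sum"):
        raise ValueError(f"unknown scoring rule {rule!r}")
    lookup = expr.values.get
    scores: Dict[str, Optional[float]] = {}
    no_gene: Set[str] = set()
    for rid in sorted(model.reactions):
        gpr = model.reactions[rid].gpr
        if not gpr:
            no_gene.add(rid)
            continue
        if rule == "min-max":
            scores[rid] = gpr.evaluate(lookup)
        else:
            scores[rid] = _evaluate_sum(gpr.root, lookup)
    threshold = expr.median(include_zeros=True)
    return ReactionScoreSet(scores, frozenset(no_gene), threshold)


def _evaluate_sum(node, lookup):
    if isinstance(node, str):
        return lookup(node)
    op, children = node
    parts = [_evaluate_sum(c, lookup) for c in children]
    if op == "and":
        if any(p is None for p in parts):
            return None
        return min(parts)
    known = [p for p in parts if p is not None]
    return sum(known) if known else None


def build_core(scores: ReactionScoreSet, cfg: ExtractionConfig) -> Set[str]:
    """Core = reactions scoring >= threshold, plus protected reactions.

    Reactions without genes are never core: they may enter the extracted
    model only as consistency fillers.
    """
    threshold = cfg.threshold if cfg.threshold is not None else scores.threshold
    core = {
        rid
        for rid, s in scores.scores.items()
        if s is not None and s >= threshold
    }
    core |= set(cfg.protected_reactions)
    if not core:
        raise ValueError("empty core: no reaction meets the threshold")
    return core


# ------------------------------------------------------------- FASTCORE LPs

class _FastcoreLP:
    """Shared LP scaffold for the two FASTCORE subproblems."""

    def __init__(self, model: MetabolicModel, epsilon: float):
        self.model = model
        self.eps = epsilon
        self.rxn_ids = sorted(model.reactions)
        self.lb = {r: model.reactions[r].lower_bound for r in self.rxn_ids}
        self.ub = {r: model.reactions[r].upper_bound for r in self.rxn_ids}
        self.irrev = {r for r in self.rxn_ids if self.lb[r] >= 0}
        self.flipped: Set[str] = set()

    def flip(self, rxns: Iterable[str]) -> None:
        for r in rxns:
            self.lb[r], self.ub[r] = -self.ub[r], -self.lb[r]
            self.flipped.symmetric_difference_update({r})

    def _base(self, name: str):
        lp = LPModel(name=name)
        vs = {
            r: Variable(r, lb=self.lb[r], ub=self.ub[r]) for r in self.rxn_ids
        }
        lp.add(list(vs.values()))
        rows: Dict[str, Dict[Variable, float]] = {
            m: {} for m in self.model.metabolites
        }
        sign = lambda r: -1.0 if r in self.flipped else 1.0
        for r in self.rxn_ids:
            for mid, coeff in self.model.reactions[r].stoichiometry.items():
                rows[mid][vs[r]] = coeff * sign(r)
        cons = [
            Constraint(0, lb=0, ub=0, name=f"m_{m}")
            for m in sorted(rows)
            if rows[m]
        ]
        lp.add(cons)
        lp.update()
        for con in cons:
            con.set_linear_coefficients(rows[con.name[2:]])
        return lp, vs

    def lp7(self, J: Set[str]) -> Dict[str, float]:
        """Maximize the number of reactions in J with v >= eps (relaxed)."""
        lp, vs = self._base("lp7")
        zs = {r: Variable(f"z_{r}", lb=0, ub=self.eps) for r in sorted(J)}
        lp.add(list(zs.values()))
        cons = [Constraint(0, lb=0, name=f"c_{r}") for r in sorted(J)]
        lp.add(cons)
        lp.update()
        for r in sorted(J):
            lp.constraints[f"c_{r}"].set_linear_coefficients(
                {vs[r]: 1.0, zs[r]: -1.0}
            )
        lp.objective = Objective(0, direction="max")
        lp.update()
        lp.objective.set_linear_coefficients({z: 1.0 for z in zs.values()})
        if lp.optimize() != "optimal":
            raise RuntimeError("FASTCORE LP7 failed")
        return {r: vs[r].primal for r in self.rxn_ids}

    def lp9(self, K: Set[str], P: Set[str]) -> Dict[str, float]:
        """Minimize L1 flux over P subject to v_k >= eps for k in K."""
        lp, vs = self._base("lp9")
        for r in K:
            vs[r].lb = max(vs[r].lb, self.eps)
        aux = {r: Variable(f"a_{r}", lb=0) for r in sorted(P)}
        lp.add(list(aux.values()))
        cons = []
        for r in sorted(P):
            cons.append(Constraint(0, lb=0, name=f"p_{r}"))
            cons.append(Constraint(0, lb=0, name=f"n_{r}"))
        lp.add(cons)
        lp.update()
        for r in sorted(P):
            lp.constraints[f"p_{r}"].set_linear_coefficients(
                {aux[r]: 1.0, vs[r]: -1.0}
            )
            lp.constraints[f"n_{r}"].set_linear_coefficients(
                {aux[r]: 1.0, vs[r]: 1.0}
            )
        lp.objective = Objective(0, direction="min")
        lp.update()
        lp.objective.set_linear_coefficients({a: 1.0 for a in aux.values()})
        if lp.optimize() != "optimal":
            raise RuntimeError("FASTCORE LP9 failed")
        return {r: vs[r].primal for r in self.rxn_ids}


_SUPPORT_TOL = 1e-9


def _find_sparse_mode(
    lp: _FastcoreLP, J: Set[str], P: Set[str], singleton: bool
) -> Set[str]:
    if not J:
        return set()
    target = {sorted(J)[0]} if singleton else J
    v = lp.lp7(target)
    K = {r for r in target if v[r] >= 0.99 * lp.eps}
    if not K:
        return set()
    v = lp.lp9(K, P)
    # keep the full support of the sparse mode: stoichiometric couplings
    # (e.g. biomass precursor coefficients << 1) make required reactions
    # carry fluxes far below eps, yet dropping them breaks consistency
    return {r for r in lp.rxn_ids if abs(v[r]) > _SUPPORT_TOL}


def fastcore_extract(
    model: MetabolicModel,
    core: Iterable[str],
    epsilon: float = 1e-4,
) -> MetabolicModel:
    """Extract a flux-consistent submodel supporting every core reaction.

    The parent model must already be flux-consistent and the core a subset
    of its reactions; a core reaction that cannot be activated is reported
    as an error, never dropped.
    """
    core = set(core)
    missing = core - set(model.reactions)
    if missing:
        raise KeyError(f"core reactions not in model: {sorted(missing)}")

    lp = _FastcoreLP(model, epsilon)
    J = core & lp.irrev
    P = set(lp.rxn_ids) - core
    A = _find_sparse_mode(lp, J, P, singleton=False)
    if not J <= A:
        raise ValueError(
            f"inconsistent irreversible core reactions: {sorted(J - A)}"
        )
    J = core - A
    flipped = False
    singleton = False
    while J:
        P -= A
        A |= _find_sparse_mode(lp, J, P, singleton)
        if J & A:
            J -= A
            flipped = False
            singleton = False
            continue
        J_rev = ({sorted(J)[0]} if singleton else J) - lp.irrev
        if flipped or not J_rev:
            if singleton:
                raise ValueError(
                    f"core reactions inconsistent in parent model: {sorted(J)}"
                )
            flipped = False
            singleton = True
        else:
            lp.flip(J_rev)
            flipped = True
    return model.submodel(sorted(A), model_id=f"{model.id}_extracted")


def extract_tissue(
    model: MetabolicModel,
    expr: ExpressionDataset,
    cfg: ExtractionConfig = ExtractionConfig(),
    rule: str = "min-max",
) -> MetabolicModel:
    """Full extraction: score -> core -> consistency pre-pass -> FASTCORE.

    Retained reactions keep their complete GPRs.  Growth feasibility of
    the extracted model (under the parent's current bounds) is verified
    before returning; infeasibility raises with a precursor gap report.
    """
    if model.biomass_reaction_id is None:
        raise ValueError("extraction requires a designated biomass reaction")
    scores = score_reactions(model, expr, rule=rule)
    if cfg.threshold is None and not cfg.include_zeros_in_median:
        scores.threshold = expr.median(include_zeros=False)
    protected = set(cfg.protected_reactions) | {model.biomass_reaction_id}
    cfg = ExtractionConfig(
        epsilon=cfg.epsilon,
        protected_reactions=frozenset(protected),
        keep_all_genes=cfg.keep_all_genes,
        include_zeros_in_median=cfg.include_zeros_in_median,
        threshold=cfg.threshold,
        keep_exchanges=cfg.keep_exchanges,
    )
    core = build_core(scores, cfg)

    blocked = blocked_reactions(model, open_boundaries=False)
    blocked_core = core & blocked
    if blocked_core:
        warnings.warn(
            "core reactions blocked in the parent model are unreachable and "
            f"excluded from the core: {sorted(blocked_core)}"
        )
        core -= blocked_core
    consistent = model.submodel(
        sorted(set(model.reactions) - blocked), model_id=f"{model.id}_consistent"
    )
    sub = fastcore_extract(consistent, core, cfg.epsilon)
    sub.id = f"{model.id}_{expr.tissue}"
    sub.biomass_reaction_id = model.biomass_reaction_id
    if cfg.keep_exchanges:
        from .model import Metabolite, find_boundary_reactions

        for rid in find_boundary_reactions(model):
            if rid in sub.reactions:
                continue
            rxn = model.reactions[rid].copy()
            (mid,) = rxn.stoichiometry
            if mid not in sub.metabolites:
                src = model.metabolites[mid]
                sub.add_metabolite(
                    Metabolite(mid, name=src.name, compartment=src.compartment,
                               formula=src.formula, charge=src.charge)
                )
            sub.add_reaction(rxn)

    growth = fba(sub)
    if not growth.ok or growth.objective_value <= cfg.epsilon / 10:
        from .protocols import biomass_precursor_gaps

        gaps = biomass_precursor_gaps(sub)
        raise ValueError(
            f"tissue {expr.tissue}: biomass infeasible after extraction; "
            f"unserviced precursors: {gaps}"
        )
    return sub


def read_expression_tsv(path: str, tissue: str) -> ExpressionDataset:
    """Read a gene-by-tissue TSV (column ``gene_id`` plus one per tissue)."""
    df = pd.read_csv(path, sep="\t")
    if tissue not in df.columns:
        raise KeyError(f"tissue column {tissue!r} not in {path}")
    return ExpressionDataset(
        tissue, dict(zip(df["gene_id"], df[tissue].astype(float)))
    )
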