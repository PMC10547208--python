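"""Conversion of a metabolic model to irreversible, OR-free form.

The expression-usage constraint ties the summed flux of the reactions a
gene supports to that gene's expression level.  For the sum to be
meaningful every flux must be nonnegative and every reaction must carry a
single conjunctive gene rule, so the model is rewritten in two steps:

1. every reversible reaction is split into a forward and a backward copy
   (negated column), both with nonnegative bounds;
2. every OR rule is expanded to disjunctive normal form and the reaction is
   duplicated once per disjunct (isozyme copies), each copy keeping one
   conjunct.

AND conjuncts are deliberately NOT split: an isozyme copy's flux counts
against every member of its enzyme complex, so any complex member can limit
the reaction.

The registry of opposite-direction groups records, per reversible source
reaction, all forward copies and all backward copies; the MILP later forbids
simultaneous use of the two sides to exclude expression-inflating cycles.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .model_io import StoichiometricModel, compute_exchange_flags

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionOrigin",
    "ReversibleGroup",
    "IrreversibleModel",
    "split_reversible",
    "expand_gpr_without_or",
    "build_gene_map",
    "convert_model",
    "gpr_to_dnf",
]

#: Default cap on DNF disjuncts per reaction; deep nesting aborts loudly.
DEFAULT_DNF_CAP = 32


@dataclass(frozen=True)
class ReactionOrigin:
    """Provenance of a converted reaction column."""

    source_id: str
    direction: str  # "f" or "b"
    isozyme_index: int = 0


@dataclass
class ReversibleGroup:
    """All converted copies of one reversible source reaction, by side."""

    source_id: str
    forward: list[int]
    backward: list[int]


@dataclass
class IrreversibleModel:
    """A converted model plus provenance, gene map and direction registry.

    ``gene_map`` (K_j) maps each gene to the converted-reaction indices
    whose conjunctive rule contains it; it is populated by
    :func:`build_gene_map` once an expression profile is known.
    """

    base: StoichiometricModel
    origin: list[ReactionOrigin]
    reversible_groups: list[ReversibleGroup] = field(default_factory=list)
    gene_map: dict[str, list[int]] = field(default_factory=dict)

    @property
    def opposite_pairs(self) -> list[tuple[int, frozenset[int]]]:
        """Per forward copy, the set of all opposing backward copies."""
        pairs = []
        for grp in self.reversible_groups:
            back = frozenset(grp.backward)
            for fi in grp.forward:
                pairs.append((fi, back))
        return pairs

    def indices_of_source(self, source_id: str) -> list[int]:
        return [
            i for i, o in enumerate(self.origin) if o.source_id == source_id
        ]

    def validate(self, require_or_free: bool = True) -> None:
        if np.any(self.base.lower_bound < 0):
            raise ValueError("converted model has a negative lower bound")
        if require_or_free:
            for rule in self.base.gene_rules:
                if "or" in rule.lower().split():
                    raise ValueError(f"OR survives conversion in rule {rule!r}")
        S = self.base.S.tocsc()
        for grp in self.reversible_groups:
            for fi, bi in itertools.product(grp.forward, grp.backward):
                delta = (S.getcol(fi) + S.getcol(bi)).toarray()
                if np.any(np.abs(delta) > 1e-12):
                    raise ValueError(
                        f"columns {fi} and {bi} of {grp.source_id} are not "
                        f"exact negatives"
                    )
        for gene, idx in self.gene_map.items():
            if not idx:
                raise ValueError(f"gene {gene} retained with empty K_j")

    def copy(self) -> "IrreversibleModel":
        return IrreversibleModel(
            base=self.base.copy(),
            origin=list(self.origin),
            reversible_groups=[
                ReversibleGroup(g.source_id, list(g.forward), list(g.backward))
                for g in self.reversible_groups
            ],
            gene_map={g: list(v) for g, v in self.gene_map.items()},
        )


# ---------------------------------------------------------------------------
# GPR parsing
# ---------------------------------------------------------------------------

def gpr_to_dnf(rule: str, cap: int = DEFAULT_DNF_CAP) -> list[frozenset[str]]:
    """Rewrite a Boolean gene rule as a list of conjunctive gene sets.

    Returns one frozenset of genes per disjunct (isozyme); an empty rule
    yields an empty list.  Raises if the rule cannot be parsed or the DNF
    exceeds ``cap`` disjuncts.
    """
    if not rule or not rule.strip():
        return []
    from cobra.core.gene import GPR

    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # cobra warns instead of raising
            gpr = GPR.from_string(rule)
    except Exception as exc:
        raise ValueError(f"unparseable gene rule {rule!r}: {exc}") from exc
    if gpr.body is None:
        # non-empty text that parsed to nothing is malformed, not "no rule"
        raise ValueError(f"unparseable gene rule {rule!r}")

    import ast

    def expand(node) -> list[frozenset[str]]:
        if isinstance(node, ast.Name):
            return [frozenset([node.id])]
        if isinstance(node, ast.BoolOp):
            parts = [expand(v) for v in node.values]
            if isinstance(node.op, ast.Or):
                out = [d for p in parts for d in p]
            else:  # And: cartesian product of disjunct lists
                out = [frozenset().union(*combo) for combo in itertools.product(*parts)]
            if len(out) > cap:
                raise ValueError(
                    f"rule {rule!r} expands to {len(out)} disjuncts "
                    f"(cap {cap}); refusing to truncate"
                )
            return out
        raise ValueError(f"unparseable gene rule {rule!r}")

    return expand(gpr.body)


def conjunct_to_rule(conjunct: frozenset[str]) -> str:
    return " and ".join(sorted(conjunct))


# ---------------------------------------------------------------------------
# Conversion steps
# ---------------------------------------------------------------------------

def _rebuild(
    model: StoichiometricModel,
    cols: list[np.ndarray],
    ids: list[str],
    lbs: list[float],
    ubs: list[float],
    objs: list[float],
    rules: list[str],
) -> StoichiometricModel:
    S = sp.csc_matrix(np.column_stack(cols)) if cols else sp.csc_matrix((model.n_metabolites, 0))
    new = StoichiometricModel(
        metabolite_ids=list(model.metabolite_ids),
        reaction_ids=ids,
        S=S,
        lower_bound=np.array(lbs, float),
        upper_bound=np.array(ubs, float),
        objective_coeffs=np.array(objs, float),
        rhs=model.rhs.copy(),
        gene_rules=rules,
        genes=list(model.genes),
        exchange_flags=compute_exchange_flags(S),
        biomass_reaction=model.biomass_reaction,
    )
    return new


def split_reversible(model: StoichiometricModel) -> IrreversibleModel:
    """Split every reversible reaction into forward/backward copies.

    A reaction running only backward (lb < 0, ub <= 0) is normalized by
    flipping its direction; inconsistent bounds raise.  Irreversible
    reactions pass through untouched.  Each split registers one
    opposite-direction group.
    """
    S = model.S.tocsc()
    cols: list[np.ndarray] = []
    ids: list[str] = []
    lbs: list[float] = []
    ubs: list[float] = []
    objs: list[float] = []
    rules: list[str] = []
    origin: list[ReactionOrigin] = []
    groups: list[ReversibleGroup] = []

    for j, rid in enumerate(model.reaction_ids):
        col = S.getcol(j).toarray().ravel()
        lb, ub = model.lower_bound[j], model.upper_bound[j]
        c = model.objective_coeffs[j]
        rule = model.gene_rules[j]
        if lb > ub:
            raise ValueError(f"reaction {rid}: inconsistent bounds [{lb}, {ub}]")
        if lb >= 0:
            cols.append(col)
            ids.append(rid)
            lbs.append(lb)
            ubs.append(ub)
            objs.append(c)
            rules.append(rule)
            origin.append(ReactionOrigin(rid, "f"))
        elif ub <= 0:
            # runs only backward: flip direction, keep a single column
            cols.append(-col)
            ids.append(rid)
            lbs.append(-ub)
            ubs.append(-lb)
            objs.append(-c)
            rules.append(rule)
            origin.append(ReactionOrigin(rid, "b"))
        else:
            fwd = len(ids)
            cols.append(col)
            ids.append(f"{rid}_f")
            lbs.append(0.0)
            ubs.append(ub)
            objs.append(c)
            rules.append(rule)
            origin.append(ReactionOrigin(rid, "f"))
            bwd = len(ids)
            cols.append(-col)
            ids.append(f"{rid}_b")
            lbs.append(0.0)
            ubs.append(-lb)
            objs.append(-c)
            rules.append(rule)
            origin.append(ReactionOrigin(rid, "b"))
            groups.append(ReversibleGroup(rid, [fwd], [bwd]))

    new = _rebuild(model, cols, ids, lbs, ubs, objs, rules)
    if model.biomass_reaction is not None and model.biomass_reaction not in new.reaction_ids:
        new.biomass_reaction = f"{model.biomass_reaction}_f"
    irr = IrreversibleModel(base=new, origin=origin, reversible_groups=groups)
    irr.validate(require_or_free=False)
    return irr


def expand_gpr_without_or(
    model: IrreversibleModel, cap: int = DEFAULT_DNF_CAP
) -> IrreversibleModel:
    """Duplicate reactions per DNF disjunct so no OR rule survives.

    A reaction with k disjuncts becomes k identical columns, each carrying
    one conjunct; bounds and objective are copied verbatim (the isozyme
    copies jointly inherit the original capacity).  Direction groups are
    extended so every forward copy opposes ALL backward copies of the same
    source reaction.
    """
    base = model.base
    S = base.S.tocsc()
    cols: list[np.ndarray] = []
    ids: list[str] = []
    lbs: list[float] = []
    ubs: list[float] = []
    objs: list[float] = []
    rules: list[str] = []
    origin: list[ReactionOrigin] = []
    sides: dict[str, dict[str, list[int]]] = {}

    reversible_sources = {g.source_id for g in model.reversible_groups}

    for j, rid in enumerate(base.reaction_ids):
        col = S.getcol(j).toarray().ravel()
        disjuncts = gpr_to_dnf(base.gene_rules[j], cap=cap)
        orig = model.origin[j]
        if len(disjuncts) <= 1:
            copies = [(rid, disjuncts[0] if disjuncts else None, 0)]
        else:
            copies = [
                (f"{rid}#{k + 1}", conj, k) for k, conj in enumerate(disjuncts)
            ]
        for new_id, conj, k in copies:
            idx = len(ids)
            cols.append(col)
            ids.append(new_id)
            lbs.append(float(base.lower_bound[j]))
            ubs.append(float(base.upper_bound[j]))
            objs.append(float(base.objective_coeffs[j]))
            rules.append(conjunct_to_rule(conj) if conj else "")
            origin.append(ReactionOrigin(orig.source_id, orig.direction, k))
            if orig.source_id in reversible_sources:
                side = sides.setdefault(orig.source_id, {"f": [], "b": []})
                side[orig.direction].append(idx)

    new = _rebuild(base, cols, ids, lbs, ubs, objs, rules)
    if base.biomass_reaction is not None and base.biomass_reaction not in new.reaction_ids:
        # biomass itself expanded (unusual); point at the first copy
        new.biomass_reaction = f"{base.biomass_reaction}#1"
    groups = [
        ReversibleGroup(src, side["f"], side["b"])
        for src, side in sides.items()
    ]
    out = IrreversibleModel(base=new, origin=origin, reversible_groups=groups)
    out.validate()
    return out


def build_gene_map(
    model: IrreversibleModel, profile=None
) -> IrreversibleModel:
    """Populate K_j: gene -> converted-reaction indices whose rule holds it.

    If ``profile`` is given, measured genes absent from every rule are
    reported with a warning (they are ignored by constraint assembly); the
    count of mapped AND measured genes is the P of the adaptation score.
    """
    out = model.copy()
    gene_map: dict[str, list[int]] = {}
    for idx, rule in enumerate(out.base.gene_rules):
        if not rule:
            continue
        for gene in rule.split(" and "):
            gene = gene.strip()
            if gene:
                gene_map.setdefault(gene, []).append(idx)
    out.gene_map = gene_map
    if profile is not None:
        orphans = sorted(profile.genes - set(gene_map))
        if orphans:
            logger.warning(
                "%d measured genes are absent from every gene rule and are "
                "ignored: %s%s",
                len(orphans),
                ", ".join(orphans[:10]),
                "..." if len(orphans) > 10 else "",
            )
    out.validate()
    return out


def convert_model(
    model: StoichiometricModel, cap: int = DEFAULT_DNF_CAP
) -> IrreversibleModel:
    """Full conversion: split reversibles, expand ORs, build the gene map."""
    return build_gene_map(expand_gpr_without_or(split_reversible(model), cap=cap))


def mapped_measured_genes(model: IrreversibleModel, profile) -> list[str]:
    """Genes both mapped to a reaction and measured in the profile (sorted).

    Its length is P, the denominator of the adaptation score.
    """
    if not model.gene_map:
        raise ValueError("gene map not built; call build_gene_map first")
    return sorted(set(model.gene_map) & profile.genes)
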