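"""Small fixture networks, simulated expression profiles, and an
exhaustive-enumeration oracle for the adaptation score.

The oracle answers the same question as the MILP — how many measured genes
can simultaneously convert all their expression into flux — by brute force:
it enumerates gene subsets (largest first) and, per subset, every
orientation of the reversible reactions, testing plain LP feasibility of
the resulting system.  It shares no code with the MILP assembly, so
agreement between the two is a real check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .milp import DEFAULT_TOL, FLUX_CAP, MediumSpec, apply_medium
from .model_io import ExpressionProfile, StoichiometricModel, compute_exchange_flags
from .transform import (
    IrreversibleModel,
    build_gene_map,
    convert_model,
    mapped_measured_genes,
)

__all__ = [
    "ToySpec",
    "toy1_model",
    "toy1_profiles",
    "toy1_medium",
    "make_toy_model",
    "random_toy_model",
    "simulate_expression_profiles",
    "SimulatedProfiles",
    "OracleResult",
    "brute_force_adaptation_score",
]

MAX_ORACLE_GENES = 12


# ---------------------------------------------------------------------------
# Toy model construction
# ---------------------------------------------------------------------------

def _assemble(metabolites, reactions) -> StoichiometricModel:
    """Build a model from (id, {met: coeff}, lb, ub, rule) reaction tuples."""
    met_index = {m: i for i, m in enumerate(metabolites)}
    n = len(reactions)
    S = np.zeros((len(metabolites), n))
    ids, lbs, ubs, rules = [], [], [], []
    genes: set[str] = set()
    for j, (rid, stoich, lb, ub, rule) in enumerate(reactions):
        ids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        rules.append(rule)
        for met, coeff in stoich.items():
            S[met_index[met], j] = coeff
        from .model_io import genes_in_rule

        genes |= genes_in_rule(rule)
    Ssp = sp.csc_matrix(S)
    return StoichiometricModel(
        metabolite_ids=list(metabolites),
        reaction_ids=ids,
        S=Ssp,
        lower_bound=np.array(lbs, float),
        upper_bound=np.array(ubs, float),
        objective_coeffs=np.zeros(n),
        rhs=np.zeros(len(metabolites)),
        gene_rules=rules,
        genes=sorted(genes),
        exchange_flags=compute_exchange_flags(Ssp),
        biomass_reaction=None,
    )


def toy1_model(growth: bool = False) -> StoichiometricModel:
    """The canonical worked instance TOY1.

    A uptake feeds two isozyme-like parallel steps (R1 with gene g1, R2
    with g2) into B; a reversible step R3 (gene g3) links B and C; C is
    secreted.  With WT expression (g1=2, g2=4, g3=5) and C=1 the three
    genes cannot all run at capacity (inflow 6 vs a g3 cap of 5), so the
    adaptation score is 2 with optimal patterns {g1,g3} and {g2,g3}.

    With ``growth=True`` the C-secretion exchange is declared the biomass
    reaction (yield 1), giving the closed-form growth rate
    min(E_g1+E_g2, E_g3) * C for small C.
    """
    model = _assemble(
        metabolites=["A", "B", "C"],
        reactions=[
            ("EX_A", {"A": -1}, -FLUX_CAP, 0.0, ""),      # uptake only
            ("R1", {"A": -1, "B": 1}, 0.0, FLUX_CAP, "g1"),
            ("R2", {"A": -1, "B": 1}, 0.0, FLUX_CAP, "g2"),
            ("R3", {"B": -1, "C": 1}, -FLUX_CAP, FLUX_CAP, "g3"),
            ("EX_C", {"C": -1}, 0.0, FLUX_CAP, ""),       # secretion only
        ],
    )
    if growth:
        model.biomass_reaction = "EX_C"
        model.objective_coeffs[model.reaction_index("EX_C")] = 1.0
    return model


def toy1_medium() -> MediumSpec:
    return MediumSpec(unlimited_exchanges=frozenset({"EX_A"}), carbon_source="EX_A")


def toy1_profiles() -> tuple[ExpressionProfile, ExpressionProfile]:
    """WT (g1=2, g2=4, g3=5) and an evolved profile with g2 shifted to 6."""
    wt = ExpressionProfile("WT", {"g1": 2.0, "g2": 4.0, "g3": 5.0})
    ev = ExpressionProfile("EV1", {"g1": 2.0, "g2": 6.0, "g3": 5.0})
    return wt, ev


@dataclass
class ToySpec:
    """Recipe for a deterministic random fixture network.

    A linear pathway of ``n_chain`` interior metabolites with uptake and
    secretion exchanges; optional structural templates: a parallel branch
    (two reactions, different genes, same conversion), an isozyme OR rule,
    an enzyme-complex AND rule, and extra reversible steps.  Expression is
    drawn uniformly from [1, 10] and rounded to 2 decimals.
    """

    n_chain: int = 3
    n_reversible: int = 1
    with_branch: bool = True
    with_isozyme_rule: bool = False
    with_complex_rule: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chain < 2:
            raise ValueError("need at least 2 chain metabolites")
        if self.n_reversible > self.n_chain - 1:
            raise ValueError("more reversible steps than chain reactions")


def make_toy_model(spec: ToySpec) -> tuple[StoichiometricModel, ExpressionProfile]:
    """Deterministically generate a fixture model and a WT profile.

    Every generated gene maps to at least one reaction, and b = 0 keeps the
    all-zero flux vector feasible by construction.
    """
    rng = np.random.default_rng(spec.seed)
    mets = [f"M{i + 1}" for i in range(spec.n_chain)]
    reactions = [("EX_in", {"M1": -1}, -FLUX_CAP, 0.0, "")]
    gene_counter = itertools.count(1)
    genes: list[str] = []

    def next_gene() -> str:
        g = f"g{next(gene_counter)}"
        genes.append(g)
        return g

    reversible_steps = set(
        rng.choice(spec.n_chain - 1, size=spec.n_reversible, replace=False)
    )
    for i in range(spec.n_chain - 1):
        lb = -FLUX_CAP if i in reversible_steps else 0.0
        if spec.with_complex_rule and i == spec.n_chain - 2:
            rule = f"{next_gene()} and {next_gene()}"
        elif spec.with_isozyme_rule and i == 0:
            rule = f"{next_gene()} or {next_gene()}"
        else:
            rule = next_gene()
        reactions.append(
            (f"R{i + 1}", {mets[i]: -1, mets[i + 1]: 1}, lb, FLUX_CAP, rule)
        )
    if spec.with_branch:
        # a second route for the first conversion, carried by its own gene
        reactions.append(
            ("Rb", {mets[0]: -1, mets[1]: 1}, 0.0, FLUX_CAP, next_gene())
        )
    reactions.append((f"EX_out", {mets[-1]: -1}, 0.0, FLUX_CAP, ""))

    model = _assemble(mets, reactions)
    profile = ExpressionProfile(
        "WT", {g: float(np.round(rng.uniform(1, 10), 2)) for g in genes}
    )
    return model, profile


def random_toy_model(seed: int) -> tuple[StoichiometricModel, ExpressionProfile, MediumSpec]:
    """A seeded random fixture in the oracle-checkable size range."""
    rng = np.random.default_rng(seed)
    n_chain = int(rng.integers(3, 5))
    spec = ToySpec(
        n_chain=n_chain,
        n_reversible=min(int(rng.integers(0, 3)), n_chain - 1, 2),
        with_branch=bool(rng.random() < 0.7),
        with_isozyme_rule=bool(rng.random() < 0.5),
        with_complex_rule=bool(rng.random() < 0.4),
        seed=seed,
    )
    model, profile = make_toy_model(spec)
    medium = MediumSpec(
        unlimited_exchanges=frozenset({"EX_in"}), carbon_source="EX_in"
    )
    return model, profile, medium


# ---------------------------------------------------------------------------
# Simulated expression profiles
# ---------------------------------------------------------------------------

@dataclass
class SimulatedProfiles:
    """WT plus evolved profiles with the ground-truth shifted genes."""

    wild_type: ExpressionProfile
    evolved: list[ExpressionProfile]
    shifted_genes: frozenset[str]
    shift: float

    @property
    def all_profiles(self) -> list[ExpressionProfile]:
        return [self.wild_type, *self.evolved]


def simulate_expression_profiles(
    wild_type: ExpressionProfile,
    shifted_genes: set[str],
    shift: float,
    n_evolved: int,
    noise: float = 0.0,
    seed: int = 0,
) -> SimulatedProfiles:
    """Evolved profiles = WT + ``shift`` on the shifted genes + seeded noise.

    The default noise spread of 0 gives exact arithmetic profiles; values
    are clipped at 0 to stay valid expression levels.
    """
    if not np.isfinite(shift):
        raise ValueError("shift must be finite")
    missing = set(shifted_genes) - wild_type.genes
    if missing:
        raise ValueError(f"shifted genes not in profile: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    evolved = []
    for k in range(n_evolved):
        values = {}
        for gene, base in wild_type.values.items():
            v = base + (shift if gene in shifted_genes else 0.0)
            if noise:
                v += rng.normal(0.0, noise)
            values[gene] = max(0.0, float(v))
        evolved.append(ExpressionProfile(f"EV{k + 1}", values))
    return SimulatedProfiles(
        wild_type=wild_type,
        evolved=evolved,
        shifted_genes=frozenset(shifted_genes),
        shift=shift,
    )


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleResult:
    score: int
    P: int
    optimal_patterns: list[frozenset[str]] = field(default_factory=list)
    target_optimum: float | None = None


def _orientation_bounds(irr: IrreversibleModel, orientation) -> tuple[np.ndarray, np.ndarray]:
    lb = irr.base.lower_bound.copy()
    ub = irr.base.upper_bound.copy()
    for grp, side in zip(irr.reversible_groups, orientation):
        closed = grp.backward if side == 0 else grp.forward
        for i in closed:
            lb[i] = 0.0
            ub[i] = 0.0
    return lb, ub


def _feasible(irr, genes, E_cap, subset, lb, ub, q=None, q_value=None,
              objective=None, tol=DEFAULT_TOL):
    """LP over flux variables only: equality usage for subset, cap otherwise."""
    base = irr.base
    n = base.n_reactions
    A_eq = [base.S]
    b_lo = [base.rhs]
    b_hi = [base.rhs]
    A_ub_rows, ub_vals = [], []
    for gene in genes:
        row = np.zeros(n)
        row[irr.gene_map[gene]] = 1.0
        if gene in subset:
            A_eq.append(sp.csr_matrix(row))
            b_lo.append([E_cap[gene]])
            b_hi.append([E_cap[gene]])
        else:
            A_ub_rows.append(row)
            ub_vals.append(E_cap[gene])
    if q is not None and q_value is not None:
        slack = max(tol, tol * abs(q_value))
        A_ub_rows.append(q)
        ub_vals.append(q_value + slack)
        A_ub_rows.append(-q)
        ub_vals.append(-(q_value - slack))
    A_eq_m = sp.vstack([sp.csr_matrix(a) for a in A_eq])
    b_eq = np.concatenate([np.atleast_1d(np.asarray(b)).ravel() for b in b_lo])
    kwargs = dict(
        c=np.zeros(n) if objective is None else objective,
        A_eq=A_eq_m,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if A_ub_rows:
        kwargs["A_ub"] = np.vstack(A_ub_rows)
        kwargs["b_ub"] = np.array(ub_vals)
    res = linprog(**kwargs)
    return res


def brute_force_adaptation_score(
    model: StoichiometricModel | IrreversibleModel,
    profile: ExpressionProfile,
    C: float,
    medium: MediumSpec | None = None,
    fixed_target: str | None = None,
    tol: float = DEFAULT_TOL,
) -> OracleResult:
    """Exhaustively enumerate gene subsets to find the adaptation score.

    For every subset G (largest cardinality first) and every orientation of
    the reversible reactions, an LP checks whether all genes in G can run
    at exactly full expression capacity while the rest stay at or below
    theirs.  The score is the largest |G| that is feasible; all feasible
    subsets of that cardinality are returned as the optimal patterns.

    Raises when more than 12 genes are mapped — use the MILP instead.
    """
    if isinstance(model, StoichiometricModel):
        irr = convert_model(model)
    else:
        irr = model if model.gene_map else build_gene_map(model)
    if medium is not None:
        irr = apply_medium(irr, medium)
    genes = mapped_measured_genes(irr, profile)
    P = len(genes)
    if P > MAX_ORACLE_GENES:
        raise ValueError(f"{P} genes mapped; enumeration capped at "
                         f"{MAX_ORACLE_GENES} — use the MILP")
    E_cap = {g: float(profile[g]) * C for g in genes}
    orientations = list(
        itertools.product([0, 1], repeat=len(irr.reversible_groups))
    )

    q = q_value = None
    if fixed_target is not None:
        q = np.zeros(irr.base.n_reactions)
        if fixed_target in irr.gene_map:
            q[irr.gene_map[fixed_target]] = 1.0
        else:
            idx = irr.indices_of_source(fixed_target)
            if not idx:
                raise KeyError(f"target {fixed_target!r} not in model")
            q[idx] = 1.0
        best = 0.0
        for orientation in orientations:
            lb, ub = _orientation_bounds(irr, orientation)
            res = _feasible(irr, genes, E_cap, frozenset(), lb, ub,
                            objective=-q, tol=tol)
            if res.status == 0:
                best = max(best, float(-res.fun))
        q_value = best

    patterns: list[frozenset[str]] = []
    score = 0
    for size in range(P, -1, -1):
        for combo in itertools.combinations(genes, size):
            subset = frozenset(combo)
            for orientation in orientations:
                lb, ub = _orientation_bounds(irr, orientation)
                res = _feasible(irr, genes, E_cap, subset, lb, ub,
                                q=q, q_value=q_value, tol=tol)
                if res.status == 0:
                    patterns.append(subset)
                    break
        if patterns:
            score = size
            break
    return OracleResult(
        score=score, P=P, optimal_patterns=patterns, target_optimum=q_value
    )
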