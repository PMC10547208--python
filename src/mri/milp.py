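"""Assembly and solution of the adaptation-score MILP.

The problem maximizes the number of measured genes whose expression is
fully converted into metabolic flux.  For each mapped, measured gene j the
expression-usage constraint

    sum_{i in K_j} v_i + alpha_j = E_j * C

holds with a nonnegative slack alpha_j (unused expression capacity,
mmol/gDCW/h); an indicator z_j in {0,1} with

    alpha_j - U_j * z_j <= 0,   U_j = E_j * C

forces z_j = 1 whenever any capacity is unused.  Minimizing sum z under
steady-state stoichiometry, medium bounds and direction exclusivity yields

    adaptation score = P - min sum_j z_j,

the maximum number of genes usable at full capacity simultaneously.  The
per-gene big-M U_j = E_j*C is the tightest valid constant because
alpha_j <= E_j*C in every feasible point.

Direction exclusivity: per reversible source reaction a binary pair
(w_f, w_b) with w_f + w_b = 1 gates all forward copies (v <= 1000 * w_f)
and all backward copies (v <= 1000 * w_b), excluding the two-way cycles
that would otherwise inflate the score.

All solves go through scipy's HiGHS interface.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .transform import IrreversibleModel, mapped_measured_genes

logger = logging.getLogger(__name__)

__all__ = [
    "MediumSpec",
    "MRIProblem",
    "AdaptationResult",
    "apply_medium",
    "build_mri_problem",
    "solve_adaptation_score",
    "conditional_adaptation_score",
    "full_usage_gene_set",
]

#: Flux cap shared by model bounds and the direction-exclusivity big-M.
FLUX_CAP = 1000.0

#: Default zero/feasibility/integrality tolerance (mmol/gDCW/h).
DEFAULT_TOL = 1e-6

#: M9 minimal-medium components opened for uptake besides the carbon source
#: (iJO1366 exchange identifiers): ammonium, water, oxygen, phosphate,
#: sulfate and proton.
M9_BASE_EXCHANGES = (
    "EX_nh4_e",
    "EX_h2o_e",
    "EX_o2_e",
    "EX_pi_e",
    "EX_so4_e",
    "EX_h_e",
)


@dataclass
class MediumSpec:
    """Growth-medium bounds expressed on exchange reactions.

    ``unlimited_exchanges`` get an uptake bound of 1000 mmol/gDCW/h
    (unlimited condition); every other exchange is closed for uptake.
    Secretion of every exchange is capped at 1000.
    """

    unlimited_exchanges: frozenset[str]
    carbon_source: str

    def __post_init__(self) -> None:
        self.unlimited_exchanges = frozenset(self.unlimited_exchanges)
        if self.carbon_source not in self.unlimited_exchanges:
            raise ValueError(
                f"carbon source {self.carbon_source!r} must be in "
                f"unlimited_exchanges"
            )

    @classmethod
    def m9(cls, carbon_source: str) -> "MediumSpec":
        """M9 minimal medium with the given carbon-source exchange."""
        return cls(
            unlimited_exchanges=frozenset(M9_BASE_EXCHANGES) | {carbon_source},
            carbon_source=carbon_source,
        )


def apply_medium(model: IrreversibleModel, medium: MediumSpec) -> IrreversibleModel:
    """Return a copy of the converted model with medium bounds applied.

    On the converted model an exchange's uptake direction is the copy whose
    single stoichiometric coefficient is positive (it produces the
    metabolite internally); its secretion direction has a negative one.
    """
    out = model.copy()
    base = out.base
    S = base.S.tocsc()

    source_exchanges: dict[str, list[int]] = {}
    for idx, flag in enumerate(base.exchange_flags):
        if flag and S.getcol(idx).nnz > 0:
            source_exchanges.setdefault(model.origin[idx].source_id, []).append(idx)

    missing = medium.unlimited_exchanges - set(source_exchanges)
    if missing:
        hints = {
            name: difflib.get_close_matches(name, source_exchanges, n=3)
            for name in sorted(missing)
        }
        raise KeyError(f"exchanges absent from model: {hints}")

    for src, indices in source_exchanges.items():
        for idx in indices:
            coeff = S.getcol(idx).data
            is_uptake = coeff[0] > 0
            if is_uptake:
                base.upper_bound[idx] = (
                    FLUX_CAP if src in medium.unlimited_exchanges else 0.0
                )
                base.lower_bound[idx] = min(base.lower_bound[idx], base.upper_bound[idx])
            else:
                base.upper_bound[idx] = FLUX_CAP
    return out


@dataclass
class MRIProblem:
    """The assembled MILP: converted model, profile, C and tolerances."""

    model: IrreversibleModel
    profile: object  # ExpressionProfile
    C: float
    genes: list[str] = field(default_factory=list)  # mapped & measured, sorted
    tol: float = DEFAULT_TOL
    time_limit: float | None = None  # seconds per MILP solve

    @property
    def P(self) -> int:
        return len(self.genes)

    @property
    def n_flux(self) -> int:
        return self.model.base.n_reactions

    @property
    def n_groups(self) -> int:
        return len(self.model.reversible_groups)

    # variable layout: [v (n_flux) | alpha (P) | z (P) | w_f,w_b per group]
    @property
    def n_vars(self) -> int:
        return self.n_flux + 2 * self.P + 2 * self.n_groups

    def var_slices(self):
        n, P, R = self.n_flux, self.P, self.n_groups
        return (
            slice(0, n),
            slice(n, n + P),
            slice(n + P, n + 2 * P),
            slice(n + 2 * P, n + 2 * P + 2 * R),
        )

    def expression_cap(self, gene: str) -> float:
        return float(self.profile[gene]) * self.C

    def usage_vector(self, target: str) -> np.ndarray:
        """Coefficient vector (over flux variables) of a target's usage.

        A gene target sums the fluxes of K_j; a reaction target sums the
        fluxes of every converted copy of that source reaction; a converted
        reaction identifier selects its single column.
        """
        q = np.zeros(self.n_flux)
        if target in self.model.gene_map:
            q[self.model.gene_map[target]] = 1.0
            return q
        idx = self.model.indices_of_source(target)
        if idx:
            q[idx] = 1.0
            return q
        if target in self.model.base.reaction_ids:
            q[self.model.base.reaction_ids.index(target)] = 1.0
            return q
        raise KeyError(f"target {target!r} is neither a mapped gene nor a reaction")

    # -- constraint assembly -------------------------------------------------

    def constraints(self) -> list[LinearConstraint]:
        base = self.model.base
        n, P, R = self.n_flux, self.P, self.n_groups
        nv = self.n_vars
        sv, sa, sz, sw = self.var_slices()
        cons: list[LinearConstraint] = []

        # steady state S v = b
        A = sp.hstack(
            [base.S.tocsr(), sp.csr_matrix((base.n_metabolites, nv - n))]
        )
        cons.append(LinearConstraint(A, base.rhs, base.rhs))

        if P:
            # usage: sum_{K_j} v + alpha_j = E_j C
            rows, cols, vals = [], [], []
            caps = np.zeros(P)
            for g, gene in enumerate(self.genes):
                caps[g] = self.expression_cap(gene)
                if caps[g] < self.tol:
                    logger.warning(
                        "gene %s: expression capacity %.3g below tolerance",
                        gene,
                        caps[g],
                    )
                for i in self.model.gene_map[gene]:
                    rows.append(g)
                    cols.append(i)
                    vals.append(1.0)
                rows.append(g)
                cols.append(sa.start + g)
                vals.append(1.0)
            A2 = sp.csr_matrix((vals, (rows, cols)), shape=(P, nv))
            cons.append(LinearConstraint(A2, caps, caps))

            # indicator: alpha_j - U_j z_j <= 0 with U_j = E_j C
            rows, cols, vals = [], [], []
            for g in range(P):
                rows += [g, g]
                cols += [sa.start + g, sz.start + g]
                vals += [1.0, -caps[g]]
            A3 = sp.csr_matrix((vals, (rows, cols)), shape=(P, nv))
            cons.append(LinearConstraint(A3, -np.inf, np.zeros(P)))

        if R:
            # exclusivity: v_i <= 1000 w_side; w_f + w_b = 1
            rows, cols, vals = [], [], []
            r = 0
            for gi, grp in enumerate(self.model.reversible_groups):
                wf = sw.start + 2 * gi
                wb = wf + 1
                for i in grp.forward:
                    rows += [r, r]
                    cols += [i, wf]
                    vals += [1.0, -FLUX_CAP]
                    r += 1
                for i in grp.backward:
                    rows += [r, r]
                    cols += [i, wb]
                    vals += [1.0, -FLUX_CAP]
                    r += 1
            A4 = sp.csr_matrix((vals, (rows, cols)), shape=(r, nv))
            cons.append(LinearConstraint(A4, -np.inf, np.zeros(r)))

            rows, cols, vals = [], [], []
            for gi in range(R):
                rows += [gi, gi]
                cols += [sw.start + 2 * gi, sw.start + 2 * gi + 1]
                vals += [1.0, 1.0]
            A5 = sp.csr_matrix((vals, (rows, cols)), shape=(R, nv))
            cons.append(LinearConstraint(A5, np.ones(R), np.ones(R)))

        return cons

    def bounds(self) -> Bounds:
        base = self.model.base
        lb = np.concatenate(
            [
                base.lower_bound,
                np.zeros(self.P),
                np.zeros(self.P),
                np.zeros(2 * self.n_groups),
            ]
        )
        ub = np.concatenate(
            [
                base.upper_bound,
                np.array([self.expression_cap(g) for g in self.genes]),
                np.ones(self.P),
                np.ones(2 * self.n_groups),
            ]
        )
        return Bounds(lb, ub)

    def integrality(self, relax_z: bool = False) -> np.ndarray:
        kind = np.zeros(self.n_vars)
        sv, sa, sz, sw = self.var_slices()
        if not relax_z:
            kind[sz] = 1
        kind[sw] = 1
        return kind


@dataclass
class AdaptationResult:
    """Outcome of one adaptation-score solve."""

    P: int
    score: int
    fully_used_genes: set[str]
    alpha_values: dict[str, float]
    witness_flux: dict[str, float]
    solver_status: str
    objective_bound: float | None = None
    target: str | None = None
    target_optimum: float | None = None

    def to_dict(self) -> dict:
        return {
            "P": self.P,
            "score": self.score,
            "fully_used_genes": sorted(self.fully_used_genes),
            "alpha": {g: float(a) for g, a in self.alpha_values.items()},
            "status": self.solver_status,
            "objective_bound": self.objective_bound,
            "target": self.target,
            "target_optimum": self.target_optimum,
        }


def build_mri_problem(
    model: IrreversibleModel,
    profile,
    C: float,
    tol: float = DEFAULT_TOL,
    time_limit: float | None = None,
) -> MRIProblem:
    """Assemble the adaptation-score MILP for one strain.

    ``C`` converts expression units to mmol/gDCW/h.  C = 0 is accepted (it
    degenerates to a score of P) but negative C is not.
    """
    if C < 0:
        raise ValueError("C must be >= 0")
    genes = mapped_measured_genes(model, profile)
    return MRIProblem(model=model, profile=profile, C=C, genes=genes, tol=tol,
                      time_limit=time_limit)


def _solve(problem: MRIProblem, objective: np.ndarray, *, relax_z=False,
           extra: list[LinearConstraint] | None = None,
           fixed_z: dict[int, float] | None = None):
    cons = problem.constraints()
    if extra:
        cons = cons + list(extra)
    bounds = problem.bounds()
    if fixed_z:
        _, _, sz, _ = problem.var_slices()
        lb, ub = bounds.lb.copy(), bounds.ub.copy()
        for g, val in fixed_z.items():
            lb[sz.start + g] = val
            ub[sz.start + g] = val
        bounds = Bounds(lb, ub)
    options = {"mip_rel_gap": 0.0, "presolve": True}
    if problem.time_limit is not None:
        options["time_limit"] = problem.time_limit
    res = milp(
        c=objective,
        constraints=cons,
        integrality=problem.integrality(relax_z=relax_z),
        bounds=bounds,
        options=options,
    )
    return res


def _result_from_solution(problem: MRIProblem, res, target=None,
                          target_optimum=None) -> AdaptationResult:
    sv, sa, sz, sw = problem.var_slices()
    x = res.x
    alpha = {g: float(x[sa.start + i]) for i, g in enumerate(problem.genes)}
    z = x[sz]
    fully = {g for i, g in enumerate(problem.genes) if z[i] < 0.5}
    score = problem.P - int(round(float(np.sum(np.round(z)))))
    flux = {
        rid: float(v)
        for rid, v in zip(problem.model.base.reaction_ids, x[sv])
    }
    return AdaptationResult(
        P=problem.P,
        score=score,
        fully_used_genes=fully,
        alpha_values=alpha,
        witness_flux=flux,
        solver_status="optimal",
        objective_bound=float(res.mip_dual_bound)
        if getattr(res, "mip_dual_bound", None) is not None
        else None,
        target=target,
        target_optimum=target_optimum,
    )


def solve_adaptation_score(problem: MRIProblem) -> AdaptationResult:
    """Solve min sum z and return the proven-optimal adaptation score.

    With b = 0 the all-zero-flux point (alpha_j = E_j C, z_j = 1) is always
    feasible, so an infeasible status signals a modelling defect and raises.
    """
    objective = np.zeros(problem.n_vars)
    _, _, sz, _ = problem.var_slices()
    objective[sz] = 1.0
    res = _solve(problem, objective)
    if not res.success:
        raise RuntimeError(
            f"MILP solve failed (status {res.status}): {res.message}; "
            f"best bound {getattr(res, 'mip_dual_bound', None)}"
        )
    return _result_from_solution(problem, res)


def _target_constraint(problem: MRIProblem, q: np.ndarray, optimum: float,
                       tol: float) -> LinearConstraint:
    pad = np.concatenate([q, np.zeros(problem.n_vars - problem.n_flux)])
    slack = max(tol, tol * abs(optimum))
    return LinearConstraint(
        sp.csr_matrix(pad), optimum - slack, optimum + slack
    )


def maximize_target(problem: MRIProblem, target: str) -> float:
    """Stage 1 of conditional scoring: the maximum usage of the target.

    Solved with the z indicators relaxed (they never bind when alpha is
    free) but the direction binaries kept integral, so two-way cycles
    cannot inflate the optimum.
    """
    q = problem.usage_vector(target)
    objective = np.zeros(problem.n_vars)
    objective[: problem.n_flux] = -q
    res = _solve(problem, objective, relax_z=True)
    if not res.success:
        raise RuntimeError(
            f"target maximization failed (status {res.status}): {res.message}"
        )
    return float(-res.fun)


def conditional_adaptation_score(
    problem: MRIProblem, target: str
) -> AdaptationResult:
    """Adaptation score with a reaction or gene fixed at its maximum usage.

    Two stages: (1) maximize the target's usage; (2) pin the usage to that
    optimum (equality within tolerance) and minimize sum z.  Quantifies how
    compatible the expression profile is with maximal use of the target.
    """
    optimum = maximize_target(problem, target)
    if abs(optimum) < problem.tol:
        logger.warning(
            "target %s has maximum usage 0; the condition is vacuous", target
        )
    q = problem.usage_vector(target)
    extra = [_target_constraint(problem, q, optimum, problem.tol)]
    objective = np.zeros(problem.n_vars)
    _, _, sz, _ = problem.var_slices()
    objective[sz] = 1.0
    res = _solve(problem, objective, extra=extra)
    if not res.success:
        raise RuntimeError(
            f"conditional MILP failed (status {res.status}): {res.message}"
        )
    return _result_from_solution(problem, res, target=target, target_optimum=optimum)


def full_usage_gene_set(
    problem: MRIProblem, result: AdaptationResult
) -> set[str]:
    """Genes that SOME optimal solution uses at full capacity.

    The witness of a single solve is one optimum among possibly many; this
    re-solves with each candidate gene forced to full usage (z_j = 0) and
    keeps the gene iff the optimal score is preserved.  The returned set is
    solver-independent, unlike any single witness.
    """
    keep = set(result.fully_used_genes)
    objective = np.zeros(problem.n_vars)
    _, _, sz, _ = problem.var_slices()
    objective[sz] = 1.0
    extra = None
    if result.target is not None:
        q = problem.usage_vector(result.target)
        extra = [_target_constraint(problem, q, result.target_optimum, problem.tol)]
    for g, gene in enumerate(problem.genes):
        if gene in keep:
            continue
        res = _solve(problem, objective, extra=extra, fixed_z={g: 0.0})
        if res.success and problem.P - int(round(res.fun)) == result.score:
            keep.add(gene)
    return keep
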