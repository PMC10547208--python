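# Methods

## The model

The package scores how compatible a strain's gene-expression profile is
with its metabolic network. The substrate is a constraint-based
(stoichiometric) model: a steady-state flux vector `v` satisfying
`S v = b` (here `b = 0`, pure steady state) within per-reaction bounds,
with fluxes in mmol/gDCW/h. Intracellular reactions are bounded at 1000;
reversible reactions carry a lower bound of −1000 before conversion.

Expression enters through a per-gene capacity constraint. After the model
is rewritten in irreversible, OR-free form (below), each measured gene *j*
with reaction set `K_j` obeys

    sum_{i in K_j} v_i + alpha_j = E_j * C,      alpha_j >= 0

where `E_j` is the expression level on whatever scale the input table
provides (the motivating data are log-scale microarray intensities — no
log/linear conversion is applied; `C` absorbs the scale) and `C`
(mmol/gDCW/h per expression unit) converts expression into flux capacity.
The slack `alpha_j` is the unused part of gene *j*'s capacity; `alpha_j = 0`
means the gene's expression is fully converted into flux.

A binary indicator per gene,

    alpha_j - U_j * z_j <= 0,      U_j = E_j * C,

forces `z_j = 1` whenever slack remains. Since `alpha_j <= E_j * C` in any
feasible point, `U_j = E_j * C` is the tightest valid big-M; using it keeps
the LP relaxation strong and prevents numerically tiny `z` values from
cheating the count. Minimizing `sum z` yields the **adaptation score**

    score = P - min sum_j z_j,

the maximum number of measured, mapped genes (`P` of them) whose expression
can be fully used simultaneously. The score is computed under an
*unlimited medium*: uptake open at 1000 mmol/gDCW/h for the carbon source
and the mineral-medium components, all other uptakes closed, every
secretion capped at 1000 — the question asked is what program the cell
*could* run with its expression pattern, not what it measured.

### Model conversion

Reversible reactions are split into a forward and a negated backward copy,
both with bounds `[0, ub]`; a reaction that only runs backward
(`lb < 0 <= ub = 0`) is flipped in place. OR rules (isozymes) are expanded
to disjunctive normal form and the reaction is duplicated once per
disjunct, each copy carrying one conjunct; AND conjuncts are kept whole, so
a copy's flux counts against *every* member of its enzyme complex and any
member can limit it. DNF expansion is capped (default 32 disjuncts per
reaction) and aborts with an error rather than truncating silently. The
conversion is idempotent and preserves the LP flux space exactly (tested
against an LP on the unconverted model).

### Direction exclusivity

With `min sum z` as objective, a reversible reaction could run both
directions at once, creating a zero-net cycle that fakes full usage of its
genes. Per reversible source reaction a binary pair `(w_f, w_b)` with
`w_f + w_b = 1` gates the two sides: every forward copy obeys
`v <= 1000 * w_f`, every backward copy `v <= 1000 * w_b`. Sharing one pair
across all isozyme copies of a source reaction realizes "each forward
against all its backwards" and also blocks the mixed cycles that arise
between different isozyme copies of opposite direction. No further
loopless-flux machinery is applied; only these pairwise exclusions are
needed for the score's integrity.

### Conditional scores

The score "given maximal use of a target" is computed in two stages:
(1) maximize the target's usage — the summed flux of a gene's `K_j`, or of
all converted copies of a reaction — with the `z` indicators relaxed (they
never bind when `alpha` is free) but the `w` binaries kept integral so
cycles cannot inflate the optimum; (2) pin the usage to that optimum
(equality within a relative tolerance of 1e-6) and minimize `sum z`.
Adding a constraint can only shrink the feasible set, so the conditional
score never exceeds the unconditional one; this is asserted across all
fixture targets.

### Degenerate inputs and numerical choices

* `b = 0` always: the all-zero flux vector with `alpha_j = E_j * C`,
  `z_j = 1` is feasible for every assembled problem, so an infeasible
  solver status is treated as a bug and raised.
* `C = 0` collapses every capacity to zero and the score is exactly `P`.
* Genes with `E_j * C` below tolerance keep their constraint; a warning is
  logged (they are trivially "fully used").
* Zero tolerance for `alpha_j = 0`, LP feasibility, and integrality are a
  single configurable value, default 1e-6 mmol/gDCW/h.
* All LP/MILP solves use HiGHS through SciPy with a zero MIP gap, so the
  reported score is proven optimal. The score is deterministic; the
  witness (one optimal `v`, `alpha`, `z`) need not be unique.

### Alternate optima

Reported per-strain gene sets from a single solve are one witness among
possibly many optima. The reproducible, solver-independent answer is the
*optimality-preserving set*: every gene *j* such that forcing `z_j = 0`
leaves the optimal score unchanged. The key-gene filter uses this set by
default; a flag switches to the witness-only behaviour.

## Key-gene identification

Two factors select reprogramming candidates: (1) the gene is fully used by
the wild-type strain under the unlimited condition; (2) the absolute
difference between wild-type expression and the mean over evolved strains
is large. Candidates are ranked by descending difference (ties broken by
gene identifier) and the top *k* (default 2) are selected; a diagnostic
flags whether the wild-type level is the extreme (minimum or maximum)
across all strains, since a candidate whose wild-type level sits inside
the evolved range does not differentiate the strains. No numeric
difference threshold beyond the ranking is claimed; `top_k` is a
parameter. Pearson correlations between conditional scores and measured
phenotypes use the sample coefficient with a two-sided t-distribution
p-value (n−2 df); p-values are reported raw, without multiple-testing
correction.

## Calibration of C

`C` is fitted per carbon source by a sensitivity sweep: for each candidate,
growth is predicted for every strain (wild-type and evolved alike) by
maximizing biomass flux under the same converted model, medium bounds,
capacity constraints with free slacks, and direction exclusivity; the
error is the mean relative deviation from measured growth rates (absolute
error by flag), and the grid minimizer is chosen, smallest C on ties.
Predicted growth is non-decreasing in `C` (capacities only relax), which
makes the relative error quasi-convex whenever the prediction crosses the
measurement. The default grid is 30 log-spaced values spanning four
decades centred at (flux cap / median expression level) — the scale-free
point where a median gene's capacity equals the model's flux cap.

## What the fixture generator emulates — and what it does not

The generator builds small networks from the motifs that drive the MILP's
behaviour: uptake and secretion exchanges, a linear pathway, a parallel
branch, isozyme (OR) and complex (AND) rules, and reversible steps; every
gene maps to at least one reaction and `b = 0` keeps the zero-flux point
feasible. Expression is uniform on [1, 10]; evolved profiles are the
wild-type plus a known shift on chosen genes plus optional seeded Gaussian
noise (default spread 0, i.e. exact). The canonical instance wires two
parallel steps (genes g1, g2; levels 2 and 4) into a reversible step
(g3, level 5): with `C = 1` the three capacities are mutually
inconsistent (2 + 4 ≠ 5), the score is 2, and the optimal patterns are
exactly {g1, g3} and {g2, g3} — small enough to verify by hand.

These fixtures exercise the solver logic, not genome-scale reality: they
have no biomass composition, no cofactor coupling, no maintenance flux,
and a handful of genes instead of ~1400 measured ones. Passing tests
demonstrate correctness of the optimization and selection machinery, not
biological validity on any particular organism's data.

## The enumeration oracle

Every solver result is checkable against an independent brute-force
answer: for each gene subset (largest cardinality first) and each
orientation assignment of the reversible reactions, a plain LP tests
whether the subset's genes can sit exactly at capacity while the rest stay
at or below theirs. The first feasible cardinality is the score; all
feasible subsets at that cardinality are the optimal patterns. The oracle
shares no code with the MILP assembly and is capped at 12 genes
(2^P enumeration). Oracle and MILP agree on 100% of 210 seeded instances
(70 fixtures × 3 C values) in the acceptance run; the same batch checks
every witness invariant and the conditional-score monotonicity.

## Problem sizes used

The bundled checks run the MILP on networks of up to ~14 converted
reactions and 8 mapped genes, 210 instances for the oracle comparison, a
17-point calibration grid, and 4 key-gene recovery scenarios; these sizes
keep the whole suite under a minute while covering every motif the
genome-scale path exercises. The same code path assembles genome-scale
problems (the MILP is sparse throughout); only the enumeration oracle is
size-limited by design.

## Known limitations

* Witness gene sets at genome scale depend on solver tie-breaking; use the
  optimality-preserving set for reproducible comparisons (at genome scale
  this costs one MILP re-solve per candidate gene).
* The mineral-medium exchange list omits trace metals some models formally
  require for biomass; under `min sum z` (no growth requirement) this is
  immaterial, and the list is configurable for growth-prediction use.
* An exchange closed in the source SBML (lower bound 0) has no uptake copy
  after conversion; naming it in the medium's unlimited set cannot open it.
  Set the exchange reversible in the source model first.
* Expression is matched to model genes case-sensitively after whitespace
  trimming; platforms using symbols (cyoC) against models using locus tags
  need the optional two-column mapping file.
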