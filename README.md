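# mri-reprogramming

**Metabolic Reprogramming Identifier (MRI)** — integrate per-gene
expression levels into a genome-scale metabolic model and find the genes
whose usage was reprogrammed during adaptive laboratory evolution.

## The problem

Adaptive laboratory evolution (ALE) shifts the expression of hundreds of
genes, but only a few of those shifts change how the cell actually *uses*
its metabolism. Expression changes alone cannot separate drivers from
passengers, and flux measurements rarely correlate cleanly with
transcription. MRI asks a sharper question: given a strain's expression
profile, how much of it *can* the stoichiometric network convert into
flux — and which genes does the wild-type use fully that the evolved
strains treat differently?

## The method

For a model in irreversible, OR-free form, each measured gene *j* with
reaction set `K_j` constrains flux by

    Σ_{i∈K_j} v_i + α_j = E_j·C,   α_j ≥ 0,

where `E_j` is the expression level and `C` (mmol/gDCW/h per expression
unit) converts expression into flux capacity; `α_j = 0` means gene *j* is
fully used. Indicators `z_j ∈ {0,1}` with `α_j − E_j·C·z_j ≤ 0` count the
incompletely used genes, and binary direction pairs `w_f + w_b = 1` on
every reversible reaction forbid the two-way cycles that would fake usage.
The MILP

    adaptation score = P − min Σ_j z_j

(P = number of measured, mapped genes) is solved under an unlimited
medium. Key genes are those fully used by the wild-type whose expression
moved most between wild-type and the evolved mean; the score recomputed
with a key gene pinned at its maximal usage (*conditional score*)
quantifies how compatible each strain's profile is with that gene, and its
correlation with measured growth phenotypes closes the loop from genotype
to phenotype. `C` is calibrated per carbon source by minimizing the mean
relative growth-prediction error. See `docs/methods.md` for the full
treatment.

All optimization runs on HiGHS via SciPy; SBML models are read and written
with COBRApy.

## Worked example

```python
import mri

model = mri.toy1_model()            # A →(g1|g2) B ↔(g3) C, secreted
wt, ev = mri.toy1_profiles()        # WT: g1=2, g2=4, g3=5; EV: g2→6
medium = mri.toy1_medium()          # only A can be consumed

conv = mri.apply_medium(mri.convert_model(model), medium)
problem = mri.build_mri_problem(conv, wt, C=1.0)
result = mri.solve_adaptation_score(problem)
print(result.P, result.score)                       # 3 2
print(sorted(mri.full_usage_gene_set(problem, result)))
                                                    # ['g1', 'g2', 'g3']
cond = mri.conditional_adaptation_score(problem, "R3")
print(cond.target_optimum, cond.score)              # 5.0 2
```

With `C = 1` the capacities 2, 4 and 5 are mutually inconsistent — the two
parallel steps would push 6 units into a step capped at 5 — so at most two
genes can be fully used (`score = 2`, out of `P = 3`). Every gene appears
in *some* optimum, hence the full-usage set is all three. Fixing the
reversible step at its maximal usage (5 units) still permits a score of 2.

The same API runs genome-scale inputs:

```python
model = mri.read_sbml_model("iJO1366.xml")
profiles = mri.read_expression_table("expression.tsv")   # strains as columns
phen = mri.read_phenotype_table("phenotypes.tsv")
config = mri.AnalysisConfig(medium=mri.MediumSpec.m9("EX_lac__L_e"), C=0.5)
bundle = mri.run_full_analysis(model, profiles, phen, config, out_dir="out/")
```

or from the shell:

```bash
mri score --model model.xml --expr expr.tsv --strain WT \
    --carbon EX_lac__L_e --c 0.5 --fix CYTBO3_4pp --out result.json
mri keygenes --model model.xml --expr expr.tsv --wild-type WT \
    --carbon EX_lac__L_e --c 0.5
mri calibrate --model model.xml --expr expr.tsv --phen phen.tsv \
    --carbon EX_lac__L_e
```

Short narrative scripts in `examples/` cover each capability.

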