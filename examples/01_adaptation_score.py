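"""Adaptation score of the canonical toy network.

Two parallel steps (genes g1, g2; expression 2 and 4) feed a reversible
step (g3, expression 5). With C = 1 the capacities are inconsistent
(2 + 4 != 5), so at most two of the three genes can convert their whole
expression into flux.
"""

import mri

model = mri.toy1_model()
wt, _ = mri.toy1_profiles()
medium = mri.toy1_medium()

converted = mri.apply_medium(mri.convert_model(model), medium)
problem = mri.build_mri_problem(converted, wt, C=1.0)
result = mri.solve_adaptation_score(problem)

print(f"measured mapped genes P = {result.P}")
print(f"adaptation score       = {result.score}")
print(f"one optimal witness    = {sorted(result.fully_used_genes)}")
print(f"optimality-preserving  = "
      f"{sorted(mri.full_usage_gene_set(problem, result))}")
# score 2 of 3: the network can fully use {g1,g3} or {g2,g3} but never all
# three; each gene appears in some optimum, so the preserving set is all 3.
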