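"""Cross-checking the MILP against the enumeration oracle.

On small fixtures the adaptation score can be recomputed by brute force:
enumerate gene subsets and reversible-reaction orientations, testing LP
feasibility. The MILP must agree exactly.
"""

import mri
from mri.fixtures import brute_force_adaptation_score, random_toy_model

for seed in range(5):
    model, profile, medium = random_toy_model(seed)
    converted = mri.apply_medium(mri.convert_model(model), medium)
    problem = mri.build_mri_problem(converted, profile, C=1.0)
    milp_score = mri.solve_adaptation_score(problem).score
    oracle = brute_force_adaptation_score(model, profile, 1.0, medium)
    mark = "ok" if milp_score == oracle.score else "MISMATCH"
    print(f"seed {seed}: MILP {milp_score} vs oracle {oracle.score} [{mark}]  "
          f"P={oracle.P}, {len(oracle.optimal_patterns)} optimal pattern(s)")
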