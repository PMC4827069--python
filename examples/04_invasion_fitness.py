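"""Invasion fitness of a phenotype-structured mutant.

A resident genotype sits at its equilibrium; a mutant genotype with two
phenotypes coupled by switching arrives as a single cell.  The mean matrix A
of the approximating multi-type branching process classifies its fate: the
clone is supercritical iff the leading eigenvalue lambda_1 of A is positive
— even when every individual phenotype has a negative net growth rate,
because an outgoing switch is a loss for the phenotype, not for the genotype.
The Monte-Carlo companion verifies the prediction and the phenotype
composition v of surviving clones.
"""

import numpy as np

from actsim import (find_fixed_points, invasion_fitness, invasion_mc_oracle,
                    mean_matrix)
from actsim.therapy import mutant_invasion_fig6

scenario = mutant_invasion_fig6()
points = find_fixed_points(scenario.params)
resident = next(fp for fp in points if fp.support == ("p",))
print("resident equilibrium:", {l: round(v, 3) for l, v in
                                zip(resident.labels, resident.x) if v > 0})

M = mean_matrix(resident, "g2", scenario.params)
res = invasion_fitness(M)
print("mean matrix A (per day, columns = parent phenotype):")
print(np.round(M.A, 3))
print(f"diagonal entries (per-phenotype net rates): "
      f"{M.A[0, 0]:.2f}, {M.A[1, 1]:.2f}  — both negative")
print(f"lambda_1 = {res.lambda1:.4f}  -> supercritical: {res.supercritical}")
print(f"predicted phenotype proportions v = {np.round(res.v, 3)}")

freq, comp, n_surv = invasion_mc_oracle(
    resident, "g2", scenario.params, epsilon=0.05, n_runs=2000, seed=5,
    K=20000)
print(f"Monte-Carlo: {n_surv}/2000 clones reached size epsilon*K; "
      f"composition there = {np.round(comp, 3)}")
print("The eigenvector predicts the composition of the successful clones.")
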