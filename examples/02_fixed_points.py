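"""Deterministic limit: fixed points and their stability.

Locates every equilibrium of the one- and two-specificity systems by support
enumeration and prints the stability pattern that organizes the stochastic
metastability: the interior point is the only fully stable one, and the
tumour-only point is stable inside the no-T-cell invariant subspace (which is
why hitting that subspace by fluctuation means relapse).
"""

from actsim import find_fixed_points
from actsim.therapy import one_tcell_qualitative, two_tcell_qualitative

for scenario in (one_tcell_qualitative(), two_tcell_qualitative()):
    print(f"\n=== {scenario.name} ===")
    for fp in find_fixed_points(scenario.params):
        dens = "  ".join(f"{lab}={v:.3f}"
                         for lab, v in zip(fp.labels, fp.x) if v > 1e-9)
        print(f"{fp.name:22s} {fp.classification:9s} "
              f"(within its subspace: {fp.restricted_classification:9s})  {dens}")

print("""
Reading: scaled densities (counts / K).  'stable' in the full space means the
deterministic flow is attracted there; a point that is only stable within its
own subspace is reachable by the stochastic system when a population dies out.
""")
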