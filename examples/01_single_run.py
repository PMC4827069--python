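"""One stochastic therapy run of the qualitative one-specificity regime.

Builds the built-in scenario (differentiated/dedifferentiated melanoma, one
T-cell specificity, TNF-alpha), runs a single exact SSA trajectory and prints
a coarse time series of raw individual counts.
"""

from actsim.therapy import one_tcell_qualitative

scenario = one_tcell_qualitative()          # K = 200, therapy at day 0
traj = scenario.run(seed=3)

print(f"traits: {traj.labels}   K = {traj.K}   stop: {traj.stop_reason}")
print("day   " + "".join(f"{lab:>8s}" for lab in traj.labels))
for day in range(0, 51, 5):
    i = min(range(len(traj.times)), key=lambda j: abs(traj.times[j] - day))
    row = "".join(f"{int(v):8d}" for v in traj.states[i])
    print(f"{traj.times[i]:5.1f} {row}")

z_final = traj.column("z_x")[-1]
print("\nT-cells at the horizon:", z_final,
      "->", "survived (controlled tumour)" if z_final else
      "extinct (tumour escapes control)")
print("The two endings occur across seeds; K sets how often each happens.")
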