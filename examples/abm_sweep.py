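"""Agent-based blastocyst simulation: selection thins the abnormal clone.

Sweeps the initial SMC/SV+ fraction against the per-cycle selection bias and
prints the mean ICM SMC/SV+ fraction over replicates, next to the closed
form the simulator should track.
"""

from shepherdsim import ABMParams, expected_icm_fraction, run_sweep

p0_grid = [0.25, 0.5, 0.75]
s_grid = [0.0, 0.05, 0.1, 0.2]
template = ABMParams(p0=0.5, n_founders=8, n_cycles=5)

sweep = run_sweep(p0_grid, s_grid, reps=500, base_seed=42, params=template)

print("mean ICM SMC/SV+ fraction (500 replicates per cell)")
print(sweep.to_tsv())

print("closed-form expectation")
for p0 in p0_grid:
    row = [
        expected_icm_fraction(ABMParams(p0=p0, selection_bias=s))
        for s in s_grid
    ]
    print(f"{p0:g}\t" + "\t".join(f"{v:.4f}" for v in row))

# Each column to the right applies stronger selection against SMC/SV+
# daughters; every row decreases left to right — even mild per-cycle losses
# (5%) visibly deplete the abnormal clone from the ICM within five cycles.
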