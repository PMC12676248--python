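"""Absorbing Markov chain of SMC/SV+ cell fate over ten developmental steps.

A proliferating abnormal cell is, per step, cleared by apoptosis, allocated
to the trophectoderm, retained in the inner cell mass, or keeps
proliferating.  The mass vector over these fates tracks where the abnormal
clone ends up.
"""

from shepherdsim import TransitionSpec, absorbing_distribution, iterate

spec = TransitionSpec(p_clear=0.2, p_te=0.2, p_icm=0.2, p_stay=0.4)
trajectory = iterate(spec, n_steps=10)

print("step  proliferating  cleared    TE         ICM")
for dist in trajectory:
    p, c, t, i = dist.mass
    print(f"{dist.iteration:4d}  {p:.6f}       {c:.6f}   {t:.6f}   {i:.6f}")

limit = absorbing_distribution(spec)
print(f"\nabsorbing limit (cleared, TE, ICM): {limit.round(6).tolist()}")
print(f"ICM mass after 10 steps: {trajectory[-1].mass[3]:.4f}")

# With the symmetric default transitions, ~33% of the abnormal clone's mass
# ends in the ICM after ten steps (the rest cleared or sequestered in the
# TE) — abnormal cells are mostly kept out of the embryo proper, but a
# benign minority fraction persists.
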