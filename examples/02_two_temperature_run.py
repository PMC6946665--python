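"""Run the two-thermostat Langevin dynamics and measure channel temperatures.

Each ring carries a consecutive hot arc coupled to a Langevin thermostat at
T_h = 3 while the rest of the melt sits at T_c = 1 (both with friction
gamma = 2/3 per tau).  The run starts with an all-cold equilibration phase;
the activity onset defines time zero.  The measured kinetic temperatures
m<v^2>/3 per channel sit *between* the two set points: in a dense melt the
stiff interactions conduct heat between the channels, so the labels define
two noise levels, not two isolated heat baths.
"""

import ringmelt as rm
from ringmelt.params import ModelParameters

params = ModelParameters(N=40, M=8, N_h=5)
state = rm.build_melt(params, seed=3)
state = rm.assign_activity(state, seed=4)

schedule = [
    ("equilibrate", 5_000, 1_000),  # all monomers cold
    ("active", 20_000, 1_000),      # hot arcs switched on at t = 0
]
traj = rm.run_protocol(state, schedule, seed=5)

t_hot, t_cold = rm.kinetic_temperatures(traj, window=0.5)
print(f"frames stored            : {traj.n_frames}")
print(f"time span                : [{traj.times[0]:.0f}, {traj.times[-1]:.0f}] tau "
      "(0 = activity onset)")
print(f"hot-channel  m<v^2>/3    : {t_hot:.3f} epsilon/k_B (thermostat 3.0)")
print(f"cold-channel m<v^2>/3    : {t_cold:.3f} epsilon/k_B (thermostat 1.0)")
print("The gap between measured and set temperatures is interaction heat")
print("conduction; the persistent difference between channels drives the")
print("non-equilibrium physics.")
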