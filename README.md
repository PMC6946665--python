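# ringmelt

Molecular dynamics and topological analysis of **active ring-polymer
melts** — dense solutions of unknotted, nonconcatenated circular polymers
in which a segment of each ring is driven by stronger thermal noise.  Such
melts develop persistent mutual *threadings* (one ring's contour passing
through the minimal surface spanned on another) and can arrest into a
topological glass; the model is also a minimal physical picture for
active chromatin loops.  `ringmelt` is aimed at polymer/soft-matter
simulators who want the full apparatus of this system at desk scale:
the simulation engine, the topology-verified melt builder, the
minimal-surface threading analysis and the glassy-dynamics observables,
all scriptable from Python.

## Model in brief

Kremer–Grest-style bead-spring rings in reduced units
(ε = σ = m = k_B = 1, τ = σ√(m/ε)) at monomer density ρ = 0.85 σ⁻³:

- WCA excluded volume: U(r) = 4ε[(σ/r)¹² − (σ/r)⁶] + ε for r < 2^{1/6}σ;
- FENE bonds: U(r) = −½Kr²_max ln[1 − (r/r_max)²], K = 30 ε/σ², r_max = 1.5 σ
  (chains effectively uncrossable — topology is conserved);
- bending: U(θ) = k_θ(1 − cos(θ − π)), k_θ = 1.5 ε.

Each active ring carries one consecutive arc of N_h monomers (default N/8)
coupled to a Langevin thermostat at T_h = 3, the rest at T_c = 1, both with
friction γ = (2/3) τ⁻¹; velocity-Verlet integration at Δt = 0.005 τ.
Threading depth is quantified by the separation length
L_sep = min(Σ_even L_i, Σ_odd L_i) over the arcs between consecutive
surface piercings, and Q = L_sep/(N − L_sep).  Dynamics are diagnosed by
the ring-COM mean squared displacement g₃(t, t₀) in the system-COM frame,
the self-ISF F_s(q, t, t₀), the non-ergodicity parameter f(q, t₀), the
ergodicity-breaking parameter EB(t), displacement kurtosis and the
cold–hot directionality vector.

## Worked example

```python
import ringmelt as rm
from ringmelt.params import ModelParameters

params = ModelParameters(N=40, M=8, N_h=5)        # 8 rings of 40 monomers
state  = rm.build_melt(params, seed=3)            # topology-verified melt
state  = rm.assign_activity(state, seed=4)        # one 5-monomer hot arc each
traj   = rm.run_protocol(
    state,
    [("equilibrate", 5_000, 1_000), ("active", 20_000, 1_000)],
    seed=5,
)
print(rm.kinetic_temperatures(traj, window=0.5))
```

prints (`examples/02_two_temperature_run.py`):

```
hot-channel  m<v^2>/3    : 1.559 epsilon/k_B (thermostat 3.0)
cold-channel m<v^2>/3    : 1.226 epsilon/k_B (thermostat 1.0)
```

The measured kinetic temperatures sit *between* the two thermostat set
points: in a dense melt the stiff interactions conduct heat between the
channels, so the labels set two noise levels rather than two isolated heat
baths (see `docs/methods.md`).  The persistent difference between the
channels is what drives the non-equilibrium physics.

Threading analysis on a constructed pair (`examples/03_threading_analysis.py`):

```
constructed pair         : 2 piercings, signs [-1, 1], L_sep = 23, Q = 0.92
```

a deep threading: the threading ring has 23 of its 48 monomers on one side
of the threaded ring's minimal surface (Q close to its maximum of 1).  The same script builds a 48-ring melt, runs the two-temperature
engine, tabulates all directed threadings and their clusters as a function
of the depth cutoff L_cutoff.

More narrative scripts live in `examples/`: building and verifying melts
(pairwise Gauss linking numbers, knot screen), two-temperature runs, the
threading pipeline, glassy observables (g₃ exponents via `fit_power_law`,
ISF, EB, cold–hot correlation, S(q)), and the bond-cutting experiment that
turns rings into cold–hot–cold triblocks.

A thin CLI mirrors the library for shell pipelines:

```bash
ringmelt build   --config config.yaml --out build/
ringmelt run     --config config.yaml --state build/state.data --out run/
ringmelt analyze --config config.yaml --traj run/traj.h5 --out analysis/
ringmelt cut     --config config.yaml --state build/state.data --out cut.data
```

All outputs embed a hash of the configuration; mixing files from different
configurations is refused.  Formats: LAMMPS data/dump, XYZ, HDF5, OFF/PLY
meshes, TSV series.

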