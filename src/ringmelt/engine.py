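"""Underdamped Langevin dynamics with two thermostats.

The equations of motion

    m dv/dt = F_conservative - gamma m v + sqrt(2 m gamma k_B T_i) xi(t)

are integrated by velocity Verlet with the friction and Gaussian noise
entering the force once per step (the semantics of the LAMMPS ``langevin``
fix).  Every monomer draws its noise variance from its *own* label's
temperature, so hot and cold monomers sit in the same melt but feel
independent thermostats obeying fluctuation--dissipation per channel.

The conservative force is WCA between all pairs (cell list under periodic
boundaries), FENE along bonds and the bending term along consecutive
triplets, all evaluated on unwrapped coordinates (pairs via minimum image).
A bond reaching ``r_max`` aborts the run: the FENE divergence there signals
imminent chain crossing, which would invalidate the topological invariants.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .errors import OverstretchedBondError
from .state import MeltState, Trajectory

__all__ = ["step", "run_protocol", "kinetic_temperatures", "Phase"]


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------


_HALF_STENCIL = np.array(
    [
        [1, 0, 0], [0, 1, 0], [0, 0, 1],
        [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1],
        [0, 1, 1], [0, 1, -1],
        [1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1],
    ],
    dtype=np.int64,
)


@njit(cache=True, fastmath=True)
def _pair_forces(pos, box, forces, epsilon, sigma, f_cap):
    """WCA forces via a cell-sorted list with a half stencil.

    Rebuilt every step (no skin); O(n^2) fallback for boxes smaller than
    three cells per side.  ``f_cap > 0`` clamps the pair-force magnitude
    (builder push-off only).
    """
    n = pos.shape[0]
    rc = 2.0 ** (1.0 / 6.0) * sigma
    rc2 = rc * rc
    hx = 0.5 * box[0]
    hy = 0.5 * box[1]
    hz = 0.5 * box[2]
    # wrapped coordinates for binning / minimum image
    w = np.empty_like(pos)
    for i in range(n):
        w[i, 0] = pos[i, 0] % box[0]
        w[i, 1] = pos[i, 1] % box[1]
        w[i, 2] = pos[i, 2] % box[2]

    ncx = int(box[0] / rc)
    ncy = int(box[1] / rc)
    ncz = int(box[2] / rc)
    # coarsen very dilute grids so the cell array stays O(n)
    while ncx * ncy * ncz > 8 * n + 64:
        ncx = max(3, ncx // 2)
        ncy = max(3, ncy // 2)
        ncz = max(3, ncz // 2)
        if ncx == 3 and ncy == 3 and ncz == 3:
            break

    use_cells = ncx >= 3 and ncy >= 3 and ncz >= 3
    if use_cells:
        ncells = ncx * ncy * ncz
        lx = box[0] / ncx
        ly = box[1] / ncy
        lz = box[2] / ncz
        ci = np.empty(n, dtype=np.int64)
        count = np.zeros(ncells + 1, dtype=np.int64)
        for i in range(n):
            cx = int(w[i, 0] / lx)
            cy = int(w[i, 1] / ly)
            cz = int(w[i, 2] / lz)
            if cx >= ncx:
                cx = ncx - 1
            if cy >= ncy:
                cy = ncy - 1
            if cz >= ncz:
                cz = ncz - 1
            c = (cx * ncy + cy) * ncz + cz
            ci[i] = c
            count[c + 1] += 1
        for c in range(ncells):
            count[c + 1] += count[c]
        order = np.empty(n, dtype=np.int64)
        fill = count[:-1].copy()
        for i in range(n):
            order[fill[ci[i]]] = i
            fill[ci[i]] += 1

    # half stencil: 13 neighbor cells plus in-cell pairs (s == 0); the
    # stencil cells are distinct under wrapping for >= 3 cells per side
    if use_cells:
        for cx in range(ncx):
            for cy in range(ncy):
                for cz in range(ncz):
                    c = (cx * ncy + cy) * ncz + cz
                    a0 = count[c]
                    a1 = count[c + 1]
                    for s in range(14):
                        if s == 0:
                            cb = c
                        else:
                            bx = (cx + _HALF_STENCIL[s - 1, 0]) % ncx
                            by = (cy + _HALF_STENCIL[s - 1, 1]) % ncy
                            bz = (cz + _HALF_STENCIL[s - 1, 2]) % ncz
                            cb = (bx * ncy + by) * ncz + bz
                        b0 = count[cb]
                        b1 = count[cb + 1]
                        for ai in range(a0, a1):
                            i = order[ai]
                            jstart = ai + 1 if s == 0 else b0
                            for bj in range(jstart, b1):
                                j = order[bj]
                                dx = w[i, 0] - w[j, 0]
                                dy = w[i, 1] - w[j, 1]
                                dz = w[i, 2] - w[j, 2]
                                if dx > hx:
                                    dx -= box[0]
                                elif dx < -hx:
                                    dx += box[0]
                                if dy > hy:
                                    dy -= box[1]
                                elif dy < -hy:
                                    dy += box[1]
                                if dz > hz:
                                    dz -= box[2]
                                elif dz < -hz:
                                    dz += box[2]
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 < rc2 and r2 > 0.0:
                                    sr2 = sigma * sigma / r2
                                    sr6 = sr2 * sr2 * sr2
                                    fr = (
                                        24.0
                                        * epsilon
                                        * (2.0 * sr6 * sr6 - sr6)
                                        / r2
                                    )
                                    if f_cap > 0.0:
                                        r = np.sqrt(r2)
                                        if fr * r > f_cap:
                                            fr = f_cap / r
                                    forces[i, 0] += fr * dx
                                    forces[i, 1] += fr * dy
                                    forces[i, 2] += fr * dz
                                    forces[j, 0] -= fr * dx
                                    forces[j, 1] -= fr * dy
                                    forces[j, 2] -= fr * dz
    else:
        for i in range(n):
            for j in range(i + 1, n):
                dx = w[i, 0] - w[j, 0]
                dy = w[i, 1] - w[j, 1]
                dz = w[i, 2] - w[j, 2]
                if dx > hx:
                    dx -= box[0]
                elif dx < -hx:
                    dx += box[0]
                if dy > hy:
                    dy -= box[1]
                elif dy < -hy:
                    dy += box[1]
                if dz > hz:
                    dz -= box[2]
                elif dz < -hz:
                    dz += box[2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rc2 and r2 > 0.0:
                    sr2 = sigma * sigma / r2
                    sr6 = sr2 * sr2 * sr2
                    fr = 24.0 * epsilon * (2.0 * sr6 * sr6 - sr6) / r2
                    if f_cap > 0.0:
                        r = np.sqrt(r2)
                        if fr * r > f_cap:
                            fr = f_cap / r
                    forces[i, 0] += fr * dx
                    forces[i, 1] += fr * dy
                    forces[i, 2] += fr * dz
                    forces[j, 0] -= fr * dx
                    forces[j, 1] -= fr * dy
                    forces[j, 2] -= fr * dz


@njit(cache=True)
def _bond_angle_forces(pos, bonds, angles, forces, K, r_max, k_theta):
    """FENE + bending forces on unwrapped coordinates.

    Returns 0 on success, 1 if any bond reached r_max (overstretch).
    """
    rmax2 = r_max * r_max
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rmax2:
            return 1
        # -dU/dr = -K r/(1-(r/rmax)^2); force on i points toward j
        c = K / (1.0 - r2 / rmax2)
        forces[i, 0] += c * dx
        forces[i, 1] += c * dy
        forces[i, 2] += c * dz
        forces[j, 0] -= c * dx
        forces[j, 1] -= c * dy
        forces[j, 2] -= c * dz

    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k, 0] - pos[j, 0]
        by = pos[k, 1] - pos[j, 1]
        bz = pos[k, 2] - pos[j, 2]
        la2 = ax * ax + ay * ay + az * az
        lb2 = bx * bx + by * by + bz * bz
        la = np.sqrt(la2)
        lb = np.sqrt(lb2)
        if la < 1e-12 or lb < 1e-12:
            continue
        ct = (ax * bx + ay * by + az * bz) / (la * lb)
        # U = k_theta (1 + cos theta); F = -k_theta * grad(cos theta)
        gi_x = bx / (la * lb) - ct * ax / la2
        gi_y = by / (la * lb) - ct * ay / la2
        gi_z = bz / (la * lb) - ct * az / la2
        gk_x = ax / (la * lb) - ct * bx / lb2
        gk_y = ay / (la * lb) - ct * by / lb2
        gk_z = az / (la * lb) - ct * bz / lb2
        forces[i, 0] -= k_theta * gi_x
        forces[i, 1] -= k_theta * gi_y
        forces[i, 2] -= k_theta * gi_z
        forces[k, 0] -= k_theta * gk_x
        forces[k, 1] -= k_theta * gk_y
        forces[k, 2] -= k_theta * gk_z
        forces[j, 0] += k_theta * (gi_x + gk_x)
        forces[j, 1] += k_theta * (gi_y + gk_y)
        forces[j, 2] += k_theta * (gi_z + gk_z)
    return 0


@njit(cache=True)
def _conservative_forces(
    pos, box, bonds, angles, epsilon, sigma, K, r_max, k_theta, f_cap, wca_on
):
    forces = np.zeros_like(pos)
    if wca_on:
        _pair_forces(pos, box, forces, epsilon, sigma, f_cap)
    status = _bond_angle_forces(pos, bonds, angles, forces, K, r_max, k_theta)
    return forces, status


@njit(cache=True)
def _tether_forces(pos, forces, centers, radii, k_t):
    """Flat-bottom spherical restraint (builder confinement only)."""
    n = pos.shape[0]
    for i in range(n):
        dx = pos[i, 0] - centers[i, 0]
        dy = pos[i, 1] - centers[i, 1]
        dz = pos[i, 2] - centers[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > radii[i]:
            c = -k_t * (r - radii[i]) / r
            forces[i, 0] += c * dx
            forces[i, 1] += c * dy
            forces[i, 2] += c * dz


@njit(cache=True)
def _run_chunk(
    pos,
    vel,
    box,
    kT,
    bonds,
    angles,
    n_steps,
    dt,
    gamma,
    mass,
    epsilon,
    sigma,
    K,
    r_max,
    k_theta,
    f_cap,
    wca_on,
    seed,
    tether_on,
    tether_centers,
    tether_radii,
    tether_k,
):
    """Advance n_steps of velocity-Verlet Langevin in place.

    Returns the number of completed steps (< n_steps on overstretch abort).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    half = 0.5 * dt / mass
    fcons, status = _conservative_forces(
        pos, box, bonds, angles, epsilon, sigma, K, r_max, k_theta, f_cap, wca_on
    )
    if status != 0:
        return 0
    if tether_on:
        _tether_forces(pos, fcons, tether_centers, tether_radii, tether_k)
    ftot = np.empty_like(fcons)
    pref = np.empty(n)
    for i in range(n):
        pref[i] = np.sqrt(2.0 * mass * gamma * kT[i] / dt)
    noise = np.random.standard_normal((n, 3))
    for i in range(n):
        for d in range(3):
            ftot[i, d] = (
                fcons[i, d] - gamma * mass * vel[i, d] + pref[i] * noise[i, d]
            )
    for s in range(n_steps):
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * ftot[i, d]
                pos[i, d] += dt * vel[i, d]
        fcons, status = _conservative_forces(
            pos, box, bonds, angles, epsilon, sigma, K, r_max, k_theta, f_cap, wca_on
        )
        if status != 0:
            return s
        if tether_on:
            _tether_forces(pos, fcons, tether_centers, tether_radii, tether_k)
        noise = np.random.standard_normal((n, 3))
        for i in range(n):
            for d in range(3):
                ftot[i, d] = (
                    fcons[i, d] - gamma * mass * vel[i, d] + pref[i] * noise[i, d]
                )
                vel[i, d] += half * ftot[i, d]
    return n_steps


# --------------------------------------------------------------------------
# python API
# --------------------------------------------------------------------------


def _channel_temperatures(state, active):
    """Per-monomer thermostat target temperature array."""
    p = state.params
    kT = np.full(p.n_monomers, p.T_c, dtype=np.float64)
    if active:
        kT[state.hot] = p.T_h
    return kT


def step(
    state: MeltState,
    n_steps: int,
    seed: int,
    *,
    active: bool = True,
    wca_on: bool = True,
    f_cap: float = 0.0,
    dt: float | None = None,
    tether: tuple | None = None,
) -> MeltState:
    """Advance the melt by ``n_steps`` integration steps.

    Deterministic given ``(state, n_steps, seed)``.  ``active=False`` couples
    every monomer to the cold thermostat regardless of labels (equilibrium
    phase).  ``f_cap`` and ``dt`` overrides exist for the builder's push-off
    and are never used in production.

    Raises
    ------
    OverstretchedBondError
        If any bond reaches ``r_max``; the exception carries the last valid
        state (the input state) and the step count reached.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    new = state.copy()
    if n_steps == 0:
        return new
    p = new.params
    kT = _channel_temperatures(new, active)
    if tether is not None:
        centers, radii, k_t = tether
        tether_args = (True, np.ascontiguousarray(centers, dtype=np.float64),
                       np.ascontiguousarray(radii, dtype=np.float64), float(k_t))
    else:
        tether_args = (False, np.zeros((1, 3)), np.zeros(1), 0.0)
    done = _run_chunk(
        new.positions,
        new.velocities,
        new.box,
        kT,
        new.bonds(),
        new.angles(),
        n_steps,
        float(dt if dt is not None else p.dt),
        p.gamma,
        p.mass,
        p.epsilon,
        p.sigma,
        p.K,
        p.r_max,
        p.k_theta,
        float(f_cap),
        wca_on,
        int(seed) % (2**32),
        *tether_args,
    )
    if done < n_steps:
        raise OverstretchedBondError(
            f"bond reached r_max={p.r_max} after {done} steps",
            last_state=state,
            step=done,
        )
    new.time = state.time + n_steps * (dt if dt is not None else p.dt)
    return new


class Phase:
    """One phase of a run schedule.

    label: 'equilibrate' (all monomers cold), 'active' (two thermostats per
    the labels) or 'cut' (cut every ring's antipodal cold bond, then continue
    with two thermostats).  ``n_steps`` integration steps, one stored frame
    every ``stride`` steps.
    """

    LABELS = ("equilibrate", "active", "cut")

    def __init__(self, label: str, n_steps: int, stride: int):
        if label not in self.LABELS:
            raise ValueError(f"unknown phase label {label!r}")
        if n_steps < 0 or stride <= 0:
            raise ValueError("n_steps must be >= 0 and stride positive")
        self.label = label
        self.n_steps = int(n_steps)
        self.stride = int(stride)

    def __repr__(self):
        return f"Phase({self.label!r}, n_steps={self.n_steps}, stride={self.stride})"


def run_protocol(
    state: MeltState,
    schedule,
    seed: int,
    *,
    store_velocities: bool = True,
) -> Trajectory:
    """Execute a multi-phase protocol and collect a trajectory.

    The clock is re-zeroed at the start of the first non-equilibrate phase
    (activity onset, or the cutting event for 'cut'), matching the t0 = 0
    convention of all aging observables.  The frame at the onset itself is
    stored.  Deterministic given (state, schedule, seed).
    """
    from .builder import cut_bonds  # deferred: builder imports engine

    schedule = [
        p if isinstance(p, Phase) else Phase(*p) for p in schedule
    ]
    seeder = np.random.default_rng(seed)
    current = state.copy()
    frames, vels, times = [], [], []
    phase_starts = {}

    def snap(s):
        frames.append(s.positions.copy())
        vels.append(s.velocities.copy())
        times.append(s.time)

    onset_seen = False
    for phase in schedule:
        if phase.label == "cut":
            current = cut_bonds(current)
        if phase.label != "equilibrate" and not onset_seen:
            onset_seen = True
            # re-zero the clock at activity onset / cutting moment
            shift = current.time
            current.time = 0.0
            times = [t - shift for t in times]
        phase_starts[phase.label] = current.time
        if not frames:
            snap(current)
        active = phase.label != "equilibrate"
        remaining = phase.n_steps
        while remaining > 0:
            chunk = min(phase.stride, remaining)
            sub = int(seeder.integers(0, 2**31))
            current = step(current, chunk, sub, active=active)
            remaining -= chunk
            snap(current)

    if len(frames) < 1:
        snap(current)
    traj = Trajectory(
        times=np.array(times),
        positions=np.array(frames),
        velocities=np.array(vels) if store_velocities else None,
        box=current.box.copy(),
        hot=current.hot.copy(),
        closed=current.closed.copy(),
        params=current.params,
        meta={
            "seed": int(seed),
            "schedule": [(p.label, p.n_steps, p.stride) for p in schedule],
            "phase_start_times": phase_starts,
            "thermostats": {"T_h": current.params.T_h, "T_c": current.params.T_c},
        },
    )
    return traj


def kinetic_temperatures(obj, window: float = 1.0):
    """Measured kinetic temperatures (T_hot, T_cold) = m<v^2>/3 per channel.

    ``obj`` is a MeltState (instantaneous) or a Trajectory with stored
    velocities (averaged over the trailing ``window`` fraction of frames).
    A channel with no monomers is reported as None, not zero.
    """
    if isinstance(obj, MeltState):
        hot, mass = obj.hot, obj.params.mass
        v2 = np.sum(obj.velocities**2, axis=1)
        th = float(mass * v2[hot].mean() / 3.0) if hot.any() else None
        tc = float(mass * v2[~hot].mean() / 3.0) if (~hot).any() else None
        return th, tc
    if obj.velocities is None:
        raise ValueError("trajectory has no stored velocities")
    if not (0 < window <= 1):
        raise ValueError("window must be in (0, 1]")
    k0 = int(np.floor((1 - window) * obj.n_frames))
    v2 = np.sum(obj.velocities[k0:] ** 2, axis=2)  # (frames, n)
    hot, mass = obj.hot, obj.params.mass
    th = float(mass * v2[:, hot].mean() / 3.0) if hot.any() else None
    tc = float(mass * v2[:, ~hot].mean() / 3.0) if (~hot).any() else None
    return th, tc
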