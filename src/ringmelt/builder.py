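"""Construction of dense melts of unknotted, nonconcatenated rings.

The paper-scale parent configurations of this model come from long
equilibration campaigns; what matters for every analysis downstream is the
set of invariants the melt must satisfy: monomer density rho, all pairwise
linking numbers zero, all rings unknotted, bonds below r_max, and a
prescribed activity pattern.  The builder guarantees the topological
invariants *by construction* rather than by rejection sampling:

1. each ring starts as a compact double-folded loop -- a random-walk spine
   confined to a ball, doubled by a small parallel offset into a closed
   ribbon boundary -- placed in its own disjoint lattice cell of a mildly
   inflated box.  Disjoint convex cells make the rings pairwise unlinked;
   the thin-ribbon construction keeps each ring unknotted, and the folded
   geometry starts the rings near their equilibrium melt size so that
   conformational relaxation is local rather than global;
2. the box is compressed affinely in geometric stages to the target volume
   M*N/rho, interleaving short Langevin relaxation runs with a magnitude-
   capped WCA force (push-off) so overlaps resolve without force blow-ups;
3. the cap is lifted in steps and a short pre-equilibration with the full
   potential follows;
4. the pairwise linking numbers are recomputed as a hard gate; a nonzero
   value (a crossing slipped through the capped phase) triggers a
   deterministic rebuild with a derived seed, then a
   :class:`~ringmelt.errors.BuilderError`.

Full conformational equilibration at paper scale is explicitly not promised
here; callers run their own equilibration phase.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import engine
from .errors import BuilderError
from .params import ModelParameters
from .state import MeltState
from .topology import verify_topology

__all__ = ["build_melt", "assign_activity", "cut_bonds"]

#: near-equilibrium FENE+WCA bond length used to size the initial circles
BOND_LENGTH0 = 0.965


def _grid_dims(M):
    """Smallest (mx, my, mz) grid with mx*my*mz >= M, as cubic as possible."""
    best = None
    mmax = int(np.ceil(M ** (1 / 3))) + 2
    for mx in range(1, mmax + 1):
        for my in range(1, mx + 1):
            for mz in range(1, my + 1):
                if mx * my * mz >= M:
                    key = (mx * my * mz, mx - mz)
                    if best is None or key < best[0]:
                        best = (key, (mx, my, mz))
    return best[1]


def maxwell_boltzmann_velocities(n, T, mass, rng):
    """Velocities drawn from the Maxwell-Boltzmann distribution at T."""
    return rng.normal(scale=np.sqrt(T / mass), size=(n, 3))


def build_melt(
    params: ModelParameters,
    seed: int,
    *,
    relax_steps: int = 400,
    preeq_steps: int = 4000,
    stage_factor: float = 0.92,
    f_cap: float = 200.0,
    push_dt: float = 0.002,
    max_attempts: int = 3,
) -> MeltState:
    """Build a melt at density rho with verified topology.

    Deterministic given ``(params, seed)``.  The returned state has all
    monomers labelled cold and ``time = 0``; call :func:`assign_activity` to
    place the hot arcs.

    Raises
    ------
    BuilderError
        If after ``max_attempts`` deterministic retries the topology gate
        (all pairwise linking numbers zero, bonds < r_max) still fails.
    """
    if params.N < 3:
        raise ValueError("a ring needs at least 3 monomers")
    failures = []
    for attempt in range(max_attempts):
        # derived, deterministic per-attempt seed
        sub = np.random.SeedSequence([int(seed), attempt])
        state = _build_once(
            params, sub, relax_steps, preeq_steps, stage_factor, f_cap, push_dt
        )
        report = verify_topology(state)
        if report.passed:
            return state
        failures.append((attempt, report.linked_pairs, report.max_bond_length))
    raise BuilderError(
        "melt construction failed the topology gate after "
        f"{max_attempts} attempts; diagnostics per attempt "
        f"(attempt, linked_pairs, max_bond): {failures}"
    )


def _confined_walk(m, l0, R_conf, rng, max_tries=40):
    """Random-walk spine of m+1 points confined to a ball of radius R_conf."""
    pts = np.empty((m + 1, 3))
    pts[0] = rng.normal(scale=R_conf / 4.0, size=3)
    for k in range(1, m + 1):
        for _ in range(max_tries):
            u = rng.normal(size=3)
            u *= l0 / np.linalg.norm(u)
            cand = pts[k - 1] + u
            if np.linalg.norm(cand) <= R_conf:
                break
        else:
            # pull straight back toward the center
            d = pts[k - 1] / np.linalg.norm(pts[k - 1])
            cand = pts[k - 1] - l0 * d
        pts[k] = cand
    return pts


def _folded_ring(N, l0, R_conf, rng, offset=0.6):
    """Closed double-folded loop of N monomers inside a ball.

    A confined random-walk spine is traversed out and back, the return
    strand displaced by a fixed small offset; the loop is the boundary of a
    thin ribbon along the spine, hence unknotted, and its size is set by
    the confinement radius rather than by the contour length.
    """
    m = N // 2
    spine = _confined_walk(m, l0, R_conf, rng)
    # offset perpendicular to both turn steps so the two turn bonds stay at
    # sqrt(l0^2 + offset^2) << r_max
    t_end = spine[m] - spine[m - 1]
    t_start = spine[1] - spine[0]
    e = np.cross(t_end, t_start)
    if np.linalg.norm(e) < 1e-6:
        e = np.cross(t_end, t_end + rng.normal(size=3))
    e *= offset / np.linalg.norm(e)
    ring = np.empty((N, 3))
    ring[: m + 1] = spine[: m + 1]
    for i in range(m + 1, N):
        ring[i] = spine[N - i] + e
    return ring


def _build_once(params, seedseq, relax_steps, preeq_steps, stage_factor, f_cap, push_dt):
    p = params
    rng = np.random.default_rng(seedseq)
    N, M = p.N, p.M
    # confinement ball sized for roughly melt-density occupation of the cell
    R_conf = 1.15 * (3.0 * N / (4.0 * np.pi * p.rho)) ** (1.0 / 3.0)
    mx, my, mz = _grid_dims(M)
    spacing = 2.0 * (R_conf + 1.0 * p.sigma)
    box0 = np.array([mx, my, mz], dtype=float) * spacing

    pos = np.empty((M * N, 3))
    cells = [(ix, iy, iz) for ix in range(mx) for iy in range(my) for iz in range(mz)]
    for r in range(M):
        ix, iy, iz = cells[r]
        center = (np.array([ix, iy, iz]) + 0.5) * spacing
        pos[r * N : (r + 1) * N] = center + _folded_ring(
            N, BOND_LENGTH0, R_conf, rng
        )

    vel = maxwell_boltzmann_velocities(M * N, p.T_c, p.mass, rng)
    state = MeltState(
        positions=pos,
        velocities=vel,
        box=box0,
        hot=np.zeros(M * N, dtype=bool),
        closed=np.ones(M, dtype=bool),
        params=dataclasses.replace(p),
        time=0.0,
    )

    target_edge = p.box_edge

    def sub_seed():
        return int(rng.integers(0, 2**31))

    # flat-bottom tethers keep each ring inside its confinement ball for the
    # whole push-off, so rings stay compact instead of ballooning into the
    # temporarily inflated box
    centers0 = np.repeat(
        np.array([( np.array(c) + 0.5) * spacing for c in cells[:M]]), N, axis=0
    )
    radii = np.full(M * N, R_conf + 0.5)
    tether_k = 5.0

    def tether(scale):
        return (centers0 * scale, radii, tether_k)

    # gentle strand separation at fixed box: the doubled ribbon strands
    # start inside each other's WCA core, so the cap is ramped from below
    # the FENE restoring strength upward
    for cap in (10.0, 30.0, 80.0):
        state = engine.step(
            state, relax_steps, sub_seed(), active=False, f_cap=cap, dt=0.001,
            tether=tether(1.0),
        )

    n_stages = max(
        1,
        int(np.ceil(np.max(np.log(target_edge / box0) / np.log(stage_factor)))),
    )
    per_stage = (target_edge / box0) ** (1.0 / n_stages)
    scale = np.ones(3)
    for _ in range(n_stages):
        state.positions *= per_stage
        state.box *= per_stage
        scale = scale * per_stage
        state = engine.step(
            state,
            relax_steps,
            sub_seed(),
            active=False,
            f_cap=f_cap,
            dt=push_dt,
            tether=tether(scale),
        )
    # box is now the exact target (up to fp roundoff); pin it
    state.box = np.full(3, target_edge)

    # lift the cap in two steps (still tethered), then release the tethers
    # for the full-potential pre-equilibration
    state = engine.step(
        state, relax_steps, sub_seed(), active=False, f_cap=5 * f_cap, dt=push_dt,
        tether=tether(scale),
    )
    state = engine.step(state, preeq_steps, sub_seed(), active=False)
    state.time = 0.0
    return state


def assign_activity(
    state: MeltState, N_h: int | None = None, M_a: int | None = None, seed: int = 0
) -> MeltState:
    """Label one contiguous hot arc of N_h monomers on each of M_a rings.

    Which rings are active and where each arc starts on its contour are
    drawn uniformly from ``seed`` (the model does not distinguish contour
    positions).  The remaining monomers, and all monomers of the M - M_a
    inactive rings, are cold.  Returns a relabelled copy.
    """
    p = state.params
    N_h = p.N_h if N_h is None else int(N_h)
    M_a = p.M_a if M_a is None else int(M_a)
    if not (0 <= N_h <= p.N):
        raise ValueError(f"N_h={N_h} outside [0, N]")
    if not (0 <= M_a <= p.M):
        raise ValueError(f"M_a={M_a} outside [0, M]")
    rng = np.random.default_rng(seed)
    new = state.copy()
    new.params = dataclasses.replace(p, N_h=N_h, M_a=M_a)
    hot = np.zeros((p.M, p.N), dtype=bool)
    if N_h > 0 and M_a > 0:
        active_rings = rng.choice(p.M, size=M_a, replace=False)
        starts = rng.integers(0, p.N, size=M_a)
        idx = np.arange(N_h)
        for r, s in zip(active_rings, starts):
            hot[r, (s + idx) % p.N] = True
    new.hot = hot.ravel()
    return new


def _contour_rotate(arr_block, shift):
    return np.roll(arr_block, -shift, axis=0)


def cut_bonds(state: MeltState) -> MeltState:
    """Cut the cold bond antipodal to each hot arc, making triblock chains.

    On every ring the single bond between the two cold monomers farthest
    (along the contour) from the midpoint of the hot arc is removed; each
    chain becomes a linear cold--hot--cold triblock of length N with both
    ends cold and the hot arc interior.  Internally the contour is relabelled
    so the cut coincides with the ring's block boundary; positions,
    velocities and labels are permuted consistently.

    Raises
    ------
    ValueError
        If a ring has no hot arc (the antipode is undefined) or no cold
        segment of length >= 2 (no cold bond to cut).
    """
    p = state.params
    N, M = p.N, p.M
    new = state.copy()
    hot = state.hot.reshape(M, N)
    for r in range(M):
        if not state.closed[r]:
            raise ValueError(f"ring {r} is already cut")
        h = np.flatnonzero(hot[r])
        if h.size == 0:
            raise ValueError(f"ring {r} has no hot arc; cut point undefined")
        if h.size > N - 2:
            raise ValueError(f"ring {r} has no cold segment of length >= 2")
        # hot arc is contiguous on the cycle; find its start
        if h.size == N:
            raise ValueError(f"ring {r} is fully hot")
        cold_mask = ~hot[r]
        # arc start: hot monomer whose predecessor is cold
        starts = h[cold_mask[(h - 1) % N]]
        if starts.size != 1:
            raise ValueError(f"ring {r}: hot labels are not one contiguous arc")
        start = int(starts[0])
        mid = start + (h.size - 1) / 2.0
        cut_bond = int(np.floor(mid + N / 2.0)) % N  # bond (cut_bond, cut_bond+1)
        a, b = cut_bond, (cut_bond + 1) % N
        if hot[r, a] or hot[r, b]:
            raise ValueError(
                f"ring {r}: antipodal bond ({a},{b}) is not cold-cold; "
                "hot arc too long to cut"
            )
        # relabel so the chain runs b, b+1, ..., a (cut at block boundary)
        sl = state.ring_slice(r)
        shift = b
        new.positions[sl] = _contour_rotate(state.positions[sl], shift)
        new.velocities[sl] = _contour_rotate(state.velocities[sl], shift)
        new.hot[sl] = _contour_rotate(hot[r], shift)
        new.closed[r] = False
    return new
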