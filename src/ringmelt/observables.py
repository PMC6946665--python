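"""Structural and dynamic observables of the melt.

All displacement-based observables (g3, ISF, EB, displacement
distributions, cold--hot directionality) are evaluated in the
system-center-of-mass frame of each snapshot: the Langevin thermostats do
not conserve momentum, and the resulting slow drift of the global center of
mass would otherwise contaminate every mean squared displacement.  Aging is
made explicit by the measurement origin ``t0`` (time 0 = activity onset),
and averages run over chains only -- no multiple-time-origin averaging,
since the dynamics is not stationary.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .state import Trajectory

__all__ = [
    "ObservableSeries",
    "radius_of_gyration",
    "segment_radius_of_gyration",
    "g3",
    "self_isf",
    "nonergodicity_parameter",
    "ergodicity_breaking",
    "cold_hot_vector",
    "internal_distances",
    "fit_power_law",
    "displacement_distribution",
    "hot_neighbor_count",
    "uniform_neighbor_expectation",
    "structure_factor",
]


@dataclasses.dataclass
class ObservableSeries:
    """A named 1-D observable with its independent variable and metadata."""

    name: str
    x: np.ndarray
    y: np.ndarray
    xlabel: str = "t"
    yerr: np.ndarray | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write(f"# observable\t{self.name}\n")
            for k, v in sorted(self.meta.items()):
                fh.write(f"# {k}\t{v}\n")
            fh.write(f"{self.xlabel}\t{self.name}")
            fh.write("\terr\n" if self.yerr is not None else "\n")
            for i in range(len(self.x)):
                row = f"{self.x[i]:.10g}\t{self.y[i]:.10g}"
                if self.yerr is not None:
                    row += f"\t{self.yerr[i]:.10g}"
                fh.write(row + "\n")


def _check_unwrapped(state_or_traj):
    """Reject coordinates that look wrapped (a bond jumping over half a box)."""
    if isinstance(state_or_traj, Trajectory):
        pos = state_or_traj.positions[0]
        box = state_or_traj.box
        N, M = state_or_traj.N, state_or_traj.M
    else:
        pos = state_or_traj.positions
        box = state_or_traj.box
        N, M = state_or_traj.N, state_or_traj.M
    p = pos.reshape(M, N, 3)
    jumps = np.abs(np.diff(p, axis=1))
    if np.any(jumps > box / 2):
        raise ValueError(
            "bond vector exceeds half the box: coordinates appear wrapped; "
            "unwrap per ring before computing conformational observables"
        )


# --------------------------------------------------------------------------
# conformation
# --------------------------------------------------------------------------


def radius_of_gyration(state, selection=None) -> float:
    """Root-mean radius of gyration <R_g^2>^(1/2) over chains (sigma).

    ``selection``: optional (M, N) or flat boolean mask choosing a
    per-chain monomer subset (e.g. the hot arc); the same number of
    monomers must be selected on every chain.
    """
    _check_unwrapped(state)
    M, N = state.M, state.N
    p = state.positions.reshape(M, N, 3)
    if selection is not None:
        mask = np.asarray(selection, dtype=bool).reshape(M, N)
        counts = mask.sum(axis=1)
        if counts.min() == 0:
            raise ValueError("selection empty on some chain")
        if len(set(counts.tolist())) != 1:
            raise ValueError("selection must pick equally many monomers per chain")
        p = p[mask].reshape(M, counts[0], 3)
    com = p.mean(axis=1, keepdims=True)
    rg2 = np.mean(np.sum((p - com) ** 2, axis=2), axis=1)
    return float(np.sqrt(rg2.mean()))


def segment_radius_of_gyration(state, s: int) -> float:
    """<R_g^2>^(1/2) of contour segments of length ``s`` monomers.

    Averaged over all cyclic start positions and all rings; the standard
    internal-segment size used e.g. for the hot arc (s = N_h).
    """
    _check_unwrapped(state)
    M, N = state.M, state.N
    if not (1 <= s <= N):
        raise ValueError("segment length outside [1, N]")
    p = state.positions.reshape(M, N, 3)
    ext = np.concatenate([p, p[:, : s - 1]], axis=1)  # cyclic windows
    w = np.lib.stride_tricks.sliding_window_view(ext, (s,), axis=1)  # (M,N,3,s)
    com = w.mean(axis=3, keepdims=True)
    rg2 = np.mean(np.sum((w - com) ** 2, axis=2), axis=2)
    return float(np.sqrt(rg2.mean()))


# --------------------------------------------------------------------------
# displacements
# --------------------------------------------------------------------------


def g3(traj: Trajectory, t0: float = 0.0) -> ObservableSeries:
    """Mean squared displacement of ring centers of mass from origin t0.

    g3(t, t0) = <[R(t0+t) - R(t0)]^2>, R in the system-COM frame, averaged
    over rings only.  The series starts at lag 0 with value 0.
    """
    k0 = traj.frame_index(t0)
    R = traj.ring_coms_relative()
    disp = R[k0:] - R[k0]
    y = np.mean(np.sum(disp**2, axis=2), axis=1)
    sem = np.std(np.sum(disp**2, axis=2), axis=1, ddof=1) / np.sqrt(traj.M) \
        if traj.M > 1 else np.zeros(len(y))
    return ObservableSeries(
        name="g3",
        x=traj.times[k0:] - traj.times[k0],
        y=y,
        yerr=sem,
        meta={"t0": t0, "n_rings": traj.M, "frame": "system-com"},
    )


def _lattice_qvectors(box, q_target, shell_width=0.02, tol=0.05):
    """Box-compatible wavevectors with |q| in a shell around q_target.

    Components are integer multiples of 2 pi / L; the shell has relative
    half-width ``shell_width``.  Falls back to the nearest available
    magnitude within ``tol`` (5%) or raises with the nearest magnitudes.
    """
    box = np.asarray(box, dtype=float)
    dq = 2 * np.pi / box
    nmax = np.maximum(1, np.ceil(q_target * (1 + tol) / dq)).astype(int) + 1
    grids = np.meshgrid(*[np.arange(-n, n + 1) for n in nmax], indexing="ij")
    ints = np.stack([g.ravel() for g in grids], axis=1)
    ints = ints[np.any(ints != 0, axis=1)]
    qs = ints * dq
    mags = np.linalg.norm(qs, axis=1)
    lo, hi = q_target * (1 - shell_width), q_target * (1 + shell_width)
    sel = (mags >= lo) & (mags <= hi)
    if not sel.any():
        nearest = mags[np.argmin(np.abs(mags - q_target))]
        if abs(nearest - q_target) / q_target <= tol:
            sel = np.abs(mags - nearest) < 1e-9
        else:
            uniq = np.unique(np.round(mags, 6))
            raise ValueError(
                f"no box-compatible q within {tol:.0%} of {q_target}; "
                f"nearest magnitudes: {uniq[np.argsort(np.abs(uniq - q_target))][:5]}"
            )
    return qs[sel]


def self_isf(
    traj: Trajectory, q_magnitude: float, t0: float = 0.0, shell_width=0.02
) -> ObservableSeries:
    """Self intermediate scattering function of the ring centers of mass.

    F_s(q, t, t0) = (1/M) sum_m exp(i q . [R_m(t0+t) - R_m(t0)]), averaged
    over a shell of lattice-compatible q-vectors nearest the requested
    magnitude; the real part is reported.
    """
    k0 = traj.frame_index(t0)
    qs = _lattice_qvectors(traj.box, q_magnitude, shell_width)
    R = traj.ring_coms_relative()
    disp = R[k0:] - R[k0]  # (F, M, 3)
    phase = np.einsum("fmd,qd->fmq", disp, qs)
    y = np.mean(np.cos(phase), axis=(1, 2))
    return ObservableSeries(
        name="F_s",
        x=traj.times[k0:] - traj.times[k0],
        y=y,
        meta={
            "t0": t0,
            "q_requested": q_magnitude,
            "q_mean": float(np.mean(np.linalg.norm(qs, axis=1))),
            "n_qvectors": len(qs),
        },
    )


def nonergodicity_parameter(
    traj: Trajectory, t0: float, q_grid, shell_width=0.02
) -> ObservableSeries:
    """f(q, t0): the ISF evaluated at the last available lag for each q."""
    vals = []
    for q in q_grid:
        series = self_isf(traj, q, t0, shell_width)
        vals.append(series.y[-1])
    return ObservableSeries(
        name="f_q",
        x=np.asarray(q_grid, dtype=float),
        y=np.array(vals),
        xlabel="q",
        meta={"t0": t0, "t_max": float(traj.times[-1] - t0)},
    )


def time_averaged_g3(traj: Trajectory, t0: float, delta: float, t: float):
    """Per-ring time average of the squared displacement at lag ``delta``.

    g3bar_m(t; t0, Delta) = 1/(t - Delta) * integral over t' in
    [t0, t0 + t - Delta] of [R_m(t'+Delta) - R_m(t')]^2 dt', evaluated by
    the trapezoidal rule at the frame spacing.  Returns an (M,) array.
    """
    if t <= delta:
        raise ValueError("window t must exceed the lag Delta")
    k0 = traj.frame_index(t0)
    times = traj.times
    dt_frame = times[k0 + 1] - times[k0]
    nd = int(round(delta / dt_frame))
    if nd < 1 or abs(nd * dt_frame - delta) > 1e-6 * max(delta, 1.0):
        raise ValueError("Delta must be a multiple of the frame spacing")
    nt = int(round((t - delta) / dt_frame))
    if k0 + nt + nd >= traj.n_frames + 1:
        raise ValueError("window extends beyond the trajectory")
    R = traj.ring_coms_relative()
    sq = np.sum((R[k0 + nd : k0 + nd + nt + 1] - R[k0 : k0 + nt + 1]) ** 2, axis=2)
    return np.trapezoid(sq, dx=dt_frame, axis=0) / (t - delta)


def ergodicity_breaking(
    traj: Trajectory, t0: float, delta: float, t_grid
) -> ObservableSeries:
    """EB(t) = relative variance across rings of the time-averaged g3.

    Decays as (4/3) Delta/t for ergodic Brownian chains; a plateau signals
    broken ergodicity.  Degenerate single-ring input yields EB = 0 (flagged
    in the metadata).
    """
    degenerate = traj.M < 2
    ys = []
    for t in t_grid:
        bar = time_averaged_g3(traj, t0, delta, t)
        mean = bar.mean()
        ys.append(0.0 if degenerate else float(bar.var() / mean**2))
    return ObservableSeries(
        name="EB",
        x=np.asarray(t_grid, dtype=float),
        y=np.array(ys),
        meta={"t0": t0, "delta": delta, "degenerate_single_ring": degenerate},
    )


# --------------------------------------------------------------------------
# directionality
# --------------------------------------------------------------------------


def cold_hot_vector(traj: Trajectory, t0: float = 0.0, delta: float | None = None):
    """|ch| series and the displacement--ch directionality correlation.

    ch(t) = COM(hot arc) - COM(cold block) per active ring.  The
    directionality correlation is <e_d(t+Delta) . e_ch(t)> over active
    rings, with d(t) = R(t+Delta) - R(t) the COM displacement (system-COM
    frame).  Fully passive rings are excluded from the averages.
    Returns (magnitude_series, correlation_series or None if delta is None).
    """
    k0 = traj.frame_index(t0)
    M, N = traj.M, traj.N
    hot = traj.hot.reshape(M, N)
    active = hot.any(axis=1)
    if not active.any():
        raise ValueError("no active rings: cold-hot vector undefined")
    pos = traj.positions[k0:].reshape(-1, M, N, 3)
    F = pos.shape[0]
    ch = np.empty((F, int(active.sum()), 3))
    for a, r in enumerate(np.flatnonzero(active)):
        ch[:, a] = pos[:, r, hot[r]].mean(axis=1) - pos[:, r, ~hot[r]].mean(axis=1)
    mag = np.linalg.norm(ch, axis=2).mean(axis=1)
    mag_series = ObservableSeries(
        name="|ch|",
        x=traj.times[k0:] - traj.times[k0],
        y=mag,
        meta={"t0": t0, "n_active_rings": int(active.sum())},
    )
    if delta is None:
        return mag_series, None
    dt_frame = traj.times[k0 + 1] - traj.times[k0]
    nd = int(round(delta / dt_frame))
    if nd < 1:
        raise ValueError("Delta below the frame spacing")
    R = traj.ring_coms_relative()[k0:, active]
    d = R[nd:] - R[:-nd]  # (F-nd, Ma, 3)
    e_d = d / np.maximum(np.linalg.norm(d, axis=2, keepdims=True), 1e-300)
    ch_t = ch[:-nd]
    e_ch = ch_t / np.maximum(np.linalg.norm(ch_t, axis=2, keepdims=True), 1e-300)
    corr = np.mean(np.sum(e_d * e_ch, axis=2), axis=1)
    corr_series = ObservableSeries(
        name="e_d.e_ch",
        x=traj.times[k0 : k0 + len(corr)] - traj.times[k0],
        y=corr,
        meta={"t0": t0, "delta": nd * dt_frame},
    )
    return mag_series, corr_series


# --------------------------------------------------------------------------
# internal distances
# --------------------------------------------------------------------------


def internal_distances(
    traj_or_state,
    block: str,
    s_values,
    frame_indices=None,
    fit_window=None,
):
    """Mean squared internal distances <R^2(s)> within one block.

    For every contour separation s the squared end-to-end distance of
    s-monomer subsegments lying entirely inside the named block ('hot' or
    'cold') is averaged over start positions, rings and frames.  If
    ``fit_window`` (s_lo, s_hi) is given, the scaling exponent nu of
    R(s) ~ s^nu is fitted by least squares on log-log axes and returned in
    the metadata together with its standard error.
    """
    if isinstance(traj_or_state, Trajectory):
        traj = traj_or_state
        frames = frame_indices if frame_indices is not None else range(traj.n_frames)
        pos = traj.positions[list(frames)]
        M, N = traj.M, traj.N
        hot = traj.hot.reshape(M, N)
    else:
        st = traj_or_state
        pos = st.positions[None]
        M, N = st.M, st.N
        hot = st.hot.reshape(M, N)
    if block not in ("hot", "cold"):
        raise ValueError("block must be 'hot' or 'cold'")
    s_values = np.asarray(s_values, dtype=int)
    pos = pos.reshape(len(pos), M, N, 3)

    # per ring: contiguous block start and length on the cycle
    block_idx = []
    for r in range(M):
        mask = hot[r] if block == "hot" else ~hot[r]
        n_blk = int(mask.sum())
        if n_blk == 0:
            continue
        if n_blk == N:
            block_idx.append((r, 0, N))
            continue
        starts = np.flatnonzero(mask & ~np.roll(mask, 1))
        if len(starts) != 1:
            raise ValueError(f"ring {r}: {block} block is not contiguous")
        block_idx.append((r, int(starts[0]), n_blk))
    if not block_idx:
        raise ValueError(f"no ring carries a {block} block")
    max_len = max(n for _, _, n in block_idx)
    if s_values.max() >= max_len:
        raise ValueError(
            f"s={s_values.max()} does not fit in the longest {block} block "
            f"({max_len} monomers)"
        )

    y = np.zeros(len(s_values))
    for si, s in enumerate(s_values):
        acc, cnt = 0.0, 0
        for r, start, n_blk in block_idx:
            if s >= n_blk:
                continue
            idx = (start + np.arange(n_blk)) % N
            seg = pos[:, r, idx]  # (F, n_blk, 3)
            d = seg[:, s:] - seg[:, :-s]
            acc += float(np.sum(d**2))
            cnt += d.shape[0] * d.shape[1]
        y[si] = acc / cnt
    series = ObservableSeries(
        name="R2_internal",
        x=s_values.astype(float),
        y=y,
        xlabel="s",
        meta={"block": block},
    )
    if fit_window is not None:
        nu, nu_err, _ = fit_power_law(series.x, np.sqrt(series.y), fit_window)
        series.meta.update({"nu": nu, "nu_stderr": nu_err})
    return series


def fit_power_law(x, y, window=None):
    """Least-squares power-law fit y ~ x^alpha on log-log axes.

    Returns (alpha, stderr, prefactor).  ``window = (x_lo, x_hi)`` restricts
    the fit range.  This is the exact fit used for the trail exponent
    nu_trail, the superdiffusion exponent of g3/t analyses and the Brownian
    checks; expose it so larger-scale runs can reuse it unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sel = (x > 0) & (y > 0)
    if window is not None:
        sel &= (x >= window[0]) & (x <= window[1])
    if sel.sum() < 3:
        raise ValueError("need at least 3 points in the fit window")
    res = stats.linregress(np.log(x[sel]), np.log(y[sel]))
    return float(res.slope), float(res.stderr), float(np.exp(res.intercept))


# --------------------------------------------------------------------------
# displacement statistics
# --------------------------------------------------------------------------


def displacement_distribution(
    traj: Trajectory, delta: float, axis: int = 0, t_min: float = 0.0, bins=41
):
    """1-D ring-COM displacement histogram at lag Delta, plus excess kurtosis.

    Displacements are collected for every frame pair separated by Delta with
    start time >= t_min (system-COM frame).  Returns (histogram density,
    bin_edges, kappa) with kappa = m4/m2^2 - 3.
    """
    times = traj.times
    dt_frame = times[1] - times[0]
    nd = int(round(delta / dt_frame))
    if nd < 1 or nd >= traj.n_frames:
        raise ValueError("lag outside the trajectory")
    k_min = int(np.searchsorted(times, t_min - 1e-9))
    R = traj.ring_coms_relative()[:, :, axis]
    d = (R[nd:] - R[:-nd])[k_min:]
    d = d.ravel()
    if d.size < 2:
        raise ValueError("need at least 2 frames at the requested lag")
    hist, edges = np.histogram(d, bins=bins, density=True)
    kappa = float(stats.kurtosis(d, fisher=True, bias=True))
    return hist, edges, kappa


# --------------------------------------------------------------------------
# neighbor counts and structure factor
# --------------------------------------------------------------------------


def _segment_coms(state):
    """(M_a, 3) hot-arc centers of mass of the active rings (unwrapped)."""
    M, N = state.M, state.N
    hot = state.hot.reshape(M, N)
    coms = []
    for r in range(M):
        if hot[r].any():
            coms.append(state.positions[state.ring_slice(r)][hot[r]].mean(axis=0))
    return np.array(coms)


def hot_neighbor_count(state, cutoff: float = 3.25) -> float:
    """Mean number of neighboring hot segments within ``cutoff`` (minimum image).

    Two hot segments are neighbors when their centers of mass lie within
    ``cutoff`` -- by convention the segment radius of gyration, 3.25 sigma at
    production scale.  Returns 0 for systems with fewer than two hot arcs.
    """
    coms = _segment_coms(state)
    if len(coms) < 2:
        return 0.0
    box = state.box
    d = coms[:, None, :] - coms[None, :, :]
    d -= box * np.rint(d / box)
    r = np.sqrt(np.sum(d**2, axis=2))
    np.fill_diagonal(r, np.inf)
    return float((r < cutoff).sum(axis=1).mean())


def uniform_neighbor_expectation(M, N, rho, cutoff=3.25, exclude_self=True):
    """Expected neighbor count for uniformly random segment positions.

    (4/3) pi cutoff^3 * (M - 1)/V with V = M N / rho; the density of *other*
    segments inside the neighbor sphere.  With ``exclude_self=False`` the
    M/V convention is used instead (indistinguishable at production scale).
    """
    V = M * N / rho
    m_eff = (M - 1) if exclude_self else M
    return (4.0 / 3.0) * np.pi * cutoff**3 * m_eff / V


def structure_factor(points, box, q_magnitudes, shell_width=0.05):
    """Isotropically averaged static structure factor of a point set.

    S(q) = (1/M) |sum_m exp(i q . R_m)|^2 averaged over lattice-compatible
    wavevectors in a shell per magnitude bin.  Returns an ObservableSeries
    whose metadata records q* = argmax S(q).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    vals = []
    for q in q_magnitudes:
        qs = _lattice_qvectors(box, q, shell_width, tol=0.5)
        phase = points @ qs.T  # (M, nq)
        s = (np.cos(phase).sum(axis=0) ** 2 + np.sin(phase).sum(axis=0) ** 2) / len(
            points
        )
        vals.append(float(s.mean()))
    y = np.array(vals)
    x = np.asarray(q_magnitudes, dtype=float)
    return ObservableSeries(
        name="S_q",
        x=x,
        y=y,
        xlabel="q",
        meta={"q_star": float(x[np.argmax(y)])},
    )
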