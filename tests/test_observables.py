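"""Observables against analytic references on synthetic trajectories."""

import numpy as np
import pytest

from ringmelt.observables import (
    cold_hot_vector,
    displacement_distribution,
    ergodicity_breaking,
    fit_power_law,
    g3,
    hot_neighbor_count,
    internal_distances,
    nonergodicity_parameter,
    radius_of_gyration,
    segment_radius_of_gyration,
    self_isf,
    structure_factor,
    uniform_neighbor_expectation,
)
from ringmelt.params import ModelParameters
from ringmelt.state import MeltState, Trajectory


def make_state(pos, M, N, hot=None, box=1e6):
    params = ModelParameters(N=N, M=M)
    n = M * N
    return MeltState(
        positions=np.asarray(pos, dtype=float).reshape(n, 3),
        velocities=np.zeros((n, 3)),
        box=np.full(3, box),
        hot=np.zeros(n, dtype=bool) if hot is None else hot,
        closed=np.ones(M, dtype=bool),
        params=params,
    )


def make_traj(pos_frames, M, N, hot=None, dt_frame=1.0, box=1e6):
    F = len(pos_frames)
    params = ModelParameters(N=N, M=M)
    return Trajectory(
        times=np.arange(F) * dt_frame,
        positions=np.asarray(pos_frames, dtype=float).reshape(F, M * N, 3),
        box=np.full(3, box),
        hot=np.zeros(M * N, dtype=bool) if hot is None else hot,
        closed=np.ones(M, dtype=bool),
        params=params,
    )


# -- radius of gyration -----------------------------------------------------


def test_rg_unit_square():
    pos = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    state = make_state(pos, M=1, N=4)
    assert radius_of_gyration(state) == pytest.approx(np.sqrt(0.5))


def test_rg_coincident_zero():
    state = make_state(np.zeros((6, 3)), M=1, N=6)
    assert radius_of_gyration(state) == 0.0


def test_rg_wrapped_coordinates_rejected():
    pos = np.zeros((8, 3))
    pos[4, 0] = 9.0  # jump larger than box/2
    state = make_state(pos, M=1, N=8, box=10.0)
    with pytest.raises(ValueError):
        radius_of_gyration(state)


def test_segment_rg_straight_rod():
    """For a rod with unit bonds, a 4-monomer segment has R_g^2 = 5/4."""
    N = 12
    pos = np.zeros((N, 3))
    pos[:, 0] = np.arange(N)
    # cyclic windows on a rod include wrap-around windows; use a ring-shaped
    # regular polygon instead for an exact closed form at s = N
    state = make_state(pos, M=1, N=N)
    rg_full = segment_radius_of_gyration(state, N)
    expected = np.sqrt(np.mean((np.arange(N) - (N - 1) / 2) ** 2))
    assert rg_full == pytest.approx(expected)


# -- g3 ---------------------------------------------------------------------


def test_g3_zero_at_origin_and_rigid_motion(brownian_traj):
    traj, _ = brownian_traj
    series = g3(traj, t0=0.0)
    assert series.y[0] == 0.0
    # rigid uniform translation of everything: g3 stays 0 (system-COM frame)
    F = 10
    shift = np.arange(F)[:, None, None] * np.array([1.0, 2.0, 3.0])
    pos = np.zeros((F, 5, 3)) + shift
    rigid = make_traj(pos, M=5, N=1)
    assert np.allclose(g3(rigid, 0.0).y, 0.0, atol=1e-20)


def test_g3_brownian_slope(brownian_traj):
    """Independent Brownian centers: g3 slope = 6D (with (M-1)/M COM bias)."""
    traj, D = brownian_traj
    series = g3(traj, t0=0.0)
    # late-lag linear fit through the origin
    sel = series.x > 50
    slope = np.sum(series.y[sel] * series.x[sel]) / np.sum(series.x[sel] ** 2)
    # subtracting the system COM rescales MSD by (M-1)/M
    expected = 6 * D * (traj.M - 1) / traj.M
    assert slope == pytest.approx(expected, rel=0.12)


def test_g3_requires_frame_time(brownian_traj):
    traj, _ = brownian_traj
    with pytest.raises(ValueError):
        g3(traj, t0=0.123)


# -- ISF --------------------------------------------------------------------


def test_isf_unity_at_zero_and_frozen():
    F, M = 6, 40
    rng = np.random.default_rng(0)
    base = rng.uniform(0, 30, size=(M, 3))
    traj = make_traj(np.repeat(base[None], F, axis=0), M=M, N=1, box=30.0)
    series = self_isf(traj, 0.7, t0=0.0)
    assert np.allclose(series.y, 1.0)


def test_isf_gaussian_closed_form():
    """Isotropic Gaussian displacements: F_s = exp(-q^2 s^2 / 2)."""
    rng = np.random.default_rng(4)
    M, box = 4000, 40.0
    s = 1.3
    base = rng.uniform(0, box, size=(M, 3))
    disp = rng.normal(scale=s, size=(M, 3))
    disp -= disp.mean(axis=0)  # measured in the system-COM frame anyway
    traj = make_traj(np.stack([base, base + disp]), M=M, N=1, box=box)
    for q in (0.5, 1.0):
        series = self_isf(traj, q, t0=0.0)
        qm = series.meta["q_mean"]
        assert series.y[0] == pytest.approx(1.0)
        assert series.y[1] == pytest.approx(np.exp(-(qm**2) * s**2 / 2), abs=0.02)


def test_isf_incompatible_q_errors():
    traj = make_traj(np.zeros((2, 5, 3)), M=5, N=1, box=10.0)
    with pytest.raises(ValueError, match="nearest"):
        self_isf(traj, 0.05, t0=0.0)  # far below 2 pi / L


def test_nonergodicity_parameter_limits():
    rng = np.random.default_rng(1)
    M, box = 500, 20.0
    base = rng.uniform(0, box, size=(M, 3))
    # q grid commensurate with the box (2 pi / 20 = 0.314 and multiples)
    frozen = make_traj(np.repeat(base[None], 4, axis=0), M=M, N=1, box=box)
    f = nonergodicity_parameter(frozen, 0.0, q_grid=[0.444, 0.628, 0.994])
    assert np.allclose(f.y, 1.0)
    # fully decorrelated positions: f ~ 0
    moved = np.stack([base, base + rng.uniform(0, box, size=(M, 3))])
    diff = make_traj(moved, M=M, N=1, box=box)
    f2 = nonergodicity_parameter(diff, 0.0, q_grid=[0.628, 0.994])
    assert np.all(np.abs(f2.y) < 0.1)


# -- EB ---------------------------------------------------------------------


def test_eb_identical_rings_zero():
    F, M = 50, 8
    walk = np.cumsum(np.random.default_rng(2).normal(size=(F, 1, 3)), axis=0)
    traj = make_traj(np.repeat(walk, M, axis=1), M=M, N=1)
    series = ergodicity_breaking(traj, 0.0, delta=2.0, t_grid=[10.0, 20.0])
    assert np.allclose(series.y, 0.0, atol=1e-20)


def test_eb_brownian_decay(brownian_traj):
    """Independent Brownian rings: EB follows the 3-D time-averaged-MSD
    law (4/9) Delta / t within a factor 1.5 over one decade (the 1-D
    coefficient would be 4/3; the three components average independently)."""
    traj, _ = brownian_traj
    delta = 8.0
    t_grid = [40.0, 80.0, 160.0, 320.0]
    series = ergodicity_breaking(traj, 0.0, delta, t_grid)
    expected = (4 / 9) * delta / np.asarray(t_grid)
    ratio = series.y / expected
    assert np.all((ratio > 1 / 1.5) & (ratio < 1.5))


def test_eb_rotation_invariant(brownian_traj):
    traj, _ = brownian_traj
    rng = np.random.default_rng(9)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    rotated = make_traj(
        traj.positions @ Q.T, M=traj.M, N=traj.N, dt_frame=1.0
    )
    a = ergodicity_breaking(traj, 0.0, 2.0, [50.0]).y
    b = ergodicity_breaking(rotated, 0.0, 2.0, [50.0]).y
    assert a == pytest.approx(b, rel=1e-9)


def test_eb_window_validation(brownian_traj):
    traj, _ = brownian_traj
    with pytest.raises(ValueError):
        ergodicity_breaking(traj, 0.0, delta=10.0, t_grid=[5.0])


# -- cold-hot vector --------------------------------------------------------


def _two_block_traj(disp_along_ch=True, F=6, M=20):
    """Rings of 4 monomers: first 2 hot at +x of the cold pair."""
    N = 4
    rng = np.random.default_rng(11)
    base = rng.uniform(0, 10, size=(M, 1, 3)) * 0
    ring = np.array([[1, 0, 0], [1.5, 0, 0], [0, 0, 0], [0.5, 0, 0]], dtype=float)
    pos0 = (base + ring).reshape(M * N, 3) + rng.uniform(0, 40, (M, 1, 3)).repeat(N, 1).reshape(M * N, 3)
    frames = []
    for f in range(F):
        if disp_along_ch:
            d = np.array([1.0, 0, 0]) * f
            frames.append(pos0 + d)
        else:
            frames.append(pos0 + rng.normal(size=(M * N, 3)))
    hot = np.tile([True, True, False, False], M)
    return make_traj(frames, M=M, N=N, hot=hot)


def test_ch_magnitude():
    traj = _two_block_traj()
    mag, _ = cold_hot_vector(traj, 0.0)
    assert np.allclose(mag.y, 1.0)  # COM(hot)=1.25, COM(cold)=0.25 along x


def test_ch_displacement_alignment():
    """Rigid translation breaks in the COM frame; use per-ring displacement
    exactly along ch instead."""
    N, M, F = 4, 30, 5
    ring = np.array([[1, 0, 0], [1.5, 0, 0], [0, 0, 0], [0.5, 0, 0]], dtype=float)
    rng = np.random.default_rng(3)
    centers = rng.uniform(0, 50, size=(M, 3))
    dirs = rng.normal(size=(M, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    # orient each ring's contour along its own direction
    frames = []
    for f in range(F):
        pos = np.empty((M, N, 3))
        for m in range(M):
            e = dirs[m]
            local = ring[:, :1] * e[None, :]
            pos[m] = centers[m] + local + f * e  # moves along its own ch
        frames.append(pos.reshape(M * N, 3))
    hot = np.tile([True, True, False, False], M)
    traj = make_traj(frames, M=M, N=N, hot=hot)
    _, corr = cold_hot_vector(traj, 0.0, delta=1.0)
    # random directions average out in the COM frame correction
    assert np.all(corr.y > 0.9)


def test_ch_random_displacements_decorrelate():
    traj = _two_block_traj(disp_along_ch=False, F=40, M=40)
    _, corr = cold_hot_vector(traj, 0.0, delta=1.0)
    assert abs(corr.y.mean()) < 3 / np.sqrt(40 * len(corr.y))  # null-model bound


def test_ch_requires_active_rings():
    traj = make_traj(np.zeros((3, 8, 3)), M=2, N=4)
    with pytest.raises(ValueError):
        cold_hot_vector(traj, 0.0)


# -- internal distances -----------------------------------------------------


def test_internal_distances_rod():
    """Straight rod with unit bonds: R^2(s) = s^2, exponent 1."""
    N, M = 40, 1
    pos = np.zeros((N, 3))
    pos[:, 0] = np.arange(N)
    hot = np.zeros(N, dtype=bool)
    hot[:20] = True  # hot block = first half (contiguous)
    state = make_state(pos, M=M, N=N, hot=hot)
    s_vals = [1, 2, 4, 8, 16]
    series = internal_distances(state, "hot", s_vals, fit_window=(1, 16))
    assert np.allclose(series.y, np.asarray(s_vals, dtype=float) ** 2)
    assert series.meta["nu"] == pytest.approx(1.0, abs=1e-9)


def test_internal_distances_random_walk_exponent():
    """Freely jointed block: nu = 0.5 within fitting error."""
    rng = np.random.default_rng(21)
    M, N = 200, 64
    steps = rng.normal(size=(M, N - 1, 3))
    steps /= np.linalg.norm(steps, axis=2, keepdims=True)
    pos = np.concatenate([np.zeros((M, 1, 3)), np.cumsum(steps, axis=1)], axis=1)
    hot = np.zeros((M, N), dtype=bool)
    hot[:, :32] = True
    state = make_state(pos.reshape(-1, 3), M=M, N=N, hot=hot.ravel())
    series = internal_distances(
        state, "hot", [2, 4, 8, 16, 24], fit_window=(2, 24)
    )
    assert series.meta["nu"] == pytest.approx(0.5, abs=0.05)


def test_internal_distances_block_overflow():
    state = make_state(np.zeros((20, 3)), M=1, N=20)
    with pytest.raises(ValueError):
        internal_distances(state, "cold", [25])


def test_fit_power_law_recovers_exponent():
    x = np.logspace(0, 3, 40)
    for alpha in (0.36, 0.8, 1.13):
        y = 2.5 * x**alpha
        a, err, pref = fit_power_law(x, y)
        assert a == pytest.approx(alpha, abs=1e-12)
        assert pref == pytest.approx(2.5, rel=1e-9)


def test_fit_power_law_noisy_recovery():
    """Prescribed growth exponent alpha recovered within +-0.03."""
    rng = np.random.default_rng(6)
    x = np.logspace(0.5, 2.5, 30)
    for alpha in (0.57, 1.13):
        y = x**alpha * np.exp(rng.normal(scale=0.02, size=len(x)))
        a, err, _ = fit_power_law(x, y)
        assert a == pytest.approx(alpha, abs=0.03)


# -- displacement distribution ---------------------------------------------


def test_kurtosis_gaussian_and_laplace():
    rng = np.random.default_rng(17)
    M, F = 400, 61
    # independent per-frame COM jumps; Gaussian case
    jumps = rng.normal(size=(F - 1, M, 3))
    pos = np.concatenate([np.zeros((1, M, 3)), np.cumsum(jumps, axis=0)])
    traj = make_traj(pos, M=M, N=1)
    _, _, kappa = displacement_distribution(traj, delta=1.0, axis=0)
    assert kappa == pytest.approx(0.0, abs=0.2)
    # Laplace jumps: excess kurtosis 3
    jumps = rng.laplace(size=(F - 1, M, 3))
    pos = np.concatenate([np.zeros((1, M, 3)), np.cumsum(jumps, axis=0)])
    traj = make_traj(pos, M=M, N=1)
    _, _, kappa = displacement_distribution(traj, delta=1.0, axis=0)
    assert kappa == pytest.approx(3.0, abs=0.5)


def test_displacement_isotropy():
    rng = np.random.default_rng(23)
    M, F = 300, 41
    jumps = rng.normal(size=(F - 1, M, 3))
    pos = np.concatenate([np.zeros((1, M, 3)), np.cumsum(jumps, axis=0)])
    traj = make_traj(pos, M=M, N=1)
    kappas = [
        displacement_distribution(traj, delta=1.0, axis=ax)[2] for ax in range(3)
    ]
    assert np.std(kappas) < 0.2


# -- neighbor counts --------------------------------------------------------


def test_hot_neighbor_single_ring_zero(small_melt):
    import ringmelt as rm

    state = rm.assign_activity(small_melt, N_h=4, M_a=1, seed=3)
    assert hot_neighbor_count(state) == 0.0


def test_hot_neighbor_pair_within_cutoff():
    N = 4
    pos = np.zeros((2 * N, 3))
    pos[N:, 0] = 3.0  # second ring 3 sigma away
    hot = np.ones(2 * N, dtype=bool)
    state = make_state(pos, M=2, N=N, hot=hot, box=100.0)
    assert hot_neighbor_count(state, cutoff=3.25) == pytest.approx(1.0)
    assert hot_neighbor_count(state, cutoff=2.9) == 0.0


def test_uniform_neighbor_expectation_production_scale():
    """(4/3) pi (3.25)^3 M/V at M=1600, N=400, rho=0.85 is about 0.3."""
    val = uniform_neighbor_expectation(1600, 400, 0.85, cutoff=3.25)
    assert val == pytest.approx(0.3, abs=0.01)


def test_hot_neighbor_monte_carlo_matches_expectation():
    """Uniformly random hot-segment positions reproduce the closed form."""
    M, N, rho = 1600, 4, 0.85
    L = (M * N / rho) ** (1 / 3)
    rng = np.random.default_rng(29)
    coms = rng.uniform(0, L, size=(M, 3))
    pos = np.repeat(coms, N, axis=0)  # collapse each segment to its COM
    hot = np.ones(M * N, dtype=bool)
    state = make_state(pos, M=M, N=N, hot=hot, box=L)
    mc = hot_neighbor_count(state, cutoff=3.25)
    assert mc == pytest.approx(
        uniform_neighbor_expectation(M, N, rho, 3.25), rel=0.2
    )


# -- structure factor -------------------------------------------------------


def test_structure_factor_poisson_unity():
    rng = np.random.default_rng(31)
    L = 20.0
    pts = rng.uniform(0, L, size=(800, 3))
    series = structure_factor(pts, np.full(3, L), q_magnitudes=[2.0, 3.0, 5.0])
    assert np.all(series.y > 0)
    assert np.allclose(series.y, 1.0, atol=0.35)


def test_structure_factor_lattice_bragg():
    """Simple cubic lattice with spacing a peaks at 2 pi / a."""
    a = 2.0
    m = 8
    g = np.stack(np.meshgrid(*[np.arange(m)] * 3, indexing="ij"), -1).reshape(-1, 3)
    pts = g * a
    L = m * a
    qs = [1.5, 2.5, 2 * np.pi / a, 4.0]
    series = structure_factor(pts, np.full(3, L), q_magnitudes=qs, shell_width=0.01)
    assert series.meta["q_star"] == pytest.approx(2 * np.pi / a)
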