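"""Shared fixtures: small deterministic melts reused across test modules."""

import numpy as np
import pytest

import ringmelt as rm
from ringmelt.params import ModelParameters


@pytest.fixture(scope="session")
def tiny_melt():
    """Smallest useful melt (2 rings of 16) for fast structural checks."""
    params = ModelParameters(N=16, M=2)
    return rm.build_melt(params, seed=101)


@pytest.fixture(scope="session")
def small_melt():
    """4 rings of 32 monomers at production density."""
    params = ModelParameters(N=32, M=4)
    return rm.build_melt(params, seed=42)


@pytest.fixture(scope="session")
def active_melt(small_melt):
    """The small melt with hot arcs assigned (N_h = 4 per ring)."""
    return rm.assign_activity(small_melt, N_h=4, M_a=4, seed=7)


@pytest.fixture(scope="session")
def threading_melt():
    """Many short rings (48 x 12) whose extent provably stays below half
    the box (a fully stretched 12-ring spans 3.7 sigma < L/2 = 4.4),
    suitable for minimum-image threading analysis."""
    params = ModelParameters(N=12, M=48, N_h=2)
    state = rm.build_melt(params, seed=5)
    state = rm.assign_activity(state, seed=6)
    # short two-temperature run to generate generic disordered contours
    return rm.step(state, 4000, seed=9, active=True)


@pytest.fixture(scope="session")
def fourier_loops():
    """Overlapping smooth random closed curves (no periodic box).

    Low-order Fourier loops clustered in space; generic pairs both thread
    and occasionally link, which exercises the full sign bookkeeping of the
    piercing detector against the exact Gauss linking number.
    """
    rng = np.random.default_rng(77)
    loops = []
    t = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    for k in range(6):
        center = rng.uniform(-1.5, 1.5, size=3)
        c = np.zeros((48, 3))
        for order in (1, 2, 3):
            amp = 3.0 / order**1.5
            a = rng.normal(scale=amp, size=3)
            b = rng.normal(scale=amp, size=3)
            c += np.outer(np.cos(order * t), a) + np.outer(np.sin(order * t), b)
        loops.append(center + c)
    return loops


@pytest.fixture(scope="session")
def brownian_traj():
    """Synthetic trajectory of independent Brownian ring centers.

    Built directly from Gaussian increments (no engine): M 'rings' of one
    effective particle each, diffusivity D, frame spacing dt_frame.  Used
    as the analytic reference for g3, EB and displacement statistics.
    """
    from ringmelt.state import Trajectory

    rng = np.random.default_rng(2024)
    M, N = 60, 1
    F = 400
    D = 0.5
    dt_frame = 1.0
    steps = rng.normal(scale=np.sqrt(2 * D * dt_frame), size=(F - 1, M, 3))
    pos = np.concatenate([np.zeros((1, M, 3)), np.cumsum(steps, axis=0)])
    params = ModelParameters(N=N, M=M)
    return (
        Trajectory(
            times=np.arange(F) * dt_frame,
            positions=pos.reshape(F, M * N, 3),
            box=np.full(3, 1e6),
            hot=np.zeros(M * N, dtype=bool),
            closed=np.ones(M, dtype=bool),
            params=params,
        ),
        D,
    )
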