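"""In-memory containers: a melt snapshot and a trajectory.

Positions are stored *unwrapped* (continuous across the periodic box).
Wrapped coordinates plus integer image flags are derived on demand, so ring
contours are always continuous and no minimum-image bookkeeping is needed
for bonded terms or analysis.  Rings occupy contiguous monomer index blocks:
ring ``r`` owns monomers ``[r*N, (r+1)*N)``, in contour order.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .params import ModelParameters

HOT, COLD = 1, 0


@dataclasses.dataclass
class MeltState:
    """One snapshot of the melt.

    Attributes
    ----------
    positions : (M*N, 3) float array
        Unwrapped monomer positions (sigma).
    velocities : (M*N, 3) float array
        Monomer velocities (sigma/tau).
    box : (3,) float array
        Periodic box edge lengths (sigma).
    hot : (M*N,) bool array
        Per-monomer thermostat label (True = hot channel at T_h).
    closed : (M,) bool array
        Whether each chain is still a ring (False after bond cutting).
    params : ModelParameters
    time : float
        Simulation time (tau); by convention 0 at activity onset.
    """

    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    hot: np.ndarray
    closed: np.ndarray
    params: ModelParameters
    time: float = 0.0

    def __post_init__(self):
        n = self.params.M * self.params.N
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        self.hot = np.asarray(self.hot, dtype=bool)
        self.closed = np.asarray(self.closed, dtype=bool)
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must have shape {(n, 3)}")
        if self.velocities.shape != (n, 3):
            raise ValueError(f"velocities must have shape {(n, 3)}")
        if self.hot.shape != (n,):
            raise ValueError("one temperature label per monomer required")
        if self.closed.shape != (self.params.M,):
            raise ValueError("one closed flag per ring required")

    # -- ring access --------------------------------------------------------

    @property
    def M(self) -> int:
        return self.params.M

    @property
    def N(self) -> int:
        return self.params.N

    def ring_slice(self, r: int) -> slice:
        return slice(r * self.N, (r + 1) * self.N)

    def ring_positions(self, r: int) -> np.ndarray:
        """Unwrapped contour of ring r, shape (N, 3), in contour order."""
        return self.positions[self.ring_slice(r)]

    def ring_is_active(self) -> np.ndarray:
        """(M,) bool: rings carrying at least one hot monomer."""
        return self.hot.reshape(self.M, self.N).any(axis=1)

    # -- topology -----------------------------------------------------------

    def bonds(self) -> np.ndarray:
        """(n_bonds, 2) int array of bonded monomer pairs.

        Cyclic per ring while closed; the closing bond is dropped for cut
        chains (cutting is always performed at the block boundary by
        relabelling, see :func:`ringmelt.builder.cut_bonds`).
        """
        out = []
        N = self.N
        for r in range(self.M):
            base = r * N
            i = np.arange(N if self.closed[r] else N - 1)
            out.append(np.column_stack([base + i, base + (i + 1) % N]))
        return np.concatenate(out).astype(np.int64)

    def angles(self) -> np.ndarray:
        """(n_angles, 3) int array of consecutive monomer triplets.

        All cyclic triplets for rings; interior triplets only for cut chains.
        """
        out = []
        N = self.N
        for r in range(self.M):
            base = r * N
            if self.closed[r]:
                i = np.arange(N)
                out.append(
                    np.column_stack(
                        [base + (i - 1) % N, base + i, base + (i + 1) % N]
                    )
                )
            else:
                i = np.arange(1, N - 1)
                out.append(np.column_stack([base + i - 1, base + i, base + i + 1]))
        return np.concatenate(out).astype(np.int64)

    def bond_lengths(self) -> np.ndarray:
        b = self.bonds()
        d = self.positions[b[:, 1]] - self.positions[b[:, 0]]
        return np.linalg.norm(d, axis=1)

    # -- wrapped view -------------------------------------------------------

    def image_flags(self) -> np.ndarray:
        return np.floor(self.positions / self.box).astype(np.int64)

    def wrapped_positions(self) -> np.ndarray:
        return self.positions - self.image_flags() * self.box

    def kinetic_temperature(self, subset=None) -> float:
        """Instantaneous kinetic temperature m<v^2>/3 over a monomer subset."""
        v = self.velocities if subset is None else self.velocities[subset]
        if v.size == 0:
            raise ValueError("empty subset has no kinetic temperature")
        return float(self.params.mass * np.mean(np.sum(v**2, axis=1)) / 3.0)

    def copy(self) -> "MeltState":
        return MeltState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            box=self.box.copy(),
            hot=self.hot.copy(),
            closed=self.closed.copy(),
            params=dataclasses.replace(self.params),
            time=self.time,
        )


@dataclasses.dataclass
class Trajectory:
    """Time-ordered melt snapshots from one run.

    ``positions`` (and optionally ``velocities``) are stacked per frame,
    unwrapped.  ``times`` are strictly increasing and, within one protocol
    phase, uniformly spaced.  ``meta`` records parameters, seeds and the
    thermostat assignment for provenance.
    """

    times: np.ndarray
    positions: np.ndarray
    box: np.ndarray
    hot: np.ndarray
    closed: np.ndarray
    params: ModelParameters
    velocities: np.ndarray | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.positions):
            raise ValueError("one time per frame required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def M(self) -> int:
        return self.params.M

    @property
    def N(self) -> int:
        return self.params.N

    def frame(self, k: int) -> MeltState:
        vel = (
            self.velocities[k]
            if self.velocities is not None
            else np.zeros_like(self.positions[k])
        )
        return MeltState(
            positions=self.positions[k].copy(),
            velocities=vel.copy(),
            box=self.box.copy(),
            hot=self.hot.copy(),
            closed=self.closed.copy(),
            params=dataclasses.replace(self.params),
            time=float(self.times[k]),
        )

    def frame_index(self, t: float, atol: float = 1e-9) -> int:
        k = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[k] - t) > atol + 1e-12 * max(1.0, abs(t)):
            raise ValueError(f"time {t} is not a frame time (nearest {self.times[k]})")
        return k

    def ring_coms(self) -> np.ndarray:
        """(n_frames, M, 3) centers of mass of each chain (unwrapped)."""
        F = self.n_frames
        return self.positions.reshape(F, self.M, self.N, 3).mean(axis=2)

    def system_com(self) -> np.ndarray:
        """(n_frames, 3) center of mass of the whole melt."""
        return self.positions.mean(axis=1)

    def ring_coms_relative(self) -> np.ndarray:
        """Ring centers of mass in the system-center-of-mass frame.

        Langevin dynamics does not conserve momentum, so every displacement
        observable subtracts the instantaneous system center of mass.
        """
        return self.ring_coms() - self.system_com()[:, None, :]
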