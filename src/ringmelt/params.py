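"""Model parameters for the active ring-polymer melt.

All quantities are in reduced Lennard-Jones units: the monomer diameter
``sigma`` is the length unit, the repulsion strength ``epsilon`` the energy
unit, the monomer mass ``m`` the mass unit, and the Boltzmann constant is 1.
The intrinsic time is ``tau = sigma * sqrt(m / epsilon)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io

import yaml

#: reduced time unit sigma*(m/epsilon)**0.5; equal to 1 in reduced units
TAU = 1.0

#: WCA cutoff 2**(1/6) sigma, where the shifted Lennard-Jones minimum sits
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


@dataclasses.dataclass
class ModelParameters:
    """Force-field, thermostat and composition constants of the melt model.

    Parameters
    ----------
    N : int
        Monomers per ring.
    M : int
        Number of rings.
    N_h : int, optional
        Length of the consecutive hot (active) segment per active ring.
        Defaults to ``N // 8``.
    M_a : int, optional
        Number of partly active rings; the remaining ``M - M_a`` rings are
        fully passive.  Defaults to ``M`` (every ring active).
    T_h, T_c : float
        Temperatures of the hot and cold Langevin thermostats (epsilon/k_B).
    rho : float
        Monomer number density (sigma^-3).
    K, r_max : float
        FENE spring constant (epsilon/sigma^2) and maximum extension (sigma).
    k_theta : float
        Bending constant of the angular potential (epsilon).
    dt : float
        Integration time step (tau).
    gamma : float
        Thermostat friction for both channels (1/tau).
    """

    N: int
    M: int
    N_h: int | None = None
    M_a: int | None = None
    epsilon: float = 1.0
    sigma: float = 1.0
    mass: float = 1.0
    r_max: float = 1.5
    K: float = 30.0
    k_theta: float = 1.5
    rho: float = 0.85
    dt: float = 0.005
    gamma: float = 2.0 / 3.0
    T_h: float = 3.0
    T_c: float = 1.0

    def __post_init__(self):
        if self.N_h is None:
            self.N_h = self.N // 8
        if self.M_a is None:
            self.M_a = self.M
        self.validate()

    def validate(self):
        if self.N < 1:
            # N >= 3 is required to *build* a ring (checked by the builder);
            # N = 1 point chains are allowed for synthetic trajectories
            raise ValueError("N must be positive")
        if self.M < 1:
            raise ValueError("M must be positive")
        if not (0 <= self.N_h <= self.N):
            raise ValueError(f"N_h={self.N_h} must lie in [0, N={self.N}]")
        if not (0 <= self.M_a <= self.M):
            raise ValueError(f"M_a={self.M_a} must lie in [0, M={self.M}]")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (self.T_h >= self.T_c > 0):
            raise ValueError("temperatures must satisfy T_h >= T_c > 0")
        if self.r_max <= WCA_CUTOFF * self.sigma:
            # a bond must be able to reach the repulsion cutoff
            raise ValueError("r_max must exceed the WCA cutoff 2^(1/6) sigma")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def n_monomers(self) -> int:
        return self.M * self.N

    @property
    def box_volume(self) -> float:
        """Fixed simulation volume M*N/rho (sigma^3)."""
        return self.M * self.N / self.rho

    @property
    def box_edge(self) -> float:
        """Edge length of the cubic production box (sigma)."""
        return self.box_volume ** (1.0 / 3.0)

    # -- plain-text config round trip --------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ModelParameters":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(io.StringIO(str(source)))
        return cls.from_dict(data)

    def content_hash(self) -> str:
        """Stable short hash of the parameter set, embedded in outputs."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
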