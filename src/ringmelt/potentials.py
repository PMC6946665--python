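"""The three interaction potentials of the bead-spring ring model.

* :func:`wca_energy` -- purely repulsive, cut-shifted Lennard-Jones (WCA)
  acting between all monomer pairs,
  ``U(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6] + eps`` for
  ``r < 2^(1/6) sigma`` and zero beyond.
* :func:`fene_energy` -- finitely extensible nonlinear elastic bond,
  ``U(r) = -(1/2) K r_max^2 log[1 - (r/r_max)^2]``, diverging at ``r_max``.
  Together with the stiff WCA core this makes the chains essentially
  uncrossable.
* :func:`angle_energy` -- bending term ``U(theta) = k_theta (1 - cos(theta -
  pi))``, minimal for a straight chain.

Energies take scalars or numpy arrays; the companion ``*_force`` functions
return the (scalar) radial force ``-dU/dr`` or the angular derivative.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError, OverstretchedBondError
from .params import WCA_CUTOFF

__all__ = [
    "wca_energy",
    "wca_force",
    "fene_energy",
    "fene_force",
    "angle_energy",
    "angle_force",
]


def _as_positive(r, name="r"):
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise GeometryError(f"{name} must be positive, got {r}")
    return r


def wca_energy(r, epsilon=1.0, sigma=1.0):
    """Purely repulsive shifted Lennard-Jones energy; 0 beyond 2^(1/6) sigma."""
    r = _as_positive(r)
    inside = r < WCA_CUTOFF * sigma
    sr6 = np.where(inside, (sigma / np.where(inside, r, sigma)) ** 6, 0.0)
    u = np.where(inside, 4.0 * epsilon * (sr6 * sr6 - sr6) + epsilon, 0.0)
    return u if u.ndim else float(u)


def wca_force(r, epsilon=1.0, sigma=1.0):
    """Radial WCA force -dU/dr (positive = repulsive); 0 beyond the cutoff."""
    r = _as_positive(r)
    inside = r < WCA_CUTOFF * sigma
    rs = np.where(inside, r, sigma)
    sr6 = (sigma / rs) ** 6
    f = np.where(inside, 24.0 * epsilon * (2.0 * sr6 * sr6 - sr6) / rs, 0.0)
    return f if f.ndim else float(f)


def fene_energy(r, K=30.0, r_max=1.5):
    """FENE bond energy; raises if a bond reaches r_max (chain-crossing risk)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise GeometryError("bond length must be non-negative")
    if np.any(r >= r_max):
        raise OverstretchedBondError(
            f"bond length {np.max(r):.6g} >= r_max={r_max}; FENE diverges"
        )
    u = -0.5 * K * r_max**2 * np.log1p(-((r / r_max) ** 2))
    return u if u.ndim else float(u)


def fene_force(r, K=30.0, r_max=1.5):
    """Radial FENE force -dU/dr = -K r / (1 - (r/r_max)^2) (always attractive)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise GeometryError("bond length must be non-negative")
    if np.any(r >= r_max):
        raise OverstretchedBondError(
            f"bond length {np.max(r):.6g} >= r_max={r_max}; FENE diverges"
        )
    f = -K * r / (1.0 - (r / r_max) ** 2)
    return f if f.ndim else float(f)


def angle_energy(theta, k_theta=1.5):
    """Bending energy k_theta (1 - cos(theta - pi)); 0 for a straight chain."""
    theta = np.asarray(theta, dtype=float)
    u = k_theta * (1.0 - np.cos(theta - np.pi))
    return u if u.ndim else float(u)


def angle_force(theta, k_theta=1.5):
    """Angular derivative -dU/dtheta = -k_theta sin(theta - pi)."""
    theta = np.asarray(theta, dtype=float)
    f = -k_theta * np.sin(theta - np.pi)
    return f if f.ndim else float(f)
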