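"""Analytic finite-cylinder series solution for constant Robin boundaries.

Verification oracle for the numerical solver: the classical
separation-of-variables product solution for a finite cylinder of radius
R and half-length L_h, initially uniform at T0, suddenly exposed on the
lateral surface and end faces to a medium at Tp with a constant
heat-transfer coefficient h. The dimensionless excess temperature
factorizes into an infinite-cylinder part and a symmetric-slab part:

    T(r, z, t) = Tp + (T0 - Tp) * Theta_cyl(r, t) * Theta_slab(z, t)

with eigenvalues of the transcendental conditions

    lam * J1(lam) = Bi_R * J0(lam)      (cylinder, Bi_R = h R / k)
    mu * tan(mu)  = Bi_L                (slab,     Bi_L = h L_h / k)

found by bracketed root-finding (the n-th cylinder root lies between
consecutive zeros of J0; the n-th slab root in (n*pi, n*pi + pi/2)).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import j0, j1, jn_zeros

from .errors import EigenvalueError, ParameterError
from .properties import ThermoProps

__all__ = ["analytic_finite_cylinder", "cylinder_eigenvalues", "slab_eigenvalues"]


def cylinder_eigenvalues(bi: float, n: int) -> np.ndarray:
    """First ``n`` positive roots of ``lam*J1(lam) = Bi*J0(lam)``."""
    if bi <= 0:
        raise ParameterError(f"Biot number must be positive, got {bi}")
    f = lambda lam: lam * j1(lam) - bi * j0(lam)
    zeros = jn_zeros(0, n + 1)
    brackets = [(1e-12, zeros[0])] + [(zeros[i], zeros[i + 1]) for i in range(n - 1)]
    roots = []
    for lo, hi in brackets[:n]:
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            raise EigenvalueError(f"no sign change on cylinder bracket ({lo}, {hi})")
        roots.append(brentq(f, lo, hi, xtol=1e-14, rtol=1e-15))
    return np.asarray(roots)


def slab_eigenvalues(bi: float, n: int) -> np.ndarray:
    """First ``n`` positive roots of ``mu*tan(mu) = Bi``."""
    if bi <= 0:
        raise ParameterError(f"Biot number must be positive, got {bi}")
    f = lambda mu: mu * np.sin(mu) - bi * np.cos(mu)
    roots = []
    for m in range(n):
        lo, hi = m * np.pi + 1e-12, m * np.pi + np.pi / 2.0
        if f(lo) * f(hi) > 0:
            raise EigenvalueError(f"no sign change on slab bracket ({lo}, {hi})")
        roots.append(brentq(f, lo, hi, xtol=1e-14, rtol=1e-15))
    return np.asarray(roots)


def _theta_cylinder(lam: np.ndarray, rho: float, fo: np.ndarray) -> np.ndarray:
    c = (2.0 / lam) * j1(lam) / (j0(lam) ** 2 + j1(lam) ** 2)
    terms = c * j0(lam * rho) * np.exp(-np.outer(fo, lam**2))
    return terms.sum(axis=-1)


def _theta_slab(mu: np.ndarray, xi: float, fo: np.ndarray) -> np.ndarray:
    c = 2.0 * np.sin(mu) / (mu + np.sin(mu) * np.cos(mu))
    terms = c * np.cos(mu * xi) * np.exp(-np.outer(fo, mu**2))
    return terms.sum(axis=-1)


def analytic_finite_cylinder(
    geometry,
    props: ThermoProps,
    h: float,
    Tp: float,
    T0: float,
    t,
    r: float = 0.0,
    z: float = 0.0,
    n_terms: int = 80,
) -> np.ndarray | float:
    """Series temperature (K) at point ``(r, z)`` and time(s) ``t``.

    ``z`` is measured from the mid-plane; the end face sits at
    ``z = geometry.half_length_m``. ``t`` may be a scalar or array.
    """
    if n_terms < 10:
        raise ParameterError(f"need at least 10 series terms, got {n_terms}")
    if h <= 0:
        raise ParameterError(f"h must be positive, got {h}")
    R, Lh = geometry.radius_m, geometry.half_length_m
    if not (0.0 <= r <= R and 0.0 <= z <= Lh):
        raise ParameterError(f"point (r={r}, z={z}) outside the cylinder")
    alpha = props.alpha
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    lam = cylinder_eigenvalues(h * R / props.k, n_terms)
    mu = slab_eigenvalues(h * Lh / props.k, n_terms)
    theta = _theta_cylinder(lam, r / R, alpha * t_arr / R**2) * _theta_slab(
        mu, z / Lh, alpha * t_arr / Lh**2
    )
    out = Tp + (T0 - Tp) * theta
    return out if np.ndim(t) else float(out[0])
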