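"""Spherically symmetric reaction–diffusion in an isolated spheroid.

A static spheroid of radius R with a fixed surface concentration consumes a
substrate by Michaelis–Menten kinetics:

    (1/r²) d/dr (K r² dc/dr) = Vmax·c/(c + Km),   c'(0) = 0,  c(R) = c_s.

Two closed forms bracket the kinetics and serve as exact oracles: the
zeroth-order limit (Km → 0, constant consumption where tissue is supplied,
with an anoxic core below the critical surface concentration) and the
first-order limit (Km ≫ c, the classic sinh(φ r/R)/r profile with Thiele
modulus φ = R·sqrt(Vmax/(Km·K))). The numerical solver covers the full
Michaelis–Menten range between them and doubles as a fast screening tool
for hypoxia radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq

from . import constants as C

__all__ = [
    "SphereProblem", "RadialProfile", "zeroth_order_profile",
    "first_order_profile", "solve_mm_sphere", "hypoxia_radius",
]


@dataclass(frozen=True)
class SphereProblem:
    """Radius (m), tissue diffusivity (m²/s), MM constants and surface value."""

    radius: float                  # m
    K_tissue: float = C.K_O2_TISSUE
    Vmax: float = C.VMAX_O2        # mM/s
    Km: float = C.KM_O2            # mM (0 allowed: zeroth-order limit)
    c_surface: float = 0.2         # mM, native tissue units

    def __post_init__(self):
        if self.radius <= 0 or self.K_tissue <= 0 or self.c_surface < 0:
            raise ValueError("radius, K_tissue must be > 0 and c_surface >= 0")
        if self.Vmax < 0 or self.Km < 0:
            raise ValueError("Vmax and Km must be non-negative")


@dataclass
class RadialProfile:
    r_m: np.ndarray
    c_mM: np.ndarray
    problem: SphereProblem
    anoxic_radius_m: float = 0.0

    def center_value(self) -> float:
        return float(self.c_mM[0])


def zeroth_order_profile(prob: SphereProblem, n: int = 201) -> RadialProfile:
    """Closed form for constant consumption rate (the Km → 0 limit).

    Without an anoxic core: ``c(r) = c_s − Vmax (R² − r²) / 6K``. When the
    surface value cannot supply the centre (``c_s < Vmax R²/6K``) an anoxic
    core of radius ``r_a`` forms, with c = 0 and zero flux at its edge.
    """
    R, K, V, cs = prob.radius, prob.K_tissue, prob.Vmax, prob.c_surface
    r = np.linspace(0.0, R, n)
    if V == 0:
        return RadialProfile(r, np.full(n, cs), prob)
    drop = V * R * R / (6.0 * K)
    if cs >= drop:
        c = cs - V * (R * R - r * r) / (6.0 * K)
        return RadialProfile(r, c, prob)

    def surface_value(ra):
        # c(R) for an active shell attached to an anoxic core of radius ra
        return V / (3.0 * K) * ((R * R - ra * ra) / 2.0 + ra ** 3 / R - ra * ra)

    ra = brentq(lambda a: surface_value(a) - cs, 0.0, R)
    c = np.zeros(n)
    act = r >= ra
    with np.errstate(divide="ignore", invalid="ignore"):
        c[act] = V / (3.0 * K) * (
            (r[act] ** 2 - ra * ra) / 2.0 + ra ** 3 / np.maximum(r[act], 1e-300)
            - ra * ra
        )
    c = np.clip(c, 0.0, None)
    return RadialProfile(r, c, prob, anoxic_radius_m=ra)


def first_order_profile(prob: SphereProblem, n: int = 201) -> RadialProfile:
    """Closed form for first-order kinetics R = (Vmax/Km)·c (the Km ≫ c limit).

    ``c(r) = c_s (R/r) sinh(φ r/R)/sinh(φ)`` with Thiele modulus
    ``φ = R sqrt(Vmax/(Km K))``.
    """
    if prob.Km <= 0:
        raise ValueError("first-order limit requires Km > 0")
    R, K, cs = prob.radius, prob.K_tissue, prob.c_surface
    phi = R * np.sqrt(prob.Vmax / (prob.Km * K))
    r = np.linspace(0.0, R, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = cs * (R / r) * np.sinh(phi * r / R) / np.sinh(phi)
    c[0] = cs * phi / np.sinh(phi)   # r -> 0 limit
    return RadialProfile(r, c, prob)


def solve_mm_sphere(prob: SphereProblem, n_nodes: int = 256,
                    tol: float = 1e-10, max_newton: int = 60) -> RadialProfile:
    """Finite-difference solution of the full Michaelis–Menten sphere.

    Conservative second-order differencing of (1/r²)(K r² c')' on a uniform
    radial grid with a symmetric centre stencil, solved by damped Newton
    iteration (concentrations clipped at zero inside the rate). Converges to
    the zeroth- and first-order closed forms in their respective limits.
    """
    if n_nodes < 16:
        raise ValueError("need at least 16 radial nodes")
    if prob.Km == 0:
        return zeroth_order_profile(prob, n_nodes)
    R, K, V, Km, cs = (prob.radius, prob.K_tissue, prob.Vmax, prob.Km,
                       prob.c_surface)
    n = n_nodes
    r = np.linspace(0.0, R, n)
    h = r[1] - r[0]
    rp = r[:-1] + h / 2.0                        # r_{i+1/2}

    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i); cols.append(j); vals.append(v)

    # interior conservative stencil, scaled by 1/(h^2 r_i^2)
    for i in range(1, n - 1):
        wp = K * rp[i] ** 2 / (h * h * r[i] ** 2)
        wm = K * rp[i - 1] ** 2 / (h * h * r[i] ** 2)
        add(i, i - 1, wm)
        add(i, i, -(wp + wm))
        add(i, i + 1, wp)
    # centre: symmetry gives laplacian -> 3 c'' -> 6 (c1 - c0)/h^2
    add(0, 0, -6.0 * K / (h * h))
    add(0, 1, 6.0 * K / (h * h))
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    keep = np.ones(n)
    keep[-1] = 0.0
    Dk = sp.diags(keep)
    e_last = sp.csr_matrix(([1.0], ([n - 1], [n - 1])), shape=(n, n))

    def newton(c, v):
        def residual(cv):
            cpos = np.clip(cv, 0.0, None)
            F = L @ cv - v * cpos / (cpos + Km)
            F[-1] = cv[-1] - cs
            return F

        F = residual(c)
        norm0 = np.linalg.norm(F)
        trace = [norm0]
        c_tol = tol * max(cs, 1e-30)      # solution-increment tolerance, mM
        for _ in range(max_newton):
            if np.linalg.norm(F) <= 1e-12 * max(norm0, 1.0):
                return c, trace
            # derivative of the clipped rate: flat where tissue is anoxic
            dR = np.where(c > 0, v * Km / (np.clip(c, 0, None) + Km) ** 2, 0.0)
            J = (Dk @ (L - sp.diags(dR)) + e_last).tocsc()
            delta = spla.splu(J).solve(-F)
            if np.abs(delta).max() <= c_tol:
                return c, trace
            step = 1.0
            for _ in range(30):
                c_try = c + step * delta
                F_try = residual(c_try)
                if np.linalg.norm(F_try) < np.linalg.norm(F):
                    c, F = c_try, F_try
                    break
                step *= 0.5
            else:
                if np.linalg.norm(F) < 1e-7 * max(norm0, 1.0):
                    return c, trace   # roundoff floor of the stencil
                return None, trace
            trace.append(float(np.linalg.norm(F)))
        return None, trace

    # plain Newton from a flat start; on failure (strongly starved cores with
    # tiny Km are stiff) use continuation, ramping Vmax up in stages
    c0 = np.full(n, cs)
    c, trace = newton(c0, V)
    if c is None:
        c = c0
        for frac in np.linspace(0.1, 1.0, 12):
            c, trace = newton(c, frac * V)
            if c is None:
                raise RuntimeError(
                    "Newton continuation failed; residual trace: "
                    + ", ".join(f"{t:.3e}" for t in trace))
    return RadialProfile(r, np.clip(c, 0.0, None), prob)


def hypoxia_radius(profile: RadialProfile, threshold_c: float) -> float | None:
    """Radius where the profile crosses a concentration threshold.

    Returns None if the whole spheroid sits above the threshold; R if the
    threshold equals the surface value. Requires a (numerically) monotone
    profile.
    """
    r, c = profile.r_m, profile.c_mM
    if np.any(np.diff(c) < -1e-9 * max(profile.problem.c_surface, 1e-30)):
        raise ValueError("profile is not monotone non-decreasing")
    if threshold_c <= c[0]:
        return None if threshold_c < c[0] else float(r[0])
    if threshold_c >= c[-1]:
        return float(r[-1])
    return float(np.interp(threshold_c, c, r))
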