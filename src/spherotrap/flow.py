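"""Steady laminar flow of culture medium through the trap channel.

The medium is an incompressible Newtonian fluid (water at 37 °C); at the
study's flow rates (5–20 µL/min in a 1 mm² channel) the Reynolds number is
~0.1, so the flow is dominated by viscosity. The solver discretizes the
stationary Navier–Stokes equations with equal-order P1/P1 elements and
Brezzi–Pitkäranta pressure stabilization; the convective term is handled by
Picard (Oseen) iteration, and a pure-Stokes mode — exact at the linear level
and linear in the flow rate — is available for screening and sweeps.

Boundary conditions: fully developed plane-Poiseuille profile at the inlet
(the side walls are symmetry planes of a periodic trap array, so the
developed profile is parabolic in the vertical coordinate only), natural
zero-traction outlet (which also pins the pressure level), no slip on the
floor, the PDMS lid underside, the barrier and the spheroid surface, and
zero normal velocity on the symmetry sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constants as C
from .fem import Subspace
from .geometry import DOMAIN_MEDIUM
from .meshing import Mesh, facet_areas_normals

__all__ = [
    "FluidProperties", "FlowSolution", "inlet_profile", "solve_flow",
    "wall_shear", "FlowError",
]

_STAB_ALPHA = 0.05  # pressure-stabilization constant (h^2-scaled)


class FlowError(RuntimeError):
    """Raised when the nonlinear flow iteration fails to converge."""


@dataclass(frozen=True)
class FluidProperties:
    density: float = C.RHO_MEDIUM     # kg/m^3
    viscosity: float = C.MU_MEDIUM    # Pa s

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


def inlet_profile(Q_uL_min: float, channel_height_um: float,
                  channel_width_um: float):
    """Fully developed inlet velocity profile for a given flow rate.

    Returns ``(profile, U)`` where ``profile(x_m)`` gives the streamwise
    velocity in m/s at height ``x`` above the floor and ``U = Q/(W·H)`` is
    the mean velocity. Between the no-slip floor and lid, with symmetric
    side planes, the developed profile is plane Poiseuille:
    ``u_z(x) = 6 U (x/H)(1 - x/H)``.
    """
    if Q_uL_min <= 0:
        raise ValueError("flow rate must be positive")
    H = channel_height_um * 1e-6
    W = channel_width_um * 1e-6
    U = Q_uL_min * C.UL_PER_MIN_TO_M3_PER_S / (W * H)

    def profile(x_m):
        xi = np.clip(np.asarray(x_m, dtype=float) / H, 0.0, 1.0)
        return 6.0 * U * xi * (1.0 - xi)

    return profile, U


@dataclass
class FlowSolution:
    """Velocity/pressure fields on the medium domain."""

    mesh: Mesh
    space: Subspace
    velocity: np.ndarray          # (n, 3) m/s, nodal
    pressure: np.ndarray          # (n,) Pa, nodal
    Q_uL_min: float
    props: FluidProperties
    residual_norms: dict[str, float]
    mode: str
    iterations: int = 0

    def cell_velocity(self) -> np.ndarray:
        """Cellwise-averaged velocity on the medium cells, (nc, 3)."""
        return self.velocity[self.space.cells].mean(axis=1)

    def boundary_flux(self, tag: str) -> float:
        """Volumetric flux (m^3/s) through a tagged facet set, outward +z."""
        f = self.mesh.facets[tag]
        area, normal = facet_areas_normals(self.mesh, tag)
        loc = self.space.loc[f]
        uz = np.where(loc >= 0, self.velocity[:, 2][np.clip(loc, 0, None)], 0.0)
        mean_uz = uz.mean(axis=1)
        return float((mean_uz * area * np.abs(normal[:, 2])).sum())

    def scaled(self, Q_new: float) -> "FlowSolution":
        """Linearly rescaled solution (exact for the Stokes mode)."""
        s = Q_new / self.Q_uL_min
        return FlowSolution(
            mesh=self.mesh, space=self.space, velocity=self.velocity * s,
            pressure=self.pressure * s, Q_uL_min=Q_new, props=self.props,
            residual_norms=dict(self.residual_norms), mode=self.mode + "+scaled",
            iterations=self.iterations,
        )


def _gradient_blocks(space: Subspace):
    """G_k[i,j] = ∫ φ_i ∂φ_j/∂x_k for k = x, y, z."""
    out = []
    for k in range(3):
        a = space.grads[:, :, k]                       # ∂φ_j/∂x_k
        ke = np.repeat((a * (space.vols / 4.0)[:, None])[:, None, :], 4, axis=1)
        out.append(space._accumulate(ke))
    return out


def solve_flow(
    mesh: Mesh,
    Q_uL_min: float,
    props: FluidProperties | None = None,
    mode: str = "picard",
    tol: float = 1e-6,
    max_iter: int = 50,
    relax: float = 0.7,
) -> FlowSolution:
    """Solve steady flow on the medium domain of a tagged mesh.

    ``mode='picard'`` iterates the full Navier–Stokes convective term to the
    requested relative tolerance; ``mode='stokes'`` drops it, which at the
    device Reynolds number (~0.1) changes the shear field by well under 2%
    and makes the solution exactly proportional to Q.
    """
    props = props or FluidProperties()
    if Q_uL_min <= 0:
        raise ValueError("flow rate must be positive")
    if mode not in ("picard", "stokes"):
        raise ValueError(f"unknown mode {mode!r}")

    cfg = mesh.config
    med = mesh.cells_of_domain(DOMAIN_MEDIUM)
    if len(med) == 0:
        raise FlowError("mesh has no medium cells")
    space = Subspace.on_cells(mesh, med)
    n = space.n
    mu = props.viscosity

    K = space.stiffness(mu)
    G = _gradient_blocks(space)
    h2 = np.cbrt(6.0 * space.vols) ** 2
    Cstab = space.stiffness(_STAB_ALPHA * h2 / mu)

    # Dirichlet bookkeeping ------------------------------------------------
    prof, _U = inlet_profile(Q_uL_min, cfg.channel_height, cfg.channel_width)
    verts = mesh.vertices[space.verts]

    def dofs_of(tag):
        return space.local_dofs(mesh.vertex_set(tag))

    noslip = np.unique(np.concatenate([
        dofs_of("floor"), dofs_of("pdms_interface"), dofs_of("spheroid_interface"),
    ]))
    inlet = np.setdiff1d(dofs_of("inlet"), noslip)
    sym = np.setdiff1d(dofs_of("symmetry_side"), np.concatenate([noslip, inlet]))

    bc_rows, bc_vals = [], []
    for comp in range(3):
        bc_rows.append(noslip + comp * n)
        bc_vals.append(np.zeros(len(noslip)))
    # Interpolating the parabola at the nodes under-integrates the discrete
    # facet flux; rescale the nodal profile so the P1 inlet flux is exactly Q.
    inlet_vals = prof(verts[inlet, 0])
    f_in = mesh.facets["inlet"]
    area_in, _ = facet_areas_normals(mesh, "inlet")
    nodal = np.zeros(n)
    nodal[space.loc[mesh.vertex_set("inlet")]] = prof(
        mesh.vertices[mesh.vertex_set("inlet"), 0])
    nodal[noslip] = 0.0
    q_h = float((nodal[space.loc[f_in]].mean(axis=1) * area_in).sum())
    q_target = Q_uL_min * C.UL_PER_MIN_TO_M3_PER_S
    if q_h > 0:
        inlet_vals = inlet_vals * (q_target / q_h)
    bc_rows.append(inlet + 2 * n)                      # u_z = profile
    bc_vals.append(inlet_vals)
    for comp in (0, 1):                                # u_x = u_y = 0 at inlet
        bc_rows.append(inlet + comp * n)
        bc_vals.append(np.zeros(len(inlet)))
    bc_rows.append(sym + 1 * n)                        # u_y = 0 on symmetry
    bc_vals.append(np.zeros(len(sym)))
    bc_rows = np.concatenate(bc_rows)
    bc_vals = np.concatenate(bc_vals)

    def assemble(u_cell):
        A = K if u_cell is None else K + space.convection(u_cell) * props.density
        blocks = [
            [A, None, None, -G[0].T],
            [None, A, None, -G[1].T],
            [None, None, A, -G[2].T],
            [G[0], G[1], G[2], Cstab],
        ]
        M = sp.bmat(blocks, format="csr")
        b = np.zeros(4 * n)
        keep = np.ones(4 * n)
        keep[bc_rows] = 0.0
        ind = np.zeros(4 * n)
        ind[bc_rows] = 1.0
        M = sp.diags(keep) @ M + sp.diags(ind)
        b[bc_rows] = bc_vals
        return M.tocsc(), b

    M0, b0 = assemble(None)
    x = spla.splu(M0).solve(b0)
    iterations = 0
    if mode == "picard":
        for iterations in range(1, max_iter + 1):
            u_cell = x[: 3 * n].reshape(3, n).T[space.cells].mean(axis=1)
            M, b = assemble(u_cell)
            x_new = spla.splu(M).solve(b)
            x_new = relax * x_new + (1.0 - relax) * x
            change = np.linalg.norm(x_new - x) / max(np.linalg.norm(x_new), 1e-30)
            x = x_new
            if change < tol:
                break
        else:
            raise FlowError(
                f"Picard iteration did not converge in {max_iter} steps "
                f"(last relative change {change:.2e})"
            )
        M, b = assemble(x[: 3 * n].reshape(3, n).T[space.cells].mean(axis=1))
    else:
        M, b = M0, b0
    res = M @ x - b
    nm = np.linalg.norm
    residuals = {
        "momentum": float(nm(res[: 3 * n]) / max(nm(b), 1e-30)),
        "continuity": float(nm(res[3 * n:]) / max(nm(x[: 3 * n]), 1e-30)),
    }
    velocity = x[: 3 * n].reshape(3, n).T.copy()
    pressure = x[3 * n:].copy()
    return FlowSolution(
        mesh=mesh, space=space, velocity=velocity, pressure=pressure,
        Q_uL_min=Q_uL_min, props=props, residual_norms=residuals, mode=mode,
        iterations=iterations,
    )


def wall_shear(flow: FlowSolution, mesh: Mesh | None = None,
               n_samples: int = 2000):
    """Maximum shear stress on the spheroid surface, in mPa.

    The viscous traction is evaluated at analytic points on the spheroid
    sphere (offset half a local cell outward so the sampled velocity
    gradient lives in medium cells), projected onto the tangent plane of the
    true surface. Returns ``(max_shear_mPa, per-sample shear array)``.
    """
    mesh = mesh or flow.mesh
    if len(mesh.facets["spheroid_interface"]) == 0:
        raise ValueError("mesh carries no spheroid_interface facets")
    cfg = mesh.config
    space = flow.space
    mu = flow.props.viscosity

    # local cell size next to the sphere
    med_side = mesh.facet_cells["spheroid_interface"][:, 0]
    h_loc = float(np.median(np.cbrt(6.0 * mesh.cell_volumes[med_side])))

    center = np.array([
        cfg.spheroid_center[0] - cfg.contact_embed,
        cfg.spheroid_center[1],
        cfg.spheroid_center[2] + (0 if cfg.trap_variant.value == "microwell"
                                  else cfg.contact_embed),
    ]) * 1e-6
    R = cfg.spheroid_radius * 1e-6

    # Fibonacci sphere sampling
    i = np.arange(n_samples) + 0.5
    phi = np.arccos(1 - 2 * i / n_samples)
    theta = math.pi * (1 + 5 ** 0.5) * i
    normals = np.column_stack([
        np.cos(phi), np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta)
    ])

    grad = np.zeros((len(space.cells), 3, 3))
    for comp in range(3):
        grad[:, comp, :] = space.cell_gradients(flow.velocity[:, comp])

    pos = np.full(mesh.n_cells, -1, dtype=np.int64)
    pos[space.cell_ids] = np.arange(len(space.cell_ids))

    shear = np.full(n_samples, np.nan)
    found = np.zeros(n_samples, dtype=bool)
    for off in (0.5, 1.0, 1.6, 2.4):
        todo = ~found
        if not todo.any():
            break
        pts = center + normals[todo] * (R + off * h_loc)
        cid = mesh.locate_cells(pts)
        sc = np.where(cid >= 0, pos[np.clip(cid, 0, None)], -1)
        ok = sc >= 0
        idx = np.flatnonzero(todo)[ok]
        gu = grad[sc[ok]]                               # (m, 3, 3) d u_i / d x_j
        nrm = normals[idx]
        tau = mu * np.einsum("mij,mj->mi", gu + np.transpose(gu, (0, 2, 1)), nrm)
        tang = tau - np.einsum("mi,mi->m", tau, nrm)[:, None] * nrm
        shear[idx] = np.linalg.norm(tang, axis=1)
        found[idx] = True
    shear_mpa = shear[found] * 1e3
    if len(shear_mpa) == 0:
        raise FlowError("no shear samples could be located in the medium")
    return float(shear_mpa.max()), shear_mpa
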