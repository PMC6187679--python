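"""Linear (P1) finite-element kernels on tagged tetrahedral meshes.

Small, self-contained assembly routines used by the flow and transport
solvers: scalar stiffness / mass / convection matrices with per-cell
coefficients, streamline-diffusion stabilization, and point interpolation.
All operators act on a :class:`Subspace`, the restriction of the mesh to a
set of active cells, so that each physics solves only on its own domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .meshing import Mesh

__all__ = ["Subspace", "interpolate"]


@dataclass
class Subspace:
    """P1 nodal space on a subset of a mesh's cells."""

    mesh: Mesh
    cell_ids: np.ndarray          # global cell indices
    verts: np.ndarray             # global vertex ids carrying dofs
    loc: np.ndarray               # global vertex id -> local dof (-1 outside)
    cells: np.ndarray             # (nc, 4) local connectivity
    grads: np.ndarray             # (nc, 4, 3) P1 basis gradients
    vols: np.ndarray              # (nc,) cell volumes

    @classmethod
    def on_cells(cls, mesh: Mesh, cell_ids: np.ndarray) -> "Subspace":
        cell_ids = np.asarray(cell_ids, dtype=np.int64)
        gcells = mesh.cells[cell_ids]
        verts = np.unique(gcells)
        loc = np.full(mesh.n_vertices, -1, dtype=np.int64)
        loc[verts] = np.arange(len(verts))
        cells = loc[gcells]
        v = mesh.vertices
        p0 = v[gcells[:, 0]]
        e = np.stack([v[gcells[:, k]] - p0 for k in (1, 2, 3)], axis=1)  # (nc,3,3)
        # gradients of phi_1..3 are the rows of inv(e)^T; phi_0 closes the sum
        einv = np.linalg.inv(e)
        g123 = np.transpose(einv, (0, 2, 1))
        g0 = -g123.sum(axis=1)
        grads = np.concatenate([g0[:, None, :], g123], axis=1)
        vols = mesh.cell_volumes[cell_ids]
        return cls(mesh=mesh, cell_ids=cell_ids, verts=verts, loc=loc,
                   cells=cells, grads=grads, vols=vols)

    @property
    def n(self) -> int:
        return len(self.verts)

    # -- assembly ----------------------------------------------------------

    def _accumulate(self, ke: np.ndarray) -> sp.csr_matrix:
        """Assemble per-cell 4x4 element matrices into CSR."""
        rows = np.repeat(self.cells, 4, axis=1).ravel()
        cols = np.tile(self.cells, (1, 4)).ravel()
        return sp.coo_matrix(
            (ke.ravel(), (rows, cols)), shape=(self.n, self.n)
        ).tocsr()

    def stiffness(self, coeff: np.ndarray | float) -> sp.csr_matrix:
        """∫ k ∇φ_j·∇φ_i with piecewise-constant coefficient k."""
        k = np.broadcast_to(np.asarray(coeff, dtype=float), (len(self.vols),))
        ke = np.einsum("cid,cjd->cij", self.grads, self.grads)
        ke = ke * (k * self.vols)[:, None, None]
        return self._accumulate(ke)

    def mass(self, coeff: np.ndarray | float = 1.0, lumped: bool = False):
        """∫ s φ_j φ_i (consistent) or its row-lumped diagonal."""
        s = np.broadcast_to(np.asarray(coeff, dtype=float), (len(self.vols),))
        w = s * self.vols
        if lumped:
            diag = np.zeros(self.n)
            np.add.at(diag, self.cells.ravel(), np.repeat(w / 4.0, 4))
            return sp.diags(diag).tocsr()
        base = (np.ones((4, 4)) + np.eye(4)) / 20.0
        ke = base[None, :, :] * w[:, None, None]
        return self._accumulate(ke)

    def convection(self, u_cell: np.ndarray, supg: bool = False,
                   diff_coeff: np.ndarray | float = 0.0) -> sp.csr_matrix:
        """∫ (u·∇φ_j) φ_i with cellwise-constant velocity.

        With ``supg=True`` a streamline-diffusion term
        τ_c ∫ (u·∇φ_j)(u·∇φ_i) is added, with the classic coth-based τ built
        from the cell Péclet number against ``diff_coeff``.
        """
        a = np.einsum("cd,cjd->cj", u_cell, self.grads)      # u·∇φ_j
        ke = np.repeat((a * (self.vols / 4.0)[:, None])[:, None, :], 4, axis=1)
        if supg:
            speed = np.linalg.norm(u_cell, axis=1)
            h = np.cbrt(6.0 * self.vols)                     # isotropic size
            k = np.broadcast_to(np.asarray(diff_coeff, float), speed.shape)
            with np.errstate(divide="ignore", invalid="ignore"):
                pe = speed * h / (2.0 * np.maximum(k, 1e-300))
                xi = 1.0 / np.tanh(pe) - 1.0 / pe
            xi = np.where(pe > 1e-8, xi, pe / 3.0)
            tau = np.where(speed > 0, h / (2.0 * np.maximum(speed, 1e-300)) * xi, 0.0)
            ke = ke + np.einsum("ci,cj->cij", a, a) * (tau * self.vols)[:, None, None]
        return self._accumulate(ke)

    def load(self, coeff: np.ndarray | float) -> np.ndarray:
        """∫ f φ_i with piecewise-constant f."""
        f = np.broadcast_to(np.asarray(coeff, dtype=float), (len(self.vols),))
        b = np.zeros(self.n)
        np.add.at(b, self.cells.ravel(), np.repeat(f * self.vols / 4.0, 4))
        return b

    def cell_values(self, nodal: np.ndarray) -> np.ndarray:
        return nodal[self.cells].mean(axis=1)

    def cell_gradients(self, nodal: np.ndarray) -> np.ndarray:
        """Piecewise-constant gradient of a P1 field, (nc, 3)."""
        return np.einsum("cj,cjd->cd", nodal[self.cells], self.grads)

    def local_dofs(self, global_vertex_ids: np.ndarray) -> np.ndarray:
        d = self.loc[global_vertex_ids]
        return d[d >= 0]


def dirichlet_apply(A: sp.csr_matrix, b: np.ndarray,
                    dofs: np.ndarray, values: np.ndarray):
    """Impose A[d,:] = e_d, b[d] = value (row replacement)."""
    n = A.shape[0]
    keep = np.ones(n)
    keep[dofs] = 0.0
    ind = np.zeros(n)
    ind[dofs] = 1.0
    A = (sp.diags(keep) @ A + sp.diags(ind)).tocsr()
    b = b.copy()
    b[dofs] = values
    return A, b


def interpolate(mesh: Mesh, space: Subspace, nodal: np.ndarray,
                pts_m: np.ndarray, fill: float = np.nan) -> np.ndarray:
    """Evaluate a P1 field of a subspace at physical points.

    Points falling in cells outside the subspace (or outside the solid)
    receive ``fill``.
    """
    pts = np.atleast_2d(pts_m)
    cid = mesh.locate_cells(pts)
    out = np.full(len(pts), fill, dtype=float)
    ok = cid >= 0
    if not ok.any():
        return out
    # map global cell -> position in subspace
    pos = np.full(mesh.n_cells, -1, dtype=np.int64)
    pos[space.cell_ids] = np.arange(len(space.cell_ids))
    sc = pos[cid[ok]]
    ok2 = np.flatnonzero(ok)[sc >= 0]
    sc = sc[sc >= 0]
    gcells = mesh.cells[space.cell_ids[sc]]
    v = mesh.vertices
    p0 = v[gcells[:, 0]]
    T = np.stack([v[gcells[:, k]] - p0 for k in (1, 2, 3)], axis=2)
    lam = np.linalg.solve(T, (pts[ok2] - p0)[:, :, None])[:, :, 0]
    w = np.column_stack([1.0 - lam.sum(axis=1), lam])
    vals = nodal[space.cells[sc]]
    out[ok2] = (w * vals).sum(axis=1)
    return out
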