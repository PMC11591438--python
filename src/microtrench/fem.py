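"""Q2/Q1 (Taylor-Hood) finite elements on bilinear quadrilaterals.

Velocity lives on 9-node biquadratic elements, pressure and scalar transport
on the 4-node bilinear corners.  Geometry is bilinear (straight-edged quads),
so on rectangular cells the mapping is affine and a parabolic channel profile
is represented exactly — plane-Poiseuille wall shear stress is recovered to
machine precision, which anchors the analytic validation.

Everything is assembled vectorised over elements with 3x3 Gauss quadrature
and scattered into scipy.sparse matrices.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .meshing import Mesh

_G = np.sqrt(0.6)
GAUSS3 = (np.array([-_G, 0.0, _G]), np.array([5 / 9, 8 / 9, 5 / 9]))
GAUSS2 = (np.array([-1 / np.sqrt(3), 1 / np.sqrt(3)]), np.array([1.0, 1.0]))

# Q2 tensor indices: corners, edge midpoints (bottom,right,top,left), centre
_Q2_IJ = [(0, 0), (2, 0), (2, 2), (0, 2), (1, 0), (2, 1), (1, 2), (0, 1), (1, 1)]


def _lag(x):
    """Quadratic Lagrange values/derivatives at nodes -1, 0, 1."""
    v = np.array([x * (x - 1) / 2, 1 - x * x, x * (x + 1) / 2])
    d = np.array([x - 0.5, -2 * x, x + 0.5])
    return v, d


def q1_shape(xi, eta):
    n = 0.25 * np.array([(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                         (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)])
    d = 0.25 * np.array([[-(1 - eta), -(1 - xi)], [(1 - eta), -(1 + xi)],
                         [(1 + eta), (1 + xi)], [-(1 + eta), (1 - xi)]])
    return n, d


def q2_shape(xi, eta):
    lx, dlx = _lag(xi)
    ly, dly = _lag(eta)
    n = np.array([lx[a] * ly[b] for a, b in _Q2_IJ])
    d = np.array([[dlx[a] * ly[b], lx[a] * dly[b]] for a, b in _Q2_IJ])
    return n, d


def _side_ref(side: int, t):
    """Reference coords along element side s, param t in [-1,1] start->end."""
    if side == 0:
        return t, -np.ones_like(t)
    if side == 1:
        return np.ones_like(t), t
    if side == 2:
        return -t, np.ones_like(t)
    return -np.ones_like(t), -t


class Q2Q1Space:
    """Discrete function space pair on a quad mesh; precomputes quadrature."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.n1 = mesh.n_nodes
        self._build_q2()
        self._precompute_volume()

    # ------------------------------------------------------------------
    def _build_q2(self):
        quads = self.mesh.quads
        ne = len(quads)
        edge_ids: dict[tuple[int, int], int] = {}
        conn = np.empty((ne, 9), dtype=np.int64)
        conn[:, :4] = quads
        nxt = self.n1
        coords = [self.mesh.nodes]
        extra = []
        for e in range(ne):
            for s in range(4):
                a, b = int(quads[e, s]), int(quads[e, (s + 1) % 4])
                key = (a, b) if a < b else (b, a)
                idx = edge_ids.get(key)
                if idx is None:
                    idx = nxt
                    edge_ids[key] = idx
                    extra.append(0.5 * (self.mesh.nodes[a] + self.mesh.nodes[b]))
                    nxt += 1
                conn[e, 4 + s] = idx
        centers = self.mesh.nodes[quads].mean(axis=1)
        conn[:, 8] = np.arange(nxt, nxt + ne)
        nxt += ne
        self.q2_conn = conn
        self.n2 = nxt
        self.q2_coords = np.concatenate([coords[0], np.asarray(extra).reshape(-1, 2),
                                         centers], axis=0)

    # ------------------------------------------------------------------
    def _precompute_volume(self):
        pts, wts = GAUSS3
        qp = [(xi, eta, wx * we) for eta, we in zip(pts, wts) for xi, wx in zip(pts, wts)]
        nq = len(qp)
        ne = self.mesh.n_cells
        corners = self.mesh.nodes[self.mesh.quads]          # (ne,4,2)
        self.nq = nq
        self.N1 = np.empty((nq, 4))
        self.N2 = np.empty((nq, 9))
        self.detJw = np.empty((ne, nq))
        self.dN1 = np.empty((ne, nq, 4, 2))
        self.dN2 = np.empty((ne, nq, 9, 2))
        for q, (xi, eta, w) in enumerate(qp):
            n1, d1 = q1_shape(xi, eta)
            n2, d2 = q2_shape(xi, eta)
            self.N1[q], self.N2[q] = n1, n2
            J = np.einsum("eci,cj->eij", corners, d1)        # (ne,2,2) [dx/dxi]
            detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            inv = np.empty_like(J)
            inv[:, 0, 0] = J[:, 1, 1]
            inv[:, 1, 1] = J[:, 0, 0]
            inv[:, 0, 1] = -J[:, 0, 1]
            inv[:, 1, 0] = -J[:, 1, 0]
            inv /= detJ[:, None, None]
            self.detJw[:, q] = detJ * w
            self.dN1[:, q] = np.einsum("cj,eji->eci", d1, inv)
            self.dN2[:, q] = np.einsum("cj,eji->eci", d2, inv)
        self.cell_h = np.sqrt(self.detJw.sum(axis=1))        # characteristic size

    # -- element->global scatter ---------------------------------------
    def _scatter(self, ke, conn, shape):
        nloc = conn.shape[1]
        rows = np.repeat(conn, nloc, axis=1).ravel()
        cols = np.tile(conn, (1, nloc)).ravel()
        return sp.csr_matrix((ke.ravel(), (rows, cols)), shape=shape)

    def _scatter_rect(self, ke, rconn, cconn, shape):
        nr, nc = rconn.shape[1], cconn.shape[1]
        rows = np.repeat(rconn, nc, axis=1).ravel()
        cols = np.tile(cconn, (1, nr)).ravel()
        return sp.csr_matrix((ke.ravel(), (rows, cols)), shape=shape)

    # -- operators ------------------------------------------------------
    def stiffness2(self) -> sp.csr_matrix:
        ke = np.einsum("eq,eqid,eqjd->eij", self.detJw, self.dN2, self.dN2)
        return self._scatter(ke, self.q2_conn, (self.n2, self.n2))

    def mass2(self) -> sp.csr_matrix:
        ke = np.einsum("eq,qi,qj->eij", self.detJw, self.N2, self.N2)
        return self._scatter(ke, self.q2_conn, (self.n2, self.n2))

    def div_matrices(self):
        """Bx, By with (B)_{ij} = int N1_i dN2_j/dx_k over the domain."""
        kx = np.einsum("eq,qi,eqj->eij", self.detJw, self.N1, self.dN2[..., 0])
        ky = np.einsum("eq,qi,eqj->eij", self.detJw, self.N1, self.dN2[..., 1])
        Bx = self._scatter_rect(kx, self.mesh.quads, self.q2_conn, (self.n1, self.n2))
        By = self._scatter_rect(ky, self.mesh.quads, self.q2_conn, (self.n1, self.n2))
        return Bx, By

    def velocity_at_qp(self, u2: np.ndarray) -> np.ndarray:
        """(ne, nq, 2) velocity at volume quadrature points."""
        ue = u2[self.q2_conn]                                # (ne,9,2)
        return np.einsum("qi,eic->eqc", self.N2, ue)

    def convection2(self, u2: np.ndarray) -> sp.csr_matrix:
        """C_{ij} = int phi_i (u . grad phi_j)."""
        uq = self.velocity_at_qp(u2)
        adv = np.einsum("eqc,eqjc->eqj", uq, self.dN2)       # u.grad(phi_j)
        ke = np.einsum("eq,qi,eqj->eij", self.detJw, self.N2, adv)
        return self._scatter(ke, self.q2_conn, (self.n2, self.n2))

    def streamline_diffusion2(self, u2: np.ndarray, nu: float) -> sp.csr_matrix:
        """Streamline-upwind stabilization for Q2 momentum advection:
        int tau (u.grad phi_i)(u.grad phi_j), tau = [(2|u|/h)^2 + (4 nu/h^2)^2]^-1/2.

        Advection-only (no pressure/viscous residual), so states with
        u.grad(u) = 0 — plane Poiseuille/Couette — are not perturbed and the
        analytic wall-shear anchors stay exact."""
        uq = self.velocity_at_qp(u2)
        umag = np.linalg.norm(uq, axis=2)
        h = self.cell_h[:, None]
        tau = 1.0 / np.sqrt((2 * umag / h) ** 2 + (4 * nu / h**2) ** 2 + 1e-300)
        adv = np.einsum("eqc,eqjc->eqj", uq, self.dN2)
        ke = np.einsum("eq,eq,eqi,eqj->eij", self.detJw, tau, adv, adv)
        return self._scatter(ke, self.q2_conn, (self.n2, self.n2))

    def newton_blocks(self, u2: np.ndarray):
        """D[a][b]_{ij} = int phi_i phi_j du_a/dx_b  (Jacobian of convection)."""
        ue = u2[self.q2_conn]                                # (ne,9,2)
        grad = np.einsum("eia,eqib->eqab", ue, self.dN2)     # (ne,nq,2,2)
        out = [[None, None], [None, None]]
        nn = np.einsum("eq,qi,qj->eqij", self.detJw, self.N2, self.N2)
        for a in range(2):
            for b in range(2):
                ke = np.einsum("eqij,eq->eij", nn, grad[..., a, b])
                out[a][b] = self._scatter(ke, self.q2_conn, (self.n2, self.n2))
        return out

    # -- Q1 scalar operators (transport) --------------------------------
    def stiffness1(self, diff=None) -> sp.csr_matrix:
        """int D grad(phi_i).grad(phi_j); diff per (elem, qp) or scalar."""
        w = self.detJw if diff is None else self.detJw * diff
        ke = np.einsum("eq,eqid,eqjd->eij", w, self.dN1, self.dN1)
        return self._scatter(ke, self.mesh.quads, (self.n1, self.n1))

    def mass1(self) -> sp.csr_matrix:
        ke = np.einsum("eq,qi,qj->eij", self.detJw, self.N1, self.N1)
        return self._scatter(ke, self.mesh.quads, (self.n1, self.n1))

    def advection1_conservative(self, u2: np.ndarray) -> sp.csr_matrix:
        """Volume part of conservative advection: -int (u.grad phi_i) phi_j."""
        uq = self.velocity_at_qp(u2)
        adv_i = np.einsum("eqc,eqic->eqi", uq, self.dN1)
        ke = -np.einsum("eq,eqi,qj->eij", self.detJw, adv_i, self.N1)
        return self._scatter(ke, self.mesh.quads, (self.n1, self.n1))

    # -- boundary machinery ---------------------------------------------
    def edge_geometry(self, edges: np.ndarray, npts: int = 2):
        """Quadrature along (elem, side) edges.

        Returns dict with per-edge, per-point arrays: physical coords
        (k,npts,2), unit tangents (edge direction), unit normals (into the
        fluid, +90 deg rotation of tangent), weights (k,npts) summing to the
        edge length, plus reference-space data to evaluate fields.
        """
        if npts == 2:
            pts, wts = GAUSS2
        elif npts == 3:
            pts, wts = GAUSS3
        else:
            pts, wts = np.array([0.0]), np.array([2.0])
        elems = edges[:, 0].astype(np.int64)
        sides = edges[:, 1].astype(np.int64)
        k = len(edges)
        a = self.mesh.quads[elems, sides]
        b = self.mesh.quads[elems, (sides + 1) % 4]
        pa, pb = self.mesh.nodes[a], self.mesh.nodes[b]
        L = np.linalg.norm(pb - pa, axis=1)
        tang = (pb - pa) / L[:, None]
        norm = np.column_stack([-tang[:, 1], tang[:, 0]])
        xy = np.empty((k, npts, 2))
        W = np.empty((k, npts))
        N2v = np.empty((k, npts, 9))
        dN2v = np.empty((k, npts, 9, 2))
        N1v = np.empty((k, npts, 4))
        corners = self.mesh.nodes[self.mesh.quads[elems]]    # (k,4,2)
        for p, (t, w) in enumerate(zip(pts, wts)):
            frac = 0.5 * (t + 1.0)
            xy[:, p] = pa + (pb - pa) * frac
            W[:, p] = w * L / 2.0
            for s in range(4):
                m = sides == s
                if not m.any():
                    continue
                xi, eta = _side_ref(s, np.array(t))
                n1, d1 = q1_shape(float(xi), float(eta))
                n2, d2 = q2_shape(float(xi), float(eta))
                J = np.einsum("kci,cj->kij", corners[m], d1)
                detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
                inv = np.empty_like(J)
                inv[:, 0, 0] = J[:, 1, 1]
                inv[:, 1, 1] = J[:, 0, 0]
                inv[:, 0, 1] = -J[:, 0, 1]
                inv[:, 1, 0] = -J[:, 1, 0]
                inv /= detJ[:, None, None]
                N1v[m, p] = n1
                N2v[m, p] = n2
                dN2v[m, p] = np.einsum("cj,kji->kci", d2, inv)
        return {"elems": elems, "sides": sides, "xy": xy, "tangent": tang,
                "normal": norm, "weights": W, "N1": N1v, "N2": N2v, "dN2": dN2v,
                "length": L}

    def boundary_mass1(self, edges: np.ndarray, coef) -> sp.csr_matrix:
        """int coef phi_i phi_j ds over edges; coef scalar or per-edge."""
        geo = self.edge_geometry(edges, npts=2)
        conn = self.mesh.quads[geo["elems"]]                 # (k,4)
        coef = np.broadcast_to(np.asarray(coef, dtype=float), (len(edges),))
        ke = np.einsum("k,kp,kpi,kpj->kij", coef, geo["weights"], geo["N1"], geo["N1"])
        return self._scatter(ke, conn, (self.n1, self.n1))

    def outflow_mass1(self, u2: np.ndarray, edges: np.ndarray) -> sp.csr_matrix:
        """int (u.n) phi_i phi_j ds over outflow edges (conservative advection)."""
        geo = self.edge_geometry(edges, npts=2)
        conn2 = self.q2_conn[geo["elems"]]
        uq = np.einsum("kpi,kic->kpc", geo["N2"], u2[conn2])
        un = np.einsum("kpc,kc->kp", uq, -geo["normal"])     # outward = -into-fluid
        conn = self.mesh.quads[geo["elems"]]
        ke = np.einsum("kp,kp,kpi,kpj->kij", geo["weights"], un, geo["N1"], geo["N1"])
        return self._scatter(ke, conn, (self.n1, self.n1))

    def boundary_flux(self, u2: np.ndarray, edges: np.ndarray) -> float:
        """Volumetric flux int u.n ds (n outward from the fluid)."""
        geo = self.edge_geometry(edges, npts=2)
        conn2 = self.q2_conn[geo["elems"]]
        uq = np.einsum("kpi,kic->kpc", geo["N2"], u2[conn2])
        un = np.einsum("kpc,kc->kp", uq, -geo["normal"])
        return float(np.sum(un * geo["weights"]))

    def nodes_on_edges(self, edges: np.ndarray, space: str = "q2") -> np.ndarray:
        """Unique node indices lying on the given (elem, side) edges."""
        elems = edges[:, 0].astype(np.int64)
        sides = edges[:, 1].astype(np.int64)
        if space == "q1":
            a = self.mesh.quads[elems, sides]
            b = self.mesh.quads[elems, (sides + 1) % 4]
            return np.unique(np.concatenate([a, b]))
        conn = self.q2_conn
        a = conn[elems, sides]
        b = conn[elems, (sides + 1) % 4]
        m = conn[elems, 4 + sides]
        return np.unique(np.concatenate([a, b, m]))


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, idx: np.ndarray,
                    vals: np.ndarray):
    """Row/column-elimination Dirichlet application (returns modified copies)."""
    b = b.copy()
    x = np.zeros(A.shape[0])
    x[idx] = vals
    b -= A @ x
    mask = np.zeros(A.shape[0], dtype=bool)
    mask[idx] = True
    keep = sp.diags((~mask).astype(float))
    A = keep @ A @ keep + sp.diags(mask.astype(float))
    b[idx] = vals
    return A.tocsc(), b
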