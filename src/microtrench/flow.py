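"""Steady incompressible laminar Navier-Stokes solver.

Discretization: Q2/Q1 Taylor-Hood mixed finite elements (inf-sup stable, no
pressure stabilization needed).  The nonlinear system is solved by a short
Picard (Oseen) warm-up followed by damped Newton iterations; every linear
saddle-point system goes through SuperLU (scipy.sparse.linalg.spsolve), so a
given mesh + conditions reproduce bit-identical residual histories.

Boundary conditions: Dirichlet velocity at the inlet (uniform plug or fully
developed parabola), no-slip walls, and a natural "do-nothing" outlet which
acts as a zero-gauge-pressure outflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import Q2Q1Space
from .geometry import ChannelSpec, FluidProperties
from .meshing import Mesh, generate_mesh

__all__ = [
    "FlowConditions",
    "FlowField",
    "ConvergenceError",
    "inlet_velocity_for_bulk_wss",
    "solve_steady_flow",
    "solve_lid_driven_cavity",
]

PA_TO_DYN_CM2 = 10.0  # 1 Pa = 10 dyn/cm^2


class ConvergenceError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


def inlet_velocity_for_bulk_wss(target_bulk_wss: float, clear_height: float,
                                viscosity: float) -> float:
    """Mean velocity giving fully developed plane-Poiseuille wall shear
    tau_w = 6 mu U / h equal to ``target_bulk_wss`` (dyn/cm^2)."""
    if target_bulk_wss < 0 or clear_height <= 0 or viscosity <= 0:
        raise ValueError("target_bulk_wss >= 0 and positive h, mu required")
    tau_pa = target_bulk_wss / PA_TO_DYN_CM2
    return tau_pa * clear_height / (6.0 * viscosity)


@dataclass(frozen=True)
class FlowConditions:
    """Inlet specification: exactly one of mean velocity (m/s) or target
    fully developed bulk WSS (dyn/cm^2).  ``inlet_profile`` 'developed'
    imposes the parabolic profile directly (short-domain shortcut);
    'uniform' imposes a plug and requires an adequate entrance length."""

    inlet_mean_velocity: float | None = None
    target_bulk_wss: float | None = None
    inlet_profile: str = "developed"
    max_reynolds: float = 2000.0

    def __post_init__(self):
        if (self.inlet_mean_velocity is None) == (self.target_bulk_wss is None):
            raise ValueError(
                "specify exactly one of inlet_mean_velocity / target_bulk_wss")
        if self.inlet_profile not in ("developed", "uniform"):
            raise ValueError(f"unknown inlet_profile {self.inlet_profile!r}")

    def mean_velocity(self, clear_height: float, viscosity: float) -> float:
        if self.inlet_mean_velocity is not None:
            return self.inlet_mean_velocity
        return inlet_velocity_for_bulk_wss(self.target_bulk_wss, clear_height,
                                           viscosity)


@dataclass
class FlowField:
    """Converged steady solution on a mesh."""

    mesh: Mesh
    space: Q2Q1Space
    velocity: np.ndarray          # (n2, 2) at Q2 nodes
    pressure: np.ndarray          # (n1,) at Q1 nodes
    residual_history: list = field(default_factory=list)
    converged: bool = False
    mean_velocity: float = 0.0
    reynolds: float = 0.0
    fluid: FluidProperties | None = None

    def mass_flux_imbalance(self) -> float:
        """|inlet flux + outlet flux| / |inlet flux| (outward normals)."""
        fin = self.space.boundary_flux(self.velocity, self.mesh.inlet_edges)
        fout = self.space.boundary_flux(self.velocity, self.mesh.outlet_edges)
        return abs(fin + fout) / max(abs(fin), 1e-300)

    def vorticity_q1(self) -> np.ndarray:
        """Lumped L2 projection of dv/dx - du/dy onto Q1 nodes."""
        sp_ = self.space
        ue = self.velocity[sp_.q2_conn]                      # (ne,9,2)
        grad = np.einsum("eia,eqib->eqab", ue, sp_.dN2)      # (ne,nq,2,2)
        om = grad[..., 1, 0] - grad[..., 0, 1]
        num = np.zeros(sp_.n1)
        den = np.zeros(sp_.n1)
        we = np.einsum("eq,qi->ei", sp_.detJw, sp_.N1)
        np.add.at(num, sp_.mesh.quads, np.einsum("eq,qi,eq->ei", sp_.detJw, sp_.N1, om))
        np.add.at(den, sp_.mesh.quads, we)
        return num / np.maximum(den, 1e-300)

    def trench_circulation(self) -> float:
        """Integral of vorticity over cells below the floor plane (y < 0)."""
        sp_ = self.space
        ue = self.velocity[sp_.q2_conn]
        grad = np.einsum("eia,eqib->eqab", ue, sp_.dN2)
        om = grad[..., 1, 0] - grad[..., 0, 1]
        centers = self.mesh.nodes[self.mesh.quads].mean(axis=1)
        below = centers[:, 1] < -1e-12
        return float(np.einsum("eq,eq->", sp_.detJw[below], om[below]))


def _assemble_constant(space: Q2Q1Space, mu: float):
    K = mu * space.stiffness2()
    Bx, By = space.div_matrices()
    return K, Bx, By


def _saddle(A00, A01, A10, A11, Bx, By):
    return sp.bmat([[A00, A01, -Bx.T], [A10, A11, -By.T], [Bx, By, None]],
                   format="csr")


def _momentum_operator(space, K, rho, nu, u2):
    """mu*K + rho*(convection + streamline-upwind stabilization) at state u2."""
    return K + rho * (space.convection2(u2) + space.streamline_diffusion2(u2, nu))


def _nonlinear_residual(space, K, Bx, By, rho, nu, u, v, p):
    A = _momentum_operator(space, K, rho, nu, np.column_stack([u, v]))
    ru = A @ u - Bx.T @ p
    rv = A @ v - By.T @ p
    rc = Bx @ u + By @ v
    return ru, rv, rc


def solve_navier_stokes(space: Q2Q1Space, mu: float, rho: float,
                        dir_idx: np.ndarray, dir_val: np.ndarray,
                        pin_pressure: bool = False, tol: float = 1e-6,
                        max_iter: int = 40, n_picard: int = 2,
                        relax: float = 0.8, u_scale: float = 1.0):
    """Low-level steady Navier-Stokes driver.

    Dirichlet dofs are given in the global [u, v, p] layout.  The nonlinear
    strategy is: Stokes start -> a short relaxed Picard (Oseen) phase with
    state-dependent streamline-upwind stabilization -> the stabilization
    operator is frozen at the last Picard state (making it a fixed linear
    term of the discretization) -> exact damped Newton, with pseudo-transient
    continuation as the fallback.  Everything is deterministic: fixed
    iteration order, direct sparse solves.
    """
    n2, n1 = space.n2, space.n1
    nu = mu / rho
    K, Bx, By = _assemble_constant(space, mu)
    Z = sp.csr_matrix((n2, n2))
    ndof = 2 * n2 + n1

    all_idx = dir_idx.copy()
    all_val = dir_val.copy()
    if pin_pressure:
        all_idx = np.append(all_idx, 2 * n2)
        all_val = np.append(all_val, 0.0)
    free = np.ones(ndof, dtype=bool)
    free[all_idx] = False

    history = []
    ref = max(mu * u_scale + rho * u_scale**2, 1e-300)
    mask_free = sp.diags(free.astype(float))
    fix = sp.diags((~free).astype(float))

    SU = None   # frozen rho * streamline-upwind operator (set after Picard)

    def momentum(u2):
        A = K + rho * space.convection2(u2)
        if SU is not None:
            A = A + SU
        else:
            A = A + rho * space.streamline_diffusion2(u2, nu)
        return A

    def residual_parts(u, v, p):
        A = momentum(np.column_stack([u, v]))
        return A @ u - Bx.T @ p, A @ v - By.T @ p, Bx @ u + By @ v

    def norms(u, v, p):
        ru, rv, rc = residual_parts(u, v, p)
        rm = np.linalg.norm(np.concatenate([ru, rv])[free[: 2 * n2]])
        return rm, np.linalg.norm(rc) * u_scale

    def record(kind, rm, rcn):
        history.append({"iter": len(history), "type": kind,
                        "r_mom": rm / denom, "r_cont": rcn / denom})
        return rm / denom < tol and rcn / denom < tol

    def constrained(S, b):
        b = b.copy()
        x0 = np.zeros(ndof)
        x0[all_idx] = all_val
        b -= S @ x0
        Sc = mask_free @ S @ mask_free + fix
        b[all_idx] = all_val
        return spla.spsolve(Sc.tocsc(), b)

    # ---- phase 0: Stokes ------------------------------------------------
    S = _saddle(K, Z, Z, K, Bx, By)
    sol = constrained(S, np.zeros(ndof))
    u, v, p = sol[:n2], sol[n2:2 * n2], sol[2 * n2:]
    rm, rcn = norms(u, v, p)
    denom = max(rm, rcn, ref * 1e-8)
    converged = record("stokes", rm, rcn)

    # ---- phase 1: relaxed Picard with live stabilization ----------------
    for _ in range(n_picard):
        if converged:
            break
        A = momentum(np.column_stack([u, v]))
        S = _saddle(A, Z, Z, A, Bx, By)
        sol_new = constrained(S, np.zeros(ndof))
        base = np.concatenate([u, v, p])
        trial = base + relax * (sol_new - base)
        u, v, p = trial[:n2], trial[n2:2 * n2], trial[2 * n2:]
        rm, rcn = norms(u, v, p)
        converged = record("picard", rm, rcn)

    # ---- freeze the stabilization operator ------------------------------
    if not converged:
        SU = rho * space.streamline_diffusion2(np.column_stack([u, v]), nu)
        rm, rcn = norms(u, v, p)
        denom = max(denom, 1e-8 * max(rm, rcn))
        converged = record("freeze-su", rm, rcn)

    def newton(u, v, p, budget):
        conv = False
        stall = 0
        for _ in range(budget):
            u2 = np.column_stack([u, v])
            A = momentum(u2)
            D = space.newton_blocks(u2)
            S = _saddle(A + rho * D[0][0], rho * D[0][1],
                        rho * D[1][0], A + rho * D[1][1], Bx, By)
            F = np.concatenate([A @ u - Bx.T @ p, A @ v - By.T @ p,
                                Bx @ u + By @ v])
            F[all_idx] = np.concatenate([u, v, p])[all_idx] - all_val
            Sc = mask_free @ S @ mask_free + fix
            delta = spla.spsolve(Sc.tocsc(), -F)
            rm_old, rc_old = norms(u, v, p)
            step = 1.0
            accepted = False
            for _ls in range(5):
                trial = np.concatenate([u, v, p]) + step * delta
                rm_t, rc_t = norms(trial[:n2], trial[n2:2 * n2],
                                   trial[2 * n2:])
                if max(rm_t, rc_t) < max(rm_old, rc_old):
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                stall += 1
                if stall >= 2:
                    break
                continue
            u, v, p = trial[:n2], trial[n2:2 * n2], trial[2 * n2:]
            conv = record("newton", rm_t, rc_t)
            if conv:
                break
        return u, v, p, conv

    def pseudo_transient(u, v, p, budget):
        """SER continuation on the same fixed-stabilization system."""
        M2 = rho * space.mass2()
        dt = float(space.cell_h.min()) / max(u_scale, 1e-12) * 2.0
        rm, rcn = norms(u, v, p)
        r_prev = max(rm, rcn)
        conv = False
        for _ in range(budget):
            lam = 1.0 / dt
            u2 = np.column_stack([u, v])
            A = momentum(u2)
            D = space.newton_blocks(u2)
            S = _saddle(A + rho * D[0][0] + lam * M2, rho * D[0][1],
                        rho * D[1][0], A + rho * D[1][1] + lam * M2, Bx, By)
            F = np.concatenate([A @ u - Bx.T @ p, A @ v - By.T @ p,
                                Bx @ u + By @ v])
            F[all_idx] = np.concatenate([u, v, p])[all_idx] - all_val
            Sc = mask_free @ S @ mask_free + fix
            delta = spla.spsolve(Sc.tocsc(), -F)
            trial = np.concatenate([u, v, p]) + delta
            rm_t, rc_t = norms(trial[:n2], trial[n2:2 * n2], trial[2 * n2:])
            r_new = max(rm_t, rc_t)
            if r_new <= 1.05 * r_prev:
                u, v, p = trial[:n2], trial[n2:2 * n2], trial[2 * n2:]
                dt *= 1.8 if r_new < r_prev else 1.0
                r_prev = min(r_prev, r_new)
                conv = record("pseudo", rm_t, rc_t)
                if conv:
                    break
            else:
                dt *= 0.2
                if dt < 1e-12:
                    break
        return u, v, p, conv

    if not converged:
        u, v, p, converged = newton(u, v, p, max(8, max_iter // 2))
    if not converged:
        u, v, p, converged = pseudo_transient(u, v, p, max(25, max_iter))
    if not converged:
        u, v, p, converged = newton(u, v, p, 6)

    return np.column_stack([u, v]), p, history, converged


def solve_steady_flow(mesh: Mesh, fluid: FluidProperties,
                      conditions: FlowConditions, *, tol: float = 1e-6,
                      max_iter: int = 40, n_picard: int = 3,
                      relax: float = 0.7) -> FlowField:
    """Solve the steady laminar flow through a meshed trench channel.

    Raises :class:`ConvergenceError` (carrying the residual history) if the
    nonlinear iteration does not meet ``tol`` within ``max_iter``, and
    ``ValueError`` for a Reynolds number beyond the laminar guard or an
    inadequate entrance length with a uniform inlet.
    """
    H = mesh.profile.clear_height
    U = conditions.mean_velocity(H, fluid.viscosity)
    Re = fluid.density * U * H / fluid.viscosity
    if Re > conditions.max_reynolds:
        raise ValueError(
            f"Re = {Re:.1f} exceeds the laminar guard {conditions.max_reynolds}; "
            "the model assumes laminar flow")
    if conditions.inlet_profile == "uniform":
        ent = mesh.profile.segments[0]
        ent_len = ent.dx if ent.cls == "entrance-flat" else 0.0
        need = 0.05 * Re * H
        if ent_len < need:
            raise ValueError(
                f"uniform inlet needs entrance_length >= 0.05*Re*h = {need:.3e} m "
                f"for developed flow at the first trench; got {ent_len:.3e} m "
                "(or use inlet_profile='developed')")

    space = Q2Q1Space(mesh)
    n2 = space.n2
    inlet_nodes = space.nodes_on_edges(mesh.inlet_edges, "q2")
    wall_nodes = np.unique(np.concatenate([
        space.nodes_on_edges(mesh.top_edges, "q2"),
        space.nodes_on_edges(mesh.wetted_edges[:, :2], "q2"),
    ]))
    y = space.q2_coords[inlet_nodes, 1]
    if conditions.inlet_profile == "developed":
        uin = 6.0 * U * y * (H - y) / H**2
    else:
        uin = np.full_like(y, U)
    # wall overrides inlet at shared corners
    dir_map: dict[int, float] = {int(n): float(val) for n, val in zip(inlet_nodes, uin)}
    for n in wall_nodes:
        dir_map[int(n)] = 0.0
    u_idx = np.array(sorted(dir_map), dtype=np.int64)
    u_val = np.array([dir_map[i] for i in u_idx])
    v_nodes = np.unique(np.concatenate([inlet_nodes, wall_nodes]))
    dir_idx = np.concatenate([u_idx, n2 + v_nodes])
    dir_val = np.concatenate([u_val, np.zeros(len(v_nodes))])

    if U == 0.0:
        vel = np.zeros((n2, 2))
        return FlowField(mesh, space, vel, np.zeros(space.n1), [], True, 0.0, 0.0,
                         fluid)

    vel, p, history, ok = solve_navier_stokes(
        space, fluid.viscosity, fluid.density, dir_idx, dir_val,
        pin_pressure=False, tol=tol, max_iter=max_iter, n_picard=n_picard,
        relax=relax, u_scale=U)
    if not ok:
        raise ConvergenceError(
            f"steady solve did not reach tol={tol} in {max_iter} iterations "
            f"(last r_mom={history[-1]['r_mom']:.2e})", history)
    return FlowField(mesh, space, vel, p, history, True, U, Re, fluid)


def solve_lid_driven_cavity(n: int = 48, reynolds: float = 100.0,
                            tol: float = 1e-8, max_iter: int = 40):
    """Validation harness: unit lid-driven cavity at the given Reynolds
    number (lid speed 1, unit viscosity scaled by 1/Re).

    Returns (FlowField-like tuple, vortex_center, psi_min): the primary
    vortex located from the streamfunction computed by a Poisson solve of
    -lap(psi) = -omega with psi = 0 on the boundary.
    """
    channel = ChannelSpec(clear_height=1.0, entrance_length=0.5, exit_length=0.5)
    from .meshing import Resolution
    res = Resolution(ny_clear=n, wall_refine=1.0, growth=2.0,
                     max_nodes=10**7)
    mesh = generate_mesh(None, channel, res)
    space = Q2Q1Space(mesh)
    n2 = space.n2
    lid = space.nodes_on_edges(mesh.top_edges, "q2")
    others = np.unique(np.concatenate([
        space.nodes_on_edges(mesh.inlet_edges, "q2"),
        space.nodes_on_edges(mesh.outlet_edges, "q2"),
        space.nodes_on_edges(mesh.wetted_edges[:, :2], "q2"),
    ]))
    dmap = {int(i): 1.0 for i in lid}
    for i in others:
        dmap[int(i)] = 0.0
    # regularize the lid corners to the wall value
    for i in lid:
        xy = space.q2_coords[i]
        if xy[0] < 1e-12 or xy[0] > 1 - 1e-12:
            dmap[int(i)] = 0.0
    u_idx = np.array(sorted(dmap), dtype=np.int64)
    u_val = np.array([dmap[i] for i in u_idx])
    vnod = np.unique(np.concatenate([lid, others]))
    dir_idx = np.concatenate([u_idx, n2 + vnod])
    dir_val = np.concatenate([u_val, np.zeros(len(vnod))])
    vel, p, history, ok = solve_navier_stokes(
        space, 1.0 / reynolds, 1.0, dir_idx, dir_val, pin_pressure=True,
        tol=tol, max_iter=max_iter, n_picard=3, relax=0.8, u_scale=1.0)
    if not ok:
        raise ConvergenceError("cavity solve failed", history)
    field = FlowField(mesh, space, vel, p, history, True, 1.0, reynolds,
                      FluidProperties(1.0 / reynolds, 1.0))
    om = field.vorticity_q1()
    K1 = space.stiffness1()
    M1 = space.mass1()
    rhs = M1 @ om
    bnodes = np.unique(np.concatenate([
        space.nodes_on_edges(mesh.top_edges, "q1"),
        space.nodes_on_edges(mesh.inlet_edges, "q1"),
        space.nodes_on_edges(mesh.outlet_edges, "q1"),
        space.nodes_on_edges(mesh.wetted_edges[:, :2], "q1"),
    ]))
    from .fem import apply_dirichlet
    A, b = apply_dirichlet(K1, rhs, bnodes, np.zeros(len(bnodes)))
    psi = spla.spsolve(A, b)
    k = int(np.argmax(np.abs(psi)))
    center = tuple(mesh.nodes[k])
    return field, center, float(psi[k])
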