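"""Transient incompressible Newtonian flow on a planar carotid bifurcation.

Solves the Navier-Stokes and continuity equations

    rho dv/dt + rho (v . grad) v - div(tau) = 0,      div v = 0,
    tau = -p I + 2 mu eps(v),   eps(v) = (grad v + grad v^T) / 2,

with Taylor-Hood (quadratic velocity / linear pressure) triangles, implicit
Euler in time and Picard linearization of the convective term.  Boundary
scheme: parabolic Dirichlet velocity profiles carrying the prescribed mass
flow at the CCA inlet and the ECA outlet, no-slip walls, and a traction-free
("do-nothing") ICA outlet that acts as the zero-pressure reference.  The
per-step Picard iteration stops when the relative velocity increment drops
below ``tol`` (default 1e-4) or after ``max_iter`` (default 150) sweeps.

The mesh is block-structured: the bifurcation geometry's transfinite block
maps are sampled into conforming quadrilateral grids (CCA trunk + two branch
blocks sharing the junction edge) and each quad is split into two triangles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._fem import (
    GAUSS3_1D,
    TriMesh,
    apply_dirichlet,
    assemble_coo,
    build_p2,
    element_geometry,
    p1_basis,
    p2_basis,
    quad_rule,
)
from .boundary_conditions import FluidProps, ParabolicProfile, Waveform
from .synth_data import BifurcationGeometry

logger = logging.getLogger(__name__)

Mesh = TriMesh  # flow meshes are tagged TriMesh instances

_MID_REF = {3: (0.5, 0.0), 4: (0.5, 0.5), 5: (0.0, 0.5)}


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------


def mesh_domain(geom: BifurcationGeometry, h_max: float = 0.16e-3) -> Mesh:
    """Block-structured triangulation of a bifurcation geometry.

    Element circumdiameters are at most ``h_max``; boundary edges are tagged
    inlet / outlet_ica / outlet_eca / wall.  Wall node chains (oriented from
    the inlet toward the outlets) are stored in ``mesh.metadata`` for the
    wall-shear extraction.
    """
    if h_max <= 0:
        raise ValueError("h_max must be positive")
    w_c = geom.widths["cca"]
    f_ica = geom.ica_share
    delta = h_max / np.sqrt(2.0)

    for attempt in range(8):
        ny_ica = max(2, int(np.ceil(f_ica * w_c / delta)))
        ny_eca = max(2, int(np.ceil((1 - f_ica) * w_c / delta)))
        ns_cca = max(2, int(np.ceil(geom.lengths["cca"] / delta)))
        ns = {
            name: max(4, int(np.ceil(geom.lengths[name] / delta)))
            for name in ("ica", "eca")
        }
        mesh = _build_bifurcation_mesh(geom, ns_cca, ny_ica, ny_eca, ns)
        dmax = mesh.circumdiameters().max()
        if dmax <= h_max:
            mesh.h = float(dmax)
            mesh.validate()
            return mesh
        delta *= 0.75
    raise RuntimeError("mesh refinement failed to reach the requested h_max "
                       "(sliver geometry near the junction)")


def _build_bifurcation_mesh(geom, ns_cca, ny_ica, ny_eca, ns_branch) -> Mesh:
    t_apex = geom.y_apex / (geom.widths["cca"] / 2)
    # transverse parameter rows across the CCA: ECA share then ICA share
    t_eca = np.linspace(-1.0, t_apex, ny_eca + 1)
    t_ica = np.linspace(t_apex, 1.0, ny_ica + 1)
    t_all = np.concatenate([t_eca, t_ica[1:]])
    ny = ny_ica + ny_eca

    coords: list[np.ndarray] = []
    node_of: dict[tuple, int] = {}

    def add(key, xy) -> int:
        if key not in node_of:
            node_of[key] = len(coords)
            coords.append(np.asarray(xy, dtype=float))
        return node_of[key]

    # CCA block nodes
    s_cca = np.linspace(0, 1, ns_cca + 1)
    for i, s in enumerate(s_cca):
        for j, t in enumerate(t_all):
            add(("cca", i, j), geom.map_cca(s, t))

    # branch blocks; u=0 column shares the CCA outlet-column nodes
    branch_nodes = {}
    for name, nt, j0 in (("eca", ny_eca, 0), ("ica", ny_ica, ny_eca)):
        nsb = ns_branch[name]
        u_vals = np.linspace(0, 1, nsb + 1)
        tau_vals = np.linspace(-1, 1, nt + 1)
        for i, u in enumerate(u_vals):
            for j, tau in enumerate(tau_vals):
                if i == 0:
                    key = ("cca", ns_cca, j0 + j)
                    add(key, geom.map_cca(1.0, t_all[j0 + j]))
                    branch_nodes[(name, 0, j)] = node_of[key]
                else:
                    branch_nodes[(name, i, j)] = add((name, i, j), geom.map_branch(name, u, tau))

    nodes = np.array(coords)

    tris: list[tuple[int, int, int]] = []

    def quad(n00, n10, n11, n01):
        # split along the shorter diagonal: keeps sheared branch cells from
        # becoming obtuse slivers with inflated circumradii
        d1 = np.linalg.norm(nodes[n11] - nodes[n00])
        d2 = np.linalg.norm(nodes[n10] - nodes[n01])
        if d1 <= d2:
            tris.append((n00, n10, n11))
            tris.append((n00, n11, n01))
        else:
            tris.append((n00, n10, n01))
            tris.append((n10, n11, n01))

    for i in range(ns_cca):
        for j in range(ny):
            quad(node_of[("cca", i, j)], node_of[("cca", i + 1, j)],
                 node_of[("cca", i + 1, j + 1)], node_of[("cca", i, j + 1)])
    for name, nt in (("eca", ny_eca), ("ica", ny_ica)):
        for i in range(ns_branch[name]):
            for j in range(nt):
                quad(branch_nodes[(name, i, j)], branch_nodes[(name, i + 1, j)],
                     branch_nodes[(name, i + 1, j + 1)], branch_nodes[(name, i, j + 1)])

    # boundary tags
    inlet = [(node_of[("cca", 0, j + 1)], node_of[("cca", 0, j)]) for j in range(ny)]
    outlets = {}
    for name, nt in (("eca", ny_eca), ("ica", ny_ica)):
        nsb = ns_branch[name]
        outlets[name] = [
            (branch_nodes[(name, nsb, j)], branch_nodes[(name, nsb, j + 1)])
            for j in range(nt)
        ]
    # ordered wall chains, oriented inlet -> outlet
    chain_bottom = [node_of[("cca", i, 0)] for i in range(ns_cca + 1)] + [
        branch_nodes[("eca", i, 0)] for i in range(1, ns_branch["eca"] + 1)
    ]
    chain_top = [node_of[("cca", i, ny)] for i in range(ns_cca + 1)] + [
        branch_nodes[("ica", i, ny_ica)] for i in range(1, ns_branch["ica"] + 1)
    ]
    chain_div_eca = [branch_nodes[("eca", i, ny_eca)] for i in range(ns_branch["eca"] + 1)]
    chain_div_ica = [branch_nodes[("ica", i, 0)] for i in range(ns_branch["ica"] + 1)]
    chains = [chain_bottom, chain_div_eca, chain_div_ica, chain_top]
    wall = []
    for ch in chains:
        wall.extend(zip(ch[:-1], ch[1:]))

    mesh = Mesh(
        nodes=nodes,
        tris=np.array(tris),
        edge_tags={
            "inlet": np.array(inlet),
            "outlet_ica": np.array(outlets["ica"]),
            "outlet_eca": np.array(outlets["eca"]),
            "wall": np.array(wall),
        },
        metadata={"wall_chains": [np.array(c) for c in chains],
                  "kind": "bifurcation"},
    )
    return mesh


def straight_channel_mesh(length: float, height: float, h_max: float) -> Mesh:
    """Rectangular channel mesh (inlet left, 'outlet_ica' right) used by the
    Poiseuille benchmarks and solver verification tests."""
    nx = max(2, int(np.ceil(length / (h_max / np.sqrt(2)))))
    ny = max(2, int(np.ceil(height / (h_max / np.sqrt(2)))))
    x = np.linspace(0, length, nx + 1)
    y = np.linspace(-height / 2, height / 2, ny + 1)
    idx = lambda i, j: i * (ny + 1) + j
    nodes = np.array([[xi, yj] for xi in x for yj in y])
    tris = []
    for i in range(nx):
        for j in range(ny):
            tris.append((idx(i, j), idx(i + 1, j), idx(i + 1, j + 1)))
            tris.append((idx(i, j), idx(i + 1, j + 1), idx(i, j + 1)))
    inlet = [(idx(0, j + 1), idx(0, j)) for j in range(ny)]
    outlet = [(idx(nx, j), idx(nx, j + 1)) for j in range(ny)]
    bottom = [idx(i, 0) for i in range(nx + 1)]
    top = [idx(i, ny) for i in range(nx + 1)]
    wall = list(zip(bottom[:-1], bottom[1:])) + list(zip(top[:-1], top[1:]))
    mesh = Mesh(
        nodes=nodes,
        tris=np.array(tris),
        edge_tags={
            "inlet": np.array(inlet),
            "outlet_ica": np.array(outlet),
            "wall": np.array(wall),
        },
        metadata={"wall_chains": [np.array(bottom), np.array(top)],
                  "kind": "channel"},
    )
    mesh.h = float(mesh.circumdiameters().max())
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Taylor-Hood spaces and operators
# ---------------------------------------------------------------------------


@dataclass
class _Space:
    mesh: Mesh
    coords: np.ndarray  # P2 node coords
    elems: np.ndarray  # (ne, 6)
    edge_mid: dict
    invJT: np.ndarray
    detJ: np.ndarray
    qp: np.ndarray
    qw: np.ndarray
    N2: np.ndarray  # (nq, 6)
    dN2: np.ndarray  # (nq, 6, 2)
    N1: np.ndarray  # (nq, 3)
    grads: np.ndarray  # (nq, ne, 6, 2) physical P2 gradients
    ediam: np.ndarray  # (ne,) element circumdiameters (SU length scale)

    @property
    def n2(self) -> int:
        return len(self.coords)

    @property
    def nv(self) -> int:
        return len(self.mesh.nodes)


def _make_space(mesh: Mesh) -> _Space:
    coords, elems, edge_mid = build_p2(mesh)
    invJT, detJ = element_geometry(mesh)
    qp, qw = quad_rule(4)
    N2, dN2 = p2_basis(qp)
    N1, _ = p1_basis(qp)
    # physical gradients: grads[q, e, b, :] = invJT[e] @ dN2[q, b]
    grads = np.einsum("eij,qbj->qebi", invJT, dN2)
    return _Space(mesh, coords, elems, edge_mid, invJT, detJ, qp, qw, N2, dN2,
                  N1, grads, mesh.circumdiameters())


def _scatter(space: _Space, local: np.ndarray, cols_conn: np.ndarray, shape) -> sp.csr_matrix:
    rows = np.repeat(space.elems[:, :, None], cols_conn.shape[1], axis=2)
    cols = np.repeat(cols_conn[:, None, :], space.elems.shape[1], axis=1)
    return assemble_coo(rows, cols, local, shape)


def _assemble_constant(space: _Space, mu: float):
    """P2 mass matrix, viscous block matrices and divergence blocks."""
    ne = len(space.elems)
    w = space.qw[:, None] * space.detJ[None, :]  # (nq, ne)
    # mass
    M_loc = np.einsum("qe,qa,qb->eab", w, space.N2, space.N2)
    # viscous blocks
    gx = space.grads[..., 0]  # (nq, ne, 6)
    gy = space.grads[..., 1]
    Kxx = mu * np.einsum("qe,qea,qeb->eab", w, 2 * gx, gx) + mu * np.einsum(
        "qe,qea,qeb->eab", w, gy, gy
    )
    Kyy = mu * np.einsum("qe,qea,qeb->eab", w, 2 * gy, gy) + mu * np.einsum(
        "qe,qea,qeb->eab", w, gx, gx
    )
    Kxy = mu * np.einsum("qe,qea,qeb->eab", w, gy, gx)  # du_y/dx into w_x eq
    Kyx = mu * np.einsum("qe,qea,qeb->eab", w, gx, gy)
    # divergence: D[i, b] = int chi_i dphi_b/dx_comp
    tri_conn = space.elems[:, :3]
    Dx_loc = np.einsum("qe,qi,qeb->eib", w, space.N1, gx)
    Dy_loc = np.einsum("qe,qi,qeb->eib", w, space.N1, gy)

    n2, nv = space.n2, space.nv
    M = _scatter(space, M_loc, space.elems, (n2, n2))
    K = {
        "xx": _scatter(space, Kxx, space.elems, (n2, n2)),
        "xy": _scatter(space, Kxy, space.elems, (n2, n2)),
        "yx": _scatter(space, Kyx, space.elems, (n2, n2)),
        "yy": _scatter(space, Kyy, space.elems, (n2, n2)),
    }
    rows = np.repeat(tri_conn[:, :, None], 6, axis=2)
    cols = np.repeat(space.elems[:, None, :], 3, axis=1)
    Dx = assemble_coo(rows, cols, Dx_loc, (nv, n2))
    Dy = assemble_coo(rows, cols, Dy_loc, (nv, n2))
    return M, K, Dx, Dy


def _assemble_convection(
    space: _Space, rho: float, mu: float, vel: np.ndarray
) -> sp.csr_matrix:
    """Convective operator with streamline-upwind stabilization.

    Galerkin part rho * int psi_a (v* . grad phi_b) plus the SU term
    rho * tau_e * int (v* . grad psi_a)(v* . grad phi_b) with the classic
    doubly-asymptotic tau_e = xi(Pe) h_e / (2 |v*|), xi = min(Pe/3, 1).
    The SU diffusion acts only along streamlines and vanishes with |v*|,
    keeping coarse convection-dominated meshes stable without polluting the
    near-wall shear."""
    v_el = vel[space.elems]  # (ne, 6, 2)
    vq = np.einsum("qb,ebi->qei", space.N2, v_el)  # (nq, ne, 2)
    adv = np.einsum("qei,qebi->qeb", vq, space.grads)  # (nq, ne, 6)
    w = space.qw[:, None] * space.detJ[None, :]
    loc = rho * np.einsum("qe,qa,qeb->eab", w, space.N2, adv)
    # SU stabilization, evaluated with the element-mean advection speed
    speed = np.linalg.norm(vq, axis=2).mean(axis=0)  # (ne,)
    h = space.ediam
    pe = rho * speed * h / (2.0 * mu)
    xi = np.minimum(pe / 3.0, 1.0)
    tau = np.where(speed > 1e-12, xi * h / (2.0 * np.maximum(speed, 1e-12)), 0.0)
    loc += rho * tau[:, None, None] * np.einsum("qe,qea,qeb->eab", w, adv, adv)
    return _scatter(space, loc, space.elems, (space.n2, space.n2))


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------


@dataclass
class DirichletBC:
    """Parabolic velocity profile on a straight tagged boundary carrying a
    prescribed per-unit-depth mass flow.  ``massflow`` is a Waveform, a
    callable t -> kg/s, or a constant.  ``outflow`` flips the direction so
    the flux leaves the domain (ECA outlet treatment)."""

    tag: str
    massflow: Waveform | float | object
    outflow: bool = False

    def rate(self, t: float) -> float:
        if isinstance(self.massflow, Waveform):
            return float(self.massflow(t))
        if callable(self.massflow):
            return float(self.massflow(t))
        return float(self.massflow)


@dataclass
class _BCData:
    nodes: np.ndarray  # P2 node ids on the boundary
    xi: np.ndarray  # transverse offset from the boundary centre
    width: float
    direction: np.ndarray  # unit flow direction (into/out of the domain)

    def values(self, massflow: float, rho: float) -> np.ndarray:
        prof = ParabolicProfile(massflow, self.width, rho)
        mag = prof(self.xi)
        return mag[:, None] * self.direction


def _bc_data(space: _Space, tag: str, outflow: bool) -> _BCData:
    mesh = space.mesh
    edges = mesh.edge_tags[tag]
    ids = set()
    for a, b in edges:
        ids.add(int(a))
        ids.add(int(b))
        ids.add(space.edge_mid[tuple(sorted((int(a), int(b))))])
    ids = np.array(sorted(ids))
    pts = space.coords[ids]
    # straight boundary: principal direction and transverse offsets
    centre = pts.mean(axis=0)
    rel = pts - centre
    tangent = rel[np.argmax(np.linalg.norm(rel, axis=1))]
    tangent = tangent / np.linalg.norm(tangent)
    xi = rel @ tangent
    width = xi.max() - xi.min()
    normal = np.array([-tangent[1], tangent[0]])
    interior = mesh.nodes.mean(axis=0)
    if normal @ (interior - centre) < 0:
        normal = -normal
    if outflow:
        normal = -normal
    return _BCData(ids, xi - 0.5 * (xi.max() + xi.min()), float(width), normal)


# ---------------------------------------------------------------------------
# solutions and wall shear records
# ---------------------------------------------------------------------------


@dataclass
class WallShearRecord:
    """Signed scalar wall shear stress tau_w(s, t) on ordered wall points.

    The sign convention is geometric: positive means the tangential traction
    points in the forward (inlet-to-outlet) direction of the wall chain the
    point belongs to.  ``chain_slices`` maps chain index -> slice into the
    point axis; arc-lengths of consecutive chains are offset so the global
    coordinate is strictly increasing.
    """

    arclengths: np.ndarray  # (np,)
    times: np.ndarray  # (nt,)
    tau: np.ndarray  # (np, nt)
    period: float
    chain_slices: list[slice] = field(default_factory=list)

    def validate(self) -> None:
        if np.any(np.diff(self.arclengths) <= 0):
            raise ValueError("arc-length must be strictly increasing")
        if not np.isfinite(self.tau).all():
            raise ValueError("wall shear contains non-finite values")

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.tau, columns=[f"t={t:.6g}" for t in self.times])
        df.insert(0, "arclength", self.arclengths)
        df.to_csv(path, index=False)


@dataclass
class FlowSolution:
    """Velocity/pressure history over the final simulated cycle plus
    per-cycle wall shear summaries for the earlier cycles."""

    mesh: Mesh
    times: np.ndarray  # final-cycle times [0, T]
    U: np.ndarray  # (nt, n2, 2) velocities at P2 nodes
    P: np.ndarray  # (nt, nv) pressures at vertices
    dt: float
    n_cycles: int
    period: float
    wall_records: list[WallShearRecord]  # one per simulated cycle
    div_residual: float = 0.0
    picard_iters: list[int] = field(default_factory=list)

    def validate(self) -> None:
        if not (np.isfinite(self.U).all() and np.isfinite(self.P).all()):
            raise ValueError("solution fields contain non-finite values")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0]):
            raise ValueError("stored timesteps must be uniformly spaced")


class _WallShearExtractor:
    """Precomputed geometry for evaluating tau_w at wall-edge midpoints."""

    def __init__(self, space: _Space):
        mesh = space.mesh
        edge2el: dict[tuple[int, int], int] = {}
        for e, tri in enumerate(mesh.tris):
            for a, b in ((0, 1), (1, 2), (2, 0)):
                edge2el[tuple(sorted((int(tri[a]), int(tri[b]))))] = e
        pts = []
        els = []
        grads = []
        tangents = []
        normals = []
        arcs = []
        slices = []
        offset = 0.0
        start = 0
        for chain in mesh.metadata["wall_chains"]:
            arc = 0.0
            for a, b in zip(chain[:-1], chain[1:]):
                key = tuple(sorted((int(a), int(b))))
                e = edge2el[key]
                mid_node = space.edge_mid[key]
                local = list(space.elems[e]).index(mid_node)
                ref = np.array([_MID_REF[local]])
                _, dN = p2_basis(ref)
                g = np.einsum("ij,bj->bi", space.invJT[e], dN[0])  # (6,2)
                pa, pb = mesh.nodes[a], mesh.nodes[b]
                tvec = pb - pa
                L = np.linalg.norm(tvec)
                tvec = tvec / L
                # inward normal (pointing into the fluid): tau_w is the
                # traction the fluid exerts ON the wall, positive streamwise
                nvec = np.array([tvec[1], -tvec[0]])
                centroid = mesh.nodes[mesh.tris[e]].mean(axis=0)
                midpt = 0.5 * (pa + pb)
                if nvec @ (centroid - midpt) < 0:
                    nvec = -nvec
                pts.append(midpt)
                els.append(e)
                grads.append(g)
                tangents.append(tvec)
                normals.append(nvec)
                arcs.append(offset + arc + 0.5 * L)
                arc += L
            offset += arc
            slices.append(slice(start, len(pts)))
            start = len(pts)
        self.space = space
        self.elements = np.array(els)
        self.grads = np.array(grads)  # (np, 6, 2)
        self.tangents = np.array(tangents)
        self.normals = np.array(normals)
        self.arclengths = np.array(arcs)
        self.chain_slices = slices
        self.conn = space.elems[self.elements]  # (np, 6)

    def tau_w(self, vel: np.ndarray, mu: float) -> np.ndarray:
        """Signed tau_w at all wall points for one velocity field."""
        v = vel[self.conn]  # (np, 6, 2)
        gradu = np.einsum("pbi,pbj->pij", v, self.grads)  # du_i/dx_j
        eps = 0.5 * (gradu + np.swapaxes(gradu, 1, 2))
        traction = 2.0 * mu * np.einsum("pij,pj->pi", eps, self.normals)
        return np.einsum("pi,pi->p", self.tangents, traction)


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------


def _dirichlet_sets(space: _Space, bcs: list[DirichletBC]):
    wall_ids = set()
    for a, b in space.mesh.edge_tags.get("wall", []):
        wall_ids.add(int(a))
        wall_ids.add(int(b))
        wall_ids.add(space.edge_mid[tuple(sorted((int(a), int(b))))])
    bc_data = [(_bc_data(space, bc.tag, bc.outflow), bc) for bc in bcs]
    for data, _ in bc_data:
        wall_ids -= set(data.nodes.tolist())
    return np.array(sorted(wall_ids)), bc_data


def _bc_arrays(space: _Space, wall_ids, bc_data, t, rho):
    """Velocity Dirichlet dof indices and values at time t."""
    n2 = space.n2
    dofs = [wall_ids, wall_ids + n2]
    vals = [np.zeros(len(wall_ids)), np.zeros(len(wall_ids))]
    for data, bc in bc_data:
        vv = data.values(bc.rate(t), rho)
        dofs.extend([data.nodes, data.nodes + n2])
        vals.extend([vv[:, 0], vv[:, 1]])
    return np.concatenate(dofs), np.concatenate(vals)


def _saddle_solve(A_blocks, Dx, Dy, rhs_u, space, dirichlet):
    """Assemble and solve one linearized saddle-point system."""
    n2, nv = space.n2, space.nv
    Axx, Axy, Ayx, Ayy = A_blocks
    A = sp.bmat(
        [
            [Axx, Axy, -Dx.T],
            [Ayx, Ayy, -Dy.T],
            [Dx, Dy, None],
        ],
        format="csr",
    )
    b = np.concatenate([rhs_u, np.zeros(nv)])
    dofs, vals = dirichlet
    A, b = apply_dirichlet(A, b, dofs, vals)
    x = spla.spsolve(A.tocsc(), b)
    return x[: 2 * n2].reshape(2, n2).T.copy(), x[2 * n2 :]


def _picard_step(space, M, K, Dx, Dy, rho_dt, props, v_guess, rhs_u, dirichlet,
                 tol, max_iter):
    v = v_guess.copy()
    iters = 0
    prev_res = np.inf
    relax = 1.0
    for iters in range(1, max_iter + 1):
        N = _assemble_convection(space, props.density, props.viscosity, v)
        Axx = rho_dt * M + N + K["xx"]
        Ayy = rho_dt * M + N + K["yy"]
        v_new, p = _saddle_solve((Axx, K["xy"], K["yx"], Ayy), Dx, Dy, rhs_u,
                                 space, dirichlet)
        num = np.linalg.norm(v_new - v)
        den = max(np.linalg.norm(v_new), 1e-30)
        res = num / den
        # damp the update when the fixed-point iteration stops contracting
        relax = 0.5 * relax if res > prev_res else min(1.0, 1.5 * relax)
        v = v + relax * (v_new - v)
        prev_res = res
        if res < tol:
            break
    else:
        logger.info("Picard iteration limit reached (residual %.2e)", res)
    return v, p, iters


def solve_transient(
    mesh: Mesh,
    inflow_bc: DirichletBC,
    eca_bc: DirichletBC | None,
    props: FluidProps = FluidProps(),
    dt: float | None = None,
    n_cycles: int = 2,
    tol: float = 1e-4,
    max_iter: int = 150,
    period: float | None = None,
) -> FlowSolution:
    """March the pulsatile flow over ``n_cycles`` cardiac cycles.

    ``dt`` defaults to T/100.  The full field history of the final cycle is
    returned together with one wall-shear record per simulated cycle (the
    periodicity of TAWSS across the last two cycles is the convergence
    diagnostic for the cycle count).
    """
    if period is None:
        if isinstance(inflow_bc.massflow, Waveform):
            period = inflow_bc.massflow.period
        else:
            raise ValueError("period required when the inflow is not a Waveform")
    if dt is None:
        dt = period / 100.0
    n_steps = int(round(period / dt))
    dt = period / n_steps

    space = _make_space(mesh)
    M, K, Dx, Dy = _assemble_constant(space, props.viscosity)
    bcs = [inflow_bc] + ([eca_bc] if eca_bc is not None else [])
    wall_ids, bc_data = _dirichlet_sets(space, bcs)
    extractor = _WallShearExtractor(space)

    n2 = space.n2
    rho_dt = props.density / dt
    v = np.zeros((n2, 2))
    p = np.zeros(space.nv)

    wall_records: list[WallShearRecord] = []
    picard_iters: list[int] = []
    div_res = 0.0
    cfl_warned = False

    U_hist = np.zeros((n_steps + 1, n2, 2))
    P_hist = np.zeros((n_steps + 1, space.nv))
    times = np.arange(n_steps + 1) * dt

    for cycle in range(n_cycles):
        tau_hist = np.zeros((len(extractor.arclengths), n_steps + 1))
        tau_hist[:, 0] = extractor.tau_w(v, props.viscosity)
        if cycle == n_cycles - 1:
            U_hist[0], P_hist[0] = v, p
        for k in range(1, n_steps + 1):
            t = k * dt
            dirichlet = _bc_arrays(space, wall_ids, bc_data, t, props.density)
            rhs = rho_dt * (M @ v)
            rhs_u = np.concatenate([rhs[:, 0], rhs[:, 1]])
            v, p, iters = _picard_step(
                space, M, K, Dx, Dy, rho_dt, props, v, rhs_u, dirichlet, tol, max_iter
            )
            picard_iters.append(iters)
            vmax = np.linalg.norm(v, axis=1).max()
            if not cfl_warned and dt * vmax / mesh.h > 5:
                warnings.warn(
                    f"advective CFL number {dt * vmax / mesh.h:.1f} > 5; "
                    "consider a smaller timestep",
                    stacklevel=2,
                )
                cfl_warned = True
            div = np.abs(Dx @ v[:, 0] + Dy @ v[:, 1]).max()
            scale = max(np.linalg.norm(v, axis=1).max(), 1e-30) * mesh.h
            div_res = max(div_res, div / scale)
            tau_hist[:, k] = extractor.tau_w(v, props.viscosity)
            if cycle == n_cycles - 1:
                U_hist[k], P_hist[k] = v, p
        wall_records.append(
            WallShearRecord(
                extractor.arclengths.copy(), times.copy(), tau_hist, period,
                list(extractor.chain_slices),
            )
        )

    sol = FlowSolution(
        mesh, times, U_hist, P_hist, dt, n_cycles, period, wall_records,
        div_residual=float(div_res), picard_iters=picard_iters,
    )
    sol.validate()
    return sol


def solve_steady(
    mesh: Mesh,
    inflow_bc: DirichletBC,
    eca_bc: DirichletBC | None = None,
    props: FluidProps = FluidProps(),
    tol: float = 1e-4,
    max_iter: int = 150,
) -> tuple[np.ndarray, np.ndarray, _Space]:
    """Steady-state Picard solve (no mass term); returns (v, p, space)."""
    space = _make_space(mesh)
    _, K, Dx, Dy = _assemble_constant(space, props.viscosity)
    bcs = [inflow_bc] + ([eca_bc] if eca_bc is not None else [])
    wall_ids, bc_data = _dirichlet_sets(space, bcs)
    dirichlet = _bc_arrays(space, wall_ids, bc_data, 0.0, props.density)
    v = np.zeros((space.n2, 2))
    rhs_u = np.zeros(2 * space.n2)
    M = sp.csr_matrix((space.n2, space.n2))
    v, p, _ = _picard_step(space, M, K, Dx, Dy, 0.0, props, v, rhs_u, dirichlet,
                           tol, max_iter)
    return v, p, space


def wall_shear_series(sol: FlowSolution, mesh: Mesh | None = None) -> WallShearRecord:
    """Wall shear record of the final simulated cycle."""
    if mesh is not None and mesh is not sol.mesh:
        raise ValueError("solution and mesh are inconsistent")
    rec = sol.wall_records[-1]
    rec.validate()
    return rec


def boundary_pressure_series(sol: FlowSolution, mesh: Mesh | None = None) -> dict[str, np.ndarray]:
    """Edge-length-averaged gauge pressure trace per tagged boundary."""
    mesh = sol.mesh
    out = {}
    for tag, edges in mesh.edge_tags.items():
        L = np.linalg.norm(mesh.nodes[edges[:, 1]] - mesh.nodes[edges[:, 0]], axis=1)
        p_edge = 0.5 * (sol.P[:, edges[:, 0]] + sol.P[:, edges[:, 1]])  # (nt, ne)
        out[tag] = (p_edge * L).sum(axis=1) / L.sum()
    return out


def boundary_flux(space: _Space, v: np.ndarray, tag: str) -> float:
    """Outward volume flux int v . n ds across a tagged boundary."""
    mesh = space.mesh
    xi, wq = GAUSS3_1D
    from ._fem import p2_edge_basis

    Nq, _ = p2_edge_basis(xi)
    total = 0.0
    interior = mesh.nodes.mean(axis=0)
    for a, b in mesh.edge_tags[tag]:
        a, b = int(a), int(b)
        mid = space.edge_mid[tuple(sorted((a, b)))]
        ids = [a, b, mid]
        pa, pb = mesh.nodes[a], mesh.nodes[b]
        tvec = pb - pa
        L = np.linalg.norm(tvec)
        nvec = np.array([tvec[1], -tvec[0]]) / L
        midpt = 0.5 * (pa + pb)
        if nvec @ (interior - midpt) > 0:
            nvec = -nvec
        vals = v[ids]  # (3, 2)
        vn = (Nq @ vals) @ nvec
        total += float((vn * wq).sum() * L / 2)
    return total


def make_space(mesh: Mesh) -> _Space:
    """Public accessor for the Taylor-Hood space (used by flux checks)."""
    return _make_space(mesh)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_vtk(path, mesh: Mesh, point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy-ASCII VTK export of a triangle mesh with optional fields
    (vertex-based; P2 fields should be restricted to vertices first)."""
    lines = ["# vtk DataFile Version 3.0", "carotidrisk mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID"]
    nv = len(mesh.nodes)
    lines.append(f"POINTS {nv} double")
    lines.extend(f"{x:.9g} {y:.9g} 0" for x, y in mesh.nodes)
    ne = len(mesh.tris)
    lines.append(f"CELLS {ne} {4 * ne}")
    lines.extend(f"3 {a} {b} {c}" for a, b, c in mesh.tris)
    lines.append(f"CELL_TYPES {ne}")
    lines.extend("5" for _ in range(ne))
    if point_data:
        lines.append(f"POINT_DATA {nv}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.9g} {v[1]:.9g} 0" for v in arr)
    if cell_data:
        lines.append(f"CELL_DATA {ne}")
        for name, arr in cell_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9g}" for v in np.asarray(arr))
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
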