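"""Shared finite-element kernels on triangular meshes.

Provides quadratic (P2) and linear (P1) Lagrange bases on the reference
triangle, Dunavant quadrature, P2 node construction from a vertex/triangle
mesh, and small sparse-assembly helpers.  The transient flow solver uses the
Taylor-Hood P2/P1 pair; the hyperelastic solver uses P2 displacements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

# ---------------------------------------------------------------------------
# quadrature on the reference triangle {(x,y): x,y>=0, x+y<=1}
# ---------------------------------------------------------------------------

# Dunavant rules; weights sum to 1/2 (reference-triangle area).
_QUAD_RULES = {
    1: (np.array([[1 / 3, 1 / 3]]), np.array([0.5])),
    2: (
        np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]]),
        np.full(3, 1 / 6),
    ),
    # degree-5, 7-point rule
    5: (
        np.array(
            [
                [1 / 3, 1 / 3],
                [0.0597158717, 0.4701420641],
                [0.4701420641, 0.0597158717],
                [0.4701420641, 0.4701420641],
                [0.7974269853, 0.1012865073],
                [0.1012865073, 0.7974269853],
                [0.1012865073, 0.1012865073],
            ]
        ),
        np.array(
            [
                0.1125,
                0.0661970764,
                0.0661970764,
                0.0661970764,
                0.0629695903,
                0.0629695903,
                0.0629695903,
            ]
        ),
    ),
}


def quad_rule(degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (points, weights) integrating polynomials of ``degree`` exactly."""
    for d in sorted(_QUAD_RULES):
        if d >= degree:
            return _QUAD_RULES[d]
    return _QUAD_RULES[5]


# ---------------------------------------------------------------------------
# shape functions
# ---------------------------------------------------------------------------


def p1_basis(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P1 basis at reference points ``pts`` (n,2) -> (N (n,3), dN (3,2))."""
    x, y = pts[:, 0], pts[:, 1]
    N = np.stack([1 - x - y, x, y], axis=1)
    dN = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    return N, dN


def p2_basis(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P2 basis at reference points ``pts`` (n,2).

    Node ordering: vertices 0,1,2 then midpoints of edges (0,1), (1,2), (2,0).
    Returns (N (n,6), dN (n,6,2)).
    """
    x, y = pts[:, 0], pts[:, 1]
    l1 = 1 - x - y
    l2 = x
    l3 = y
    N = np.stack(
        [
            l1 * (2 * l1 - 1),
            l2 * (2 * l2 - 1),
            l3 * (2 * l3 - 1),
            4 * l1 * l2,
            4 * l2 * l3,
            4 * l3 * l1,
        ],
        axis=1,
    )
    # derivatives wrt (x, y); dl1 = (-1,-1)
    z = np.zeros_like(x)
    dN = np.stack(
        [
            np.stack([-(4 * l1 - 1), -(4 * l1 - 1)], axis=1),
            np.stack([4 * l2 - 1, z], axis=1),
            np.stack([z, 4 * l3 - 1], axis=1),
            np.stack([4 * (l1 - l2), -4 * l2], axis=1),
            np.stack([4 * l3, 4 * l2], axis=1),
            np.stack([-4 * l3, 4 * (l1 - l3)], axis=1),
        ],
        axis=1,
    )
    return N, dN


# 1D quadratic basis on [-1, 1] for boundary-edge integrals (3-node edges).
def p2_edge_basis(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic edge basis at points xi in [-1,1]; nodes (-1, +1, 0)."""
    N = np.stack([0.5 * xi * (xi - 1), 0.5 * xi * (xi + 1), 1 - xi**2], axis=1)
    dN = np.stack([xi - 0.5, xi + 0.5, -2 * xi], axis=1)
    return N, dN


GAUSS3_1D = (
    np.array([-np.sqrt(3 / 5), 0.0, np.sqrt(3 / 5)]),
    np.array([5 / 9, 8 / 9, 5 / 9]),
)


# ---------------------------------------------------------------------------
# mesh container
# ---------------------------------------------------------------------------


@dataclass
class TriMesh:
    """Triangular mesh with tagged boundary edges and optional region tags.

    ``edge_tags`` maps a tag name to an (m, 2) array of vertex-index pairs;
    every boundary edge must carry exactly one tag.  ``regions`` (optional)
    assigns an integer region id per triangle, with names in ``region_names``.
    """

    nodes: np.ndarray  # (nv, 2) coordinates, metres
    tris: np.ndarray  # (ne, 3) vertex indices, CCW
    edge_tags: dict[str, np.ndarray] = field(default_factory=dict)
    h: float = 0.0  # characteristic element size
    regions: np.ndarray | None = None
    region_names: dict[int, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tris = np.asarray(self.tris, dtype=np.int64)
        self.fix_orientation()

    # -- geometry -----------------------------------------------------------
    def signed_areas(self) -> np.ndarray:
        p = self.nodes[self.tris]
        u = p[:, 1] - p[:, 0]
        v = p[:, 2] - p[:, 0]
        return 0.5 * (u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])

    def fix_orientation(self) -> None:
        neg = self.signed_areas() < 0
        if np.any(neg):
            self.tris[neg] = self.tris[neg][:, [0, 2, 1]]

    def circumdiameters(self) -> np.ndarray:
        p = self.nodes[self.tris]
        a = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
        b = np.linalg.norm(p[:, 2] - p[:, 1], axis=1)
        c = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
        area = np.abs(self.signed_areas())
        return a * b * c / (2.0 * area)

    # -- topology -----------------------------------------------------------
    def boundary_edges(self) -> np.ndarray:
        """All edges belonging to exactly one triangle, as sorted vertex pairs."""
        e = np.concatenate(
            [self.tris[:, [0, 1]], self.tris[:, [1, 2]], self.tris[:, [2, 0]]]
        )
        e_sorted = np.sort(e, axis=1)
        uniq, counts = np.unique(e_sorted, axis=0, return_counts=True)
        return uniq[counts == 1]

    def validate(self) -> None:
        if np.any(self.signed_areas() <= 0):
            raise ValueError("mesh contains degenerate or inverted elements")
        bdry = {tuple(e) for e in self.boundary_edges()}
        tagged: list[tuple[int, int]] = []
        for t, edges in self.edge_tags.items():
            for e in edges:
                key = tuple(sorted(map(int, e)))
                if key not in bdry:
                    raise ValueError(f"edge {key} tagged '{t}' is not a boundary edge")
                tagged.append(key)
        if len(tagged) != len(set(tagged)):
            raise ValueError("a boundary edge carries more than one tag")
        if set(tagged) != bdry:
            missing = bdry - set(tagged)
            raise ValueError(f"{len(missing)} untagged boundary edge(s), e.g. {next(iter(missing))}")


def build_p2(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray, dict[tuple[int, int], int]]:
    """Construct P2 nodes for a TriMesh.

    Returns (coords (n2,2) with vertex nodes first, elems (ne,6) P2
    connectivity, edge_mid mapping sorted vertex pair -> midpoint node id).
    """
    nv = len(mesh.nodes)
    edges = np.concatenate(
        [mesh.tris[:, [0, 1]], mesh.tris[:, [1, 2]], mesh.tris[:, [2, 0]]]
    )
    e_sorted = np.sort(edges, axis=1)
    uniq, inv = np.unique(e_sorted, axis=0, return_inverse=True)
    mid_ids = nv + np.arange(len(uniq))
    mids = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])
    coords = np.vstack([mesh.nodes, mids])
    ne = len(mesh.tris)
    elems = np.empty((ne, 6), dtype=np.int64)
    elems[:, :3] = mesh.tris
    elems[:, 3] = mid_ids[inv[:ne]]
    elems[:, 4] = mid_ids[inv[ne : 2 * ne]]
    elems[:, 5] = mid_ids[inv[2 * ne :]]
    edge_mid = {tuple(map(int, uniq[i])): int(mid_ids[i]) for i in range(len(uniq))}
    return coords, elems, edge_mid


def element_geometry(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-element Jacobian inverse-transpose (ne,2,2) and |detJ| (ne,)."""
    p = mesh.nodes[mesh.tris]
    J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)  # dx/dxi columns
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    invJT = np.empty_like(J)
    invJT[:, 0, 0] = J[:, 1, 1]
    invJT[:, 0, 1] = -J[:, 1, 0]
    invJT[:, 1, 0] = -J[:, 0, 1]
    invJT[:, 1, 1] = J[:, 0, 0]
    invJT /= detJ[:, None, None]
    return invJT, np.abs(detJ)


def assemble_coo(rows: np.ndarray, cols: np.ndarray, vals: np.ndarray, shape) -> sp.csr_matrix:
    return sp.coo_matrix((vals.ravel(), (rows.ravel(), cols.ravel())), shape=shape).tocsr()


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, dofs: np.ndarray, vals: np.ndarray):
    """Impose A[dofs] = vals by symmetric elimination; returns (A, b) modified."""
    dofs = np.asarray(dofs, dtype=np.int64)
    vals = np.asarray(vals, dtype=float)
    n = A.shape[0]
    free = np.ones(n)
    free[dofs] = 0.0
    x0 = np.zeros(n)
    x0[dofs] = vals
    P = sp.diags(free)
    D = sp.diags(1.0 - free)
    b = P @ (b - A @ x0)
    b[dofs] = vals
    A = (P @ A @ P + D).tocsr()
    return A, b
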