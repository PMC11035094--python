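"""Masked Cartesian grids as oriented 2D cubical complexes, with DEC operators.

The domain is the union of the closed *active* faces of a regular Cartesian
grid (a cubical complex).  Discrete differential k-forms are cochains: one
scalar per active k-cell.  The exterior derivative ``d`` is a signed incidence
matrix, the Hodge star a diagonal matrix of dual/primal measure ratios, and
the codifferential is assembled as ``delta_k = star_{k-1}^{-1} d_{k-1}^T star_k``
so that ``<d f, g> = <f, delta g>`` holds exactly for interior-supported forms.

Orientation conventions: x-edges point +x, y-edges point +y, faces are
oriented counterclockwise.  Cell index maps are row-major by (j, i) — the
y index varies slowest — with all x-edges preceding all y-edges in the
1-cochain ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


class EmptyDomainError(ValueError):
    """Raised when a face mask activates no face at all."""


@dataclass(frozen=True)
class CartesianGrid:
    """A regular 2D vertex grid.

    Parameters
    ----------
    origin : (2,) float
        Position of vertex (0, 0) in embedding units.
    spacing : (2,) float
        Strictly positive grid step per axis (hx, hy).
    counts : (2,) int
        Number of vertices per axis (nx, ny); both at least 2.
    """

    origin: tuple[float, float]
    spacing: tuple[float, float]
    counts: tuple[int, int]

    def __post_init__(self):
        hx, hy = self.spacing
        nx, ny = self.counts
        if not (hx > 0 and hy > 0):
            raise ValueError("grid spacing must be positive on both axes")
        if nx < 2 or ny < 2:
            raise ValueError("grid needs at least 2 vertices per axis")

    @property
    def n_faces(self) -> tuple[int, int]:
        return (self.counts[0] - 1, self.counts[1] - 1)

    def vertex_positions(self) -> np.ndarray:
        """All vertex coordinates, shape (ny, nx, 2)."""
        nx, ny = self.counts
        xs = self.origin[0] + self.spacing[0] * np.arange(nx)
        ys = self.origin[1] + self.spacing[1] * np.arange(ny)
        X, Y = np.meshgrid(xs, ys)  # shape (ny, nx)
        return np.stack([X, Y], axis=-1)


def _compress(active_flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map a boolean flat array to (active indices, full->compressed map with -1)."""
    idx = np.flatnonzero(active_flat)
    inv = np.full(active_flat.size, -1, dtype=np.int64)
    inv[idx] = np.arange(idx.size)
    return idx, inv


class GridComplex:
    """Oriented cubical complex on a Cartesian grid restricted by a face mask.

    2D boolean arrays are indexed ``[j, i]`` (y row, x column) so that C-order
    flattening yields the row-major-by-(j, i) cell ordering.

    Attributes
    ----------
    grid : CartesianGrid
    face_mask : (ny-1, nx-1) bool
        Active faces.
    n_vertices, n_edges, n_faces : int
        Counts of active cells; ``n_edges = n_xedges + n_yedges``.
    vertex_boundary, edge_boundary, face_boundary : bool arrays (compressed)
        Boundary flags per active cell.  A vertex/edge is boundary iff it has
        fewer than 4/2 incident active faces; a face is boundary iff one of
        its four edges is a boundary edge.
    """

    def __init__(self, grid: CartesianGrid, face_mask: np.ndarray):
        face_mask = np.asarray(face_mask, dtype=bool)
        nx, ny = grid.counts
        if face_mask.shape != (ny - 1, nx - 1):
            raise ValueError(
                f"face_mask shape {face_mask.shape} != expected {(ny - 1, nx - 1)}"
            )
        if not face_mask.any():
            raise EmptyDomainError("empty domain: no active face")
        self.grid = grid
        self.face_mask = face_mask

        # Incident-active-face counts per cell, via zero-padded mask.
        pad = np.zeros((ny + 1, nx + 1), dtype=np.int8)
        pad[1:ny, 1:nx] = face_mask
        # vertex (i, j): faces [j-1..j, i-1..i]
        self._vert_nfaces = pad[:ny, :nx] + pad[1:, :nx] + pad[:ny, 1:] + pad[1:, 1:]
        # x-edge (i, j), j in [0, ny): faces [j-1, i] and [j, i]
        self._xedge_nfaces = pad[:ny, 1:nx] + pad[1:, 1:nx]  # shape (ny, nx-1)
        # y-edge (i, j), j in [0, ny-1): faces [j, i-1] and [j, i]
        self._yedge_nfaces = pad[1:ny, :nx] + pad[1:ny, 1:]  # shape (ny-1, nx)

        self._vert_idx, self._vert_inv = _compress((self._vert_nfaces > 0).ravel())
        self._xedge_idx, self._xedge_inv = _compress((self._xedge_nfaces > 0).ravel())
        self._yedge_idx, self._yedge_inv = _compress((self._yedge_nfaces > 0).ravel())
        self._face_idx, self._face_inv = _compress(face_mask.ravel())

        self.n_vertices = self._vert_idx.size
        self.n_xedges = self._xedge_idx.size
        self.n_yedges = self._yedge_idx.size
        self.n_edges = self.n_xedges + self.n_yedges
        self.n_faces = self._face_idx.size

        self.vertex_boundary = self._vert_nfaces.ravel()[self._vert_idx] < 4
        self.edge_boundary = np.concatenate(
            [
                self._xedge_nfaces.ravel()[self._xedge_idx] < 2,
                self._yedge_nfaces.ravel()[self._yedge_idx] < 2,
            ]
        )
        # face is boundary iff any of its 4 neighbours across an edge is inactive
        nb = np.zeros((ny + 1, nx + 1), dtype=bool)
        nb[1:ny, 1:nx] = face_mask
        fj, fi = np.nonzero(face_mask)
        neighbours = (
            nb[fj, fi + 1].astype(int)      # south (j-1, i)
            + nb[fj + 2, fi + 1]            # north (j+1, i)
            + nb[fj + 1, fi]                # west  (j, i-1)
            + nb[fj + 1, fi + 2]            # east  (j, i+1)
        )
        self.face_boundary = np.zeros(self.n_faces, dtype=bool)
        self.face_boundary[self._face_inv[fj * (nx - 1) + fi]] = neighbours < 4

        self._d = {}
        self._star = {}

    # ---- coordinates -----------------------------------------------------

    def vertex_coords(self) -> np.ndarray:
        """Coordinates of active vertices, shape (n_vertices, 2)."""
        pos = self.grid.vertex_positions().reshape(-1, 2)
        return pos[self._vert_idx]

    def vertex_ij(self) -> np.ndarray:
        """(i, j) grid indices of active vertices, shape (n_vertices, 2)."""
        nx = self.grid.counts[0]
        j, i = np.divmod(self._vert_idx, nx)
        return np.column_stack([i, j])

    def face_centers(self) -> np.ndarray:
        nx, _ = self.grid.counts
        j, i = np.divmod(self._face_idx, nx - 1)
        ox, oy = self.grid.origin
        hx, hy = self.grid.spacing
        return np.column_stack([ox + (i + 0.5) * hx, oy + (j + 0.5) * hy])

    def edge_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Compressed (tail, head) vertex indices per active edge (x then y)."""
        nx, _ = self.grid.counts
        ej, ei = np.divmod(self._xedge_idx, nx - 1)
        tail_x = self._vert_inv[ej * nx + ei]
        head_x = self._vert_inv[ej * nx + ei + 1]
        ej, ei = np.divmod(self._yedge_idx, nx)
        tail_y = self._vert_inv[ej * nx + ei]
        head_y = self._vert_inv[(ej + 1) * nx + ei]
        return (
            np.concatenate([tail_x, tail_y]),
            np.concatenate([head_x, head_y]),
        )

    def face_corner_vertices(self) -> np.ndarray:
        """Compressed vertex indices of face corners in CCW order, shape (n_faces, 4)."""
        nx, _ = self.grid.counts
        fj, fi = np.divmod(self._face_idx, nx - 1)
        v00 = self._vert_inv[fj * nx + fi]
        v10 = self._vert_inv[fj * nx + fi + 1]
        v11 = self._vert_inv[(fj + 1) * nx + fi + 1]
        v01 = self._vert_inv[(fj + 1) * nx + fi]
        return np.column_stack([v00, v10, v11, v01])

    # ---- operators -------------------------------------------------------

    def exterior_derivative(self, k: int) -> sp.csr_matrix:
        """Signed incidence operator d_k mapping k-cochains to (k+1)-cochains."""
        if k not in (0, 1):
            raise ValueError(f"exterior derivative defined for k in {{0, 1}}, got {k}")
        if k in self._d:
            return self._d[k]
        nx, ny = self.grid.counts
        if k == 0:
            # x-edge (i, j): -vertex(i, j) + vertex(i+1, j)
            ej, ei = np.divmod(self._xedge_idx, nx - 1)
            tail_x = self._vert_inv[ej * nx + ei]
            head_x = self._vert_inv[ej * nx + ei + 1]
            # y-edge (i, j): -vertex(i, j) + vertex(i, j+1)
            ej, ei = np.divmod(self._yedge_idx, nx)
            tail_y = self._vert_inv[ej * nx + ei]
            head_y = self._vert_inv[(ej + 1) * nx + ei]
            rows = np.repeat(np.arange(self.n_edges), 2)
            cols = np.empty(2 * self.n_edges, dtype=np.int64)
            cols[0::2] = np.concatenate([tail_x, tail_y])
            cols[1::2] = np.concatenate([head_x, head_y])
            data = np.tile(np.array([-1.0, 1.0]), self.n_edges)
            mat = sp.csr_matrix(
                (data, (rows, cols)), shape=(self.n_edges, self.n_vertices)
            )
        else:
            # face (i, j) ccw: +bottom x(i,j) +right y(i+1,j) -top x(i,j+1) -left y(i,j)
            fj, fi = np.divmod(self._face_idx, nx - 1)
            bottom = self._xedge_inv[fj * (nx - 1) + fi]
            top = self._xedge_inv[(fj + 1) * (nx - 1) + fi]
            left = self._yedge_inv[fj * nx + fi] + 0  # compressed y index
            right = self._yedge_inv[fj * nx + fi + 1]
            left = left + self.n_xedges
            right = right + self.n_xedges
            rows = np.repeat(np.arange(self.n_faces), 4)
            cols = np.column_stack([bottom, right, top, left]).ravel()
            data = np.tile(np.array([1.0, 1.0, -1.0, -1.0]), self.n_faces)
            mat = sp.csr_matrix(
                (data, (rows, cols)), shape=(self.n_faces, self.n_edges)
            )
        self._d[k] = mat
        return mat

    def hodge_star(self, k: int, dual_clip: bool = True) -> sp.dia_matrix:
        """Diagonal Hodge star on k-cochains: dual-cell / primal-cell measure.

        With ``dual_clip`` (default) dual cells are intersected with the active
        region, so boundary vertices get half/quarter dual areas and boundary
        edges half dual lengths; the star stays strictly positive either way.
        """
        if k not in (0, 1, 2):
            raise ValueError(f"hodge star defined for k in {{0, 1, 2}}, got {k}")
        key = (k, dual_clip)
        if key in self._star:
            return self._star[key]
        hx, hy = self.grid.spacing
        if k == 0:
            if dual_clip:
                diag = self._vert_nfaces.ravel()[self._vert_idx] * (hx * hy / 4.0)
            else:
                diag = np.full(self.n_vertices, hx * hy)
        elif k == 1:
            if dual_clip:
                nx_faces = self._xedge_nfaces.ravel()[self._xedge_idx]
                ny_faces = self._yedge_nfaces.ravel()[self._yedge_idx]
                diag = np.concatenate(
                    [nx_faces * (hy / 2.0) / hx, ny_faces * (hx / 2.0) / hy]
                )
            else:
                diag = np.concatenate(
                    [np.full(self.n_xedges, hy / hx), np.full(self.n_yedges, hx / hy)]
                )
        else:
            diag = np.full(self.n_faces, 1.0 / (hx * hy))
        mat = sp.diags(diag.astype(float))
        self._star[key] = mat
        return mat

    def codifferential(self, k: int, dual_clip: bool = True) -> sp.csr_matrix:
        """delta_k = star_{k-1}^{-1} d_{k-1}^T star_k, mapping k- to (k-1)-cochains.

        The sign is fixed by discrete adjointness ``<d f, g> = <f, delta g>``
        (with this convention delta on 1-cochains is minus the divergence).
        ``delta_1 delta_2 = 0`` follows from ``d_1 d_0 = 0``.
        """
        if k not in (1, 2):
            raise ValueError(f"codifferential defined for k in {{1, 2}}, got {k}")
        d = self.exterior_derivative(k - 1)
        star_k = self.hodge_star(k, dual_clip)
        star_km1 = self.hodge_star(k - 1, dual_clip)
        inv = sp.diags(1.0 / star_km1.diagonal())
        return (inv @ d.T @ star_k).tocsr()

    def n_cells(self, k: int) -> int:
        return {0: self.n_vertices, 1: self.n_edges, 2: self.n_faces}[k]


@dataclass
class Cochain:
    """A discrete differential k-form: one value per active k-cell.

    Values follow the complex's deterministic cell ordering (row-major by
    (j, i); x-edges before y-edges for k = 1).
    """

    degree: int
    values: np.ndarray
    complex: GridComplex = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.degree not in (0, 1, 2):
            raise ValueError("cochain degree must be 0, 1 or 2")
        if self.values.shape != (self.complex.n_cells(self.degree),):
            raise ValueError(
                f"cochain length {self.values.shape} does not match "
                f"{self.complex.n_cells(self.degree)} active {self.degree}-cells"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cochain values must be finite")

    def norm(self, dual_clip: bool = True) -> float:
        return float(np.sqrt(max(inner_product(self, self, dual_clip), 0.0)))


@dataclass(frozen=True)
class DomainTopology:
    """Betti numbers of the active domain (b2 = 0 for a 2D complex with boundary)."""

    b0: int
    b1: int
    euler_characteristic: int


def build_complex(grid: CartesianGrid, face_mask: np.ndarray) -> GridComplex:
    """Build the oriented cubical complex of the masked grid."""
    return GridComplex(grid, face_mask)


def exterior_derivative(complex: GridComplex, k: int) -> sp.csr_matrix:
    return complex.exterior_derivative(k)


def hodge_star(complex: GridComplex, k: int, dual_clip: bool = True) -> sp.dia_matrix:
    return complex.hodge_star(k, dual_clip)


def codifferential(complex: GridComplex, k: int, dual_clip: bool = True) -> sp.csr_matrix:
    return complex.codifferential(k, dual_clip)


def inner_product(a: Cochain, b: Cochain, dual_clip: bool = True) -> float:
    """Hodge L2 inner product <a, b> = a^T star_k b of two equal-degree cochains."""
    if a.degree != b.degree:
        raise ValueError(f"degree mismatch: {a.degree} vs {b.degree}")
    if a.complex is not b.complex:
        raise ValueError("cochains live on different complexes")
    star = a.complex.hodge_star(a.degree, dual_clip)
    return float(a.values @ (star.diagonal() * b.values))


def compute_topology(complex: GridComplex) -> DomainTopology:
    """Betti numbers from face-adjacency components and the Euler characteristic.

    b0 counts connected components of the face adjacency graph (faces sharing
    an edge); chi = V - E + F over active cells; b1 = b0 - chi.
    """
    nx, _ = complex.grid.counts
    fj, fi = np.divmod(complex._face_idx, nx - 1)
    # adjacency across shared edges: east and north neighbours
    rows, cols = [], []
    for dj, di in ((0, 1), (1, 0)):
        nj, ni = fj + dj, fi + di
        valid = (ni < nx - 1) & (nj < complex.grid.counts[1] - 1)
        nbr = np.full(fj.shape, -1, dtype=np.int64)
        nbr[valid] = complex._face_inv[nj[valid] * (nx - 1) + ni[valid]]
        ok = nbr >= 0
        rows.append(np.arange(complex.n_faces)[ok])
        cols.append(nbr[ok])
    adj = sp.coo_matrix(
        (np.ones(sum(r.size for r in rows)), (np.concatenate(rows), np.concatenate(cols))),
        shape=(complex.n_faces, complex.n_faces),
    )
    b0, _ = connected_components(adj, directed=False)
    chi = complex.n_vertices - complex.n_edges + complex.n_faces
    return DomainTopology(b0=int(b0), b1=int(b0 - chi), euler_characteristic=int(chi))
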