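"""Voxel-based hexahedral micro-FE: model building, posture load cases, solve.

One trilinear 8-node hexahedral element per labelled voxel, small-strain
isotropic linear elasticity (bone 10 GPa, cartilage 10 MPa, ν = 0.3), the
proximal face fully constrained, and six posture load cases (−75°…+75°,
100 N resultant distributed over a 40°×30° spherical rectangle of the
cartilage surface).  Strain energy densities are evaluated at element
centroids.

Units are mm / N / MPa throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import linalg as spla

from .errors import InvalidArgumentError, LoadAreaError, SolverError
from .imaging import JointCoordinateSystem, LabeledModelImage
from .voxel import VoxelImage

__all__ = [
    "DEFAULT_MATERIALS",
    "LOAD_CASE_ANGLES_DEG",
    "FEModel",
    "LoadCase",
    "SEDField",
    "element_stiffness",
    "elasticity_matrix",
    "build_model",
    "make_load_case",
    "solve",
    "run_all_load_cases",
    "save_sed_fields",
    "load_sed_fields",
]

#: elastic modulus (MPa) and Poisson ratio per label (1 = bone, 2 = cartilage)
DEFAULT_MATERIALS: dict[int, tuple[float, float]] = {
    1: (10_000.0, 0.3),
    2: (10.0, 0.3),
}

#: the six posture load-case angles, ordered by increasing flexion angle
LOAD_CASE_ANGLES_DEG: tuple[float, ...] = (-75.0, -45.0, -15.0, 15.0, 45.0, 75.0)

# local node offsets (lexicographic in x, y, z) shared by stiffness matrix
# and element connectivity
_OFFSETS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
     [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]],
    dtype=np.int64,
)
_SIGNS = 2.0 * _OFFSETS - 1.0  # natural coordinates of the nodes

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

#: free-DOF count above which the direct factorization is abandoned for CG
#: (SuperLU fill-in grows steeply on 3-D elasticity graphs)
DIRECT_SOLVE_MAX_DOF = 30_000


def elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """Isotropic 6×6 elasticity matrix in Voigt notation (engineering shear)."""
    if E <= 0:
        raise InvalidArgumentError("elastic modulus must be positive")
    if not 0 <= nu < 0.5:
        raise InvalidArgumentError("Poisson ratio must lie in [0, 0.5)")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    g = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] = lam + 2 * g
    C[np.arange(3, 6), np.arange(3, 6)] = g
    return C


def _shape_gradients(xi: np.ndarray, h_mm: float) -> np.ndarray:
    """d N_a / d x_d at natural point ``xi`` for a cube of side ``h`` (8×3)."""
    grads = np.empty((8, 3))
    for a in range(8):
        s = _SIGNS[a]
        for d in range(3):
            g = s[d] / 2.0
            for o in range(3):
                if o != d:
                    g *= (1 + s[o] * xi[o]) / 2.0
            grads[a, d] = g * 2.0 / h_mm  # chain rule: dxi/dx = 2/h
    return grads


def _b_matrix(xi: np.ndarray, h_mm: float) -> np.ndarray:
    """Strain-displacement matrix (6×24) at natural point ``xi``."""
    dN = _shape_gradients(xi, h_mm)
    B = np.zeros((6, 24))
    for a in range(8):
        dx, dy, dz = dN[a]
        c = 3 * a
        B[0, c] = dx
        B[1, c + 1] = dy
        B[2, c + 2] = dz
        B[3, c] = dy
        B[3, c + 1] = dx
        B[4, c + 1] = dz
        B[4, c + 2] = dy
        B[5, c] = dz
        B[5, c + 2] = dx
    return B


def element_stiffness(E: float, nu: float, h_mm: float, n_gauss: int = 2) -> np.ndarray:
    """24×24 stiffness matrix of a cubic trilinear hexahedron.

    Full Gauss integration (``n_gauss`` points per axis, default 2×2×2).
    The matrix is symmetric positive semidefinite with a 6-dimensional
    rigid-body null space and scales linearly in ``E``.
    """
    if h_mm <= 0:
        raise InvalidArgumentError("element side length must be positive")
    C = elasticity_matrix(E, nu)
    pts, wts = np.polynomial.legendre.leggauss(n_gauss)
    detJ = (h_mm / 2.0) ** 3
    K = np.zeros((24, 24))
    for i, wx in zip(pts, wts, strict=True):
        for j, wy in zip(pts, wts, strict=True):
            for k, wz in zip(pts, wts, strict=True):
                B = _b_matrix(np.array([i, j, k]), h_mm)
                K += (wx * wy * wz * detJ) * (B.T @ C @ B)
    return 0.5 * (K + K.T)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class FEModel:
    """Voxel FE model: element grid, node map, materials, constraints."""

    elem_idx: np.ndarray            # (m, 3) voxel indices
    elem_label: np.ndarray          # (m,) material labels
    conn: np.ndarray                # (m, 8) compact node ids
    node_keys: np.ndarray           # sorted unique flat node keys
    grid_shape: tuple[int, int, int]
    spacing_mm: float
    origin_mm: np.ndarray
    materials: dict[int, tuple[float, float]]
    fixed_dofs: np.ndarray          # (3 * n_nodes,) bool
    label_grid: np.ndarray | None = None
    _stiffness: sparse.csr_matrix | None = field(default=None, repr=False)

    @property
    def n_elements(self) -> int:
        return len(self.elem_idx)

    @property
    def n_nodes(self) -> int:
        return len(self.node_keys)

    @property
    def n_dofs(self) -> int:
        return 3 * self.n_nodes

    def node_indices(self) -> np.ndarray:
        """(n_nodes, 3) integer grid indices of the nodes."""
        nx, ny, nz = self.grid_shape
        kyz = (ny + 2) * (nz + 2)
        ix = self.node_keys // kyz
        rem = self.node_keys % kyz
        return np.column_stack([ix, rem // (nz + 2), rem % (nz + 2)])

    def node_coords_mm(self) -> np.ndarray:
        """World coordinates of the nodes (voxel corners)."""
        return self.origin_mm + self.node_indices() * self.spacing_mm

    def fix_nodes(self, node_ids: np.ndarray, components=(0, 1, 2)) -> None:
        for c in components:
            self.fixed_dofs[3 * np.asarray(node_ids) + c] = True

    def element_stiffnesses(self, n_gauss: int = 2) -> dict[int, np.ndarray]:
        return {
            lbl: element_stiffness(E, nu, self.spacing_mm, n_gauss=n_gauss)
            for lbl, (E, nu) in self.materials.items()
        }

    def assemble(self) -> sparse.csr_matrix:
        """Assembled global stiffness matrix (all DOFs, unconstrained)."""
        if self._stiffness is not None:
            return self._stiffness
        kes = self.element_stiffnesses()
        dofs = (3 * self.conn[:, :, None] + np.arange(3)).reshape(-1, 24)
        data = np.empty((self.n_elements, 24, 24))
        for lbl, ke in kes.items():
            data[self.elem_label == lbl] = ke
        rows = np.broadcast_to(dofs[:, :, None], (self.n_elements, 24, 24))
        cols = np.broadcast_to(dofs[:, None, :], (self.n_elements, 24, 24))
        K = sparse.coo_matrix(
            (data.ravel(), (rows.ravel().astype(np.int64), cols.ravel().astype(np.int64))),
            shape=(self.n_dofs, self.n_dofs),
        ).tocsr()
        self._stiffness = K
        return K

    def centroid_strain_operator(self) -> np.ndarray:
        """6×24 strain-displacement matrix at the element centroid."""
        return _b_matrix(np.zeros(3), self.spacing_mm)


@dataclass
class LoadCase:
    """A posture load case: 100 N resultant through the CoR.

    ``resultant_N`` points from the articular surface towards the centre of
    rotation (compressive); all nodal force vectors are parallel to it and
    sum to it exactly.
    """

    index: int
    angle_deg: float
    resultant_N: np.ndarray
    node_ids: np.ndarray
    nodal_force_N: np.ndarray  # (3,) shared by every loaded node

    def nodal_forces(self) -> np.ndarray:
        return np.broadcast_to(self.nodal_force_N, (len(self.node_ids), 3))

    def force_vector(self, model: FEModel) -> np.ndarray:
        f = np.zeros(model.n_dofs)
        for c in range(3):
            np.add.at(f, 3 * self.node_ids + c, self.nodal_force_N[c])
        return f

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "angle_deg": self.angle_deg,
            "resultant_N": self.resultant_N.tolist(),
            "n_nodes": int(len(self.node_ids)),
            "nodal_force_N": self.nodal_force_N.tolist(),
        }


@dataclass
class SEDField:
    """Per-element strain energy density (MPa) for one load case."""

    values: np.ndarray
    elem_idx: np.ndarray
    angle_deg: float
    load_case_index: int = 0
    displacements: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < -1e-12).any():
            raise ValueError("strain energy density must be non-negative")
        self.values = np.maximum(self.values, 0.0)


def build_model(
    labeled: LabeledModelImage | VoxelImage,
    materials: dict[int, tuple[float, float]] | None = None,
    constrain: str | None = "proximal",
) -> FEModel:
    """Convert a labelled voxel image into a hexahedral FE model.

    Every labelled voxel becomes one element; duplicate nodes are merged.
    With ``constrain='proximal'`` all DOFs of the nodes on the minimum-x
    element face are fixed; ``constrain=None`` leaves the model free (the
    caller must fix DOFs before solving).  A plain :class:`VoxelImage`
    (binary or integer labels) is accepted for patch-test style models.
    """
    materials = dict(DEFAULT_MATERIALS if materials is None else materials)
    img = labeled.labels if isinstance(labeled, LabeledModelImage) else labeled
    grid = img.data.astype(np.uint8) if img.data.dtype == bool else img.data
    mask = grid > 0
    if not mask.any():
        raise InvalidArgumentError("label image contains no elements")
    n_comp = ndimage.label(mask, structure=_STRUCT26)[1]
    if n_comp > 1:
        lbl, _ = ndimage.label(mask, structure=_STRUCT26)
        sizes = np.bincount(lbl.ravel())[1:]
        raise InvalidArgumentError(
            f"model has {n_comp} disconnected components (sizes {sorted(sizes, reverse=True)})"
        )
    elem_idx = np.argwhere(mask)
    elem_label = grid[mask.nonzero()]
    missing = set(np.unique(elem_label)) - set(materials)
    if missing:
        raise InvalidArgumentError(f"no material given for labels {sorted(missing)}")

    nz2 = grid.shape[2] + 2
    kyz = (grid.shape[1] + 2) * nz2
    node_idx = elem_idx[:, None, :] + _OFFSETS[None, :, :]
    keys = (node_idx[..., 0] * kyz + node_idx[..., 1] * nz2 + node_idx[..., 2])
    node_keys = np.unique(keys)
    conn = np.searchsorted(node_keys, keys)

    model = FEModel(
        elem_idx=elem_idx,
        elem_label=elem_label,
        conn=conn,
        node_keys=node_keys,
        grid_shape=grid.shape,
        spacing_mm=img.spacing_mm,
        origin_mm=img.origin_mm.copy(),
        materials=materials,
        fixed_dofs=np.zeros(3 * len(node_keys), dtype=bool),
        label_grid=grid,
    )
    if constrain == "proximal":
        ni = model.node_indices()
        face = np.nonzero(ni[:, 0] == elem_idx[:, 0].min())[0]
        model.fix_nodes(face)
        if not model.fixed_dofs.any():
            raise InvalidArgumentError("no proximal face found to constrain")
    return model


# ---------------------------------------------------------------------------
# load cases
# ---------------------------------------------------------------------------


def _cartilage_surface_nodes(model: FEModel) -> np.ndarray:
    """Compact ids of nodes on exterior faces of cartilage elements."""
    if model.label_grid is None:
        raise InvalidArgumentError("model carries no label grid")
    grid = model.label_grid
    cart = grid == 2
    if not cart.any():
        raise LoadAreaError("model has no cartilage elements")
    occupied = grid > 0
    face_nodes = []
    # a face is exterior when the neighbouring voxel is void
    for axis in range(3):
        for side in (0, 1):
            shifted = np.ones_like(occupied)
            sl_src = [slice(None)] * 3
            sl_dst = [slice(None)] * 3
            if side == 0:
                sl_src[axis] = slice(None, -1)
                sl_dst[axis] = slice(1, None)
            else:
                sl_src[axis] = slice(1, None)
                sl_dst[axis] = slice(None, -1)
            shifted[tuple(sl_dst)] = occupied[tuple(sl_src)]
            exposed = cart & ~shifted
            if not exposed.any():
                continue
            vox = np.argwhere(exposed)
            face_offsets = _OFFSETS[_OFFSETS[:, axis] == side]
            nodes = vox[:, None, :] + face_offsets[None, :, :]
            face_nodes.append(nodes.reshape(-1, 3))
    if not face_nodes:
        raise LoadAreaError("cartilage has no exterior surface")
    nodes = np.unique(np.concatenate(face_nodes), axis=0)
    nz2 = grid.shape[2] + 2
    kyz = (grid.shape[1] + 2) * nz2
    keys = nodes[:, 0] * kyz + nodes[:, 1] * nz2 + nodes[:, 2]
    pos = np.searchsorted(model.node_keys, keys)
    valid = pos < len(model.node_keys)
    pos, keys = pos[valid], keys[valid]
    return np.unique(pos[model.node_keys[pos] == keys])


def make_load_case(
    model: FEModel,
    cs: JointCoordinateSystem,
    angle_deg: float,
    area_deg: tuple[float, float] = (40.0, 30.0),
    magnitude_N: float = 100.0,
    index: int = 0,
) -> LoadCase:
    """Build one posture load case.

    Cartilage surface nodes within the spherical rectangle centred on the
    posture ray (±``area_deg[0]/2`` in the flexion–extension plane,
    ±``area_deg[1]/2`` elevation) each receive an equal force along the
    direction from the articular surface towards the CoR; the shares are
    scaled so the resultant magnitude is exactly ``magnitude_N``.
    """
    half_phi, half_lam = area_deg[0] / 2.0, area_deg[1] / 2.0
    if half_phi <= 0 or half_lam <= 0:
        raise LoadAreaError(f"degenerate load area {area_deg}")
    nodes = _cartilage_surface_nodes(model)
    local = cs.world_to_local(model.node_coords_mm()[nodes])
    r = np.linalg.norm(local, axis=1)
    ok = r > 1e-9
    nodes, local, r = nodes[ok], local[ok], r[ok]
    phi = np.degrees(np.arctan2(local[:, 1], local[:, 0]))
    lam = np.degrees(np.arcsin(np.clip(local[:, 2] / r, -1, 1)))
    dphi = (phi - angle_deg + 180.0) % 360.0 - 180.0
    sel = (np.abs(dphi) <= half_phi) & (np.abs(lam) <= half_lam)
    if not sel.any():
        raise LoadAreaError(
            f"no cartilage surface nodes in the {area_deg} area at {angle_deg} deg"
        )
    node_ids = np.sort(nodes[sel])
    theta = np.deg2rad(angle_deg)
    direction_local = -np.array([np.cos(theta), np.sin(theta), 0.0])
    direction = cs.axes @ direction_local
    resultant = magnitude_N * direction
    per_node = resultant / len(node_ids)
    return LoadCase(
        index=index,
        angle_deg=float(angle_deg),
        resultant_N=resultant,
        node_ids=node_ids,
        nodal_force_N=per_node,
    )


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------


class FESolver:
    """Reusable solver for one model and many right-hand sides.

    Small systems are factorized once with SuperLU; larger ones fall back to
    conjugate gradients with a Jacobi preconditioner (relative residual
    1e-8, capped at 100 000 iterations).
    """

    def __init__(self, model: FEModel, method: str = "auto",
                 tol: float = 1e-8, maxiter: int = 100_000):
        if not model.fixed_dofs.any():
            raise SolverError("model has no constrained DOFs; system is singular")
        self.model = model
        self.tol = tol
        self.maxiter = maxiter
        self.free = np.nonzero(~model.fixed_dofs)[0]
        K = model.assemble()
        self.K_free = K[self.free][:, self.free].tocsc()
        if method == "auto":
            method = "direct" if len(self.free) <= DIRECT_SOLVE_MAX_DOF else "cg"
        self.method = method
        self._lu = None
        if method == "direct":
            try:
                self._lu = spla.splu(self.K_free)
            except (MemoryError, RuntimeError):
                self.method = "cg"
        if self.method == "cg":
            diag = self.K_free.diagonal()
            diag[diag <= 0] = 1.0
            self._M = sparse.diags(1.0 / diag)
            self.K_free = self.K_free.tocsr()

    def displacements(self, f: np.ndarray) -> np.ndarray:
        """Full-length displacement vector for force vector ``f``."""
        u = np.zeros(self.model.n_dofs)
        rhs = f[self.free]
        if self._lu is not None:
            u[self.free] = self._lu.solve(rhs)
            return u
        x, info = spla.cg(self.K_free, rhs, rtol=self.tol, atol=0.0,
                          maxiter=self.maxiter, M=self._M)
        if info != 0:
            raise SolverError(f"CG failed to converge (info={info})")
        u[self.free] = x
        return u

    def sed(self, u: np.ndarray, angle_deg: float = np.nan,
            index: int = 0) -> SEDField:
        """Strain energy density at element centroids from displacements."""
        model = self.model
        B0 = model.centroid_strain_operator()
        dofs = (3 * model.conn[:, :, None] + np.arange(3)).reshape(-1, 24)
        ue = u[dofs]
        eps = ue @ B0.T
        U = np.empty(model.n_elements)
        for lbl, (E, nu) in model.materials.items():
            m = model.elem_label == lbl
            if m.any():
                sig = eps[m] @ elasticity_matrix(E, nu).T
                U[m] = 0.5 * np.einsum("ij,ij->i", eps[m], sig)
        return SEDField(values=U, elem_idx=model.elem_idx, angle_deg=angle_deg,
                        load_case_index=index, displacements=u)


def solve(model: FEModel, load_case: LoadCase, method: str = "auto",
          tol: float = 1e-8) -> SEDField:
    """Solve one load case and return the centroid SED field."""
    solver = FESolver(model, method=method, tol=tol)
    u = solver.displacements(load_case.force_vector(model))
    return solver.sed(u, angle_deg=load_case.angle_deg, index=load_case.index)


def run_all_load_cases(
    model: FEModel,
    cs: JointCoordinateSystem,
    angles_deg=LOAD_CASE_ANGLES_DEG,
    area_deg: tuple[float, float] = (40.0, 30.0),
    magnitude_N: float = 100.0,
    method: str = "auto",
    tol: float = 1e-8,
    keep_displacements: bool = False,
) -> tuple[list[LoadCase], list[SEDField]]:
    """Solve every posture load case (sorted by angle) with one factorization."""
    angles = sorted(float(a) for a in angles_deg)
    cases = [
        make_load_case(model, cs, a, area_deg=area_deg,
                       magnitude_N=magnitude_N, index=i + 1)
        for i, a in enumerate(angles)
    ]
    solver = FESolver(model, method=method, tol=tol)
    fields = []
    for case in cases:
        u = solver.displacements(case.force_vector(model))
        f = solver.sed(u, angle_deg=case.angle_deg, index=case.index)
        if not keep_displacements:
            f.displacements = None
        fields.append(f)
    return cases, fields


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_sed_fields(path: str | Path, fields: list[SEDField],
                    spacing_mm: float | None = None) -> None:
    """Persist SED fields to an HDF5 container (one group per load case)."""
    with h5py.File(path, "w") as f:
        if spacing_mm is not None:
            f.attrs["spacing_mm"] = spacing_mm
        for fld in fields:
            g = f.create_group(f"case_{fld.load_case_index:02d}")
            g.attrs["angle_deg"] = fld.angle_deg
            g.attrs["load_case_index"] = fld.load_case_index
            g.create_dataset("sed_MPa", data=fld.values, compression="gzip")
            g.create_dataset("elem_idx", data=fld.elem_idx, compression="gzip")


def load_sed_fields(path: str | Path) -> list[SEDField]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            out.append(SEDField(
                values=g["sed_MPa"][()],
                elem_idx=g["elem_idx"][()],
                angle_deg=float(g.attrs["angle_deg"]),
                load_case_index=int(g.attrs["load_case_index"]),
            ))
    return out
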