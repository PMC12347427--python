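"""Plane-stress linear elasticity on a tagged triangle mesh.

Constant-strain triangles, direct sparse factorization, per-element strain
energy density.  Units: lengths in mm, moduli in MPa, forces in N; the SED
field then comes out in MPa (= 1e6 J/m^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import InvalidParameterError, SolverError
from .meshing import MaterialTable, Mesh, Region

__all__ = [
    "PlaneStressSystem",
    "DisplacementField",
    "SEDField",
    "assemble",
    "solve",
    "strain_energy_density",
    "element_stress",
    "interface_band",
]


@dataclass(frozen=True)
class PlaneStressSystem:
    """Assembled stiffness with mesh bookkeeping (dofs = 2 per node)."""

    stiffness: sp.csr_matrix
    mesh: Mesh
    materials: MaterialTable
    thickness: float

    @property
    def n_dofs(self) -> int:
        return self.stiffness.shape[0]


@dataclass(frozen=True)
class DisplacementField:
    """Per-node displacement vectors (mm)."""

    values: np.ndarray  # (n_nodes, 2)
    fixed_nodes: np.ndarray  # indices of fully constrained nodes
    residual: float  # |K u - f| / |f| on the free dofs


@dataclass(frozen=True)
class SEDField:
    """Per-element strain energy density in MPa with element metadata."""

    sed: np.ndarray  # (m,) MPa
    centroids: np.ndarray  # (m, 2)
    areas: np.ndarray  # (m,)
    region: np.ndarray  # (m,) Region
    stress: np.ndarray  # (m, 3) [sxx, syy, sxy] MPa
    strain: np.ndarray  # (m, 3) [exx, eyy, gxy]

    def von_mises(self) -> np.ndarray:
        sxx, syy, sxy = self.stress.T
        return np.sqrt(sxx**2 - sxx * syy + syy**2 + 3.0 * sxy**2)


def _elasticity_matrix(E: float, nu: float) -> np.ndarray:
    c = E / (1.0 - nu * nu)
    return c * np.array([[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]])


def _b_matrices(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-element CST strain-displacement matrices and areas."""
    p = mesh.nodes[mesh.triangles]  # (m, 3, 2)
    x, y = p[..., 0], p[..., 1]
    b = np.stack(
        [y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1
    )
    c = np.stack(
        [x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1
    )
    area2 = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]
    m = len(p)
    B = np.zeros((m, 3, 6))
    B[:, 0, 0::2] = b
    B[:, 1, 1::2] = c
    B[:, 2, 0::2] = c
    B[:, 2, 1::2] = b
    B /= area2[:, None, None]
    return B, 0.5 * area2


def assemble(mesh: Mesh, materials: MaterialTable, thickness: float = 10.0) -> PlaneStressSystem:
    """Assemble the global plane-stress stiffness matrix (symmetric PSD).

    Raises
    ------
    InvalidParameterError
        If the thickness or any Young's modulus is non-positive.
    """
    if thickness <= 0.0:
        raise InvalidParameterError("thickness must be > 0")
    for region in Region:
        if materials.for_region(region).youngs_modulus <= 0.0:
            raise InvalidParameterError(f"singular material in region {region.name}")

    B, areas = _b_matrices(mesh)
    m = mesh.n_elements
    D = np.empty((m, 3, 3))
    for region in Region:
        mask = mesh.region == region
        if mask.any():
            mat = materials.for_region(region)
            D[mask] = _elasticity_matrix(mat.youngs_modulus, mat.poisson_ratio)

    ke = thickness * areas[:, None, None] * np.einsum("mji,mjk,mkl->mil", B, D, B)

    dof = np.empty((m, 6), dtype=np.int64)
    dof[:, 0::2] = 2 * mesh.triangles
    dof[:, 1::2] = 2 * mesh.triangles + 1
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    n = 2 * mesh.n_nodes
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    K.sum_duplicates()
    return PlaneStressSystem(stiffness=K, mesh=mesh, materials=materials, thickness=thickness)


def solve(
    system: PlaneStressSystem,
    forces: np.ndarray,
    fixed_nodes: np.ndarray | None = None,
    *,
    fixed_dofs: np.ndarray | None = None,
) -> DisplacementField:
    """Solve K u = f with homogeneous Dirichlet constraints.

    ``fixed_nodes`` pins both displacement components of the listed nodes;
    ``fixed_dofs`` may instead (or additionally) list individual dof indices
    (2*node for x, 2*node+1 for y), e.g. for roller supports in benchmarks.
    ``forces`` is an (n_nodes, 2) nodal force array in N.
    """
    all_dofs: list[np.ndarray] = []
    if fixed_nodes is not None:
        fixed_nodes = np.unique(np.asarray(fixed_nodes, dtype=np.int64))
        pts = system.mesh.nodes[fixed_nodes]
        if len(fixed_nodes) == 2 and np.allclose(pts[0], pts[1]):
            raise SolverError("constrained nodes are coincident")
        all_dofs.append(np.concatenate([2 * fixed_nodes, 2 * fixed_nodes + 1]))
    else:
        fixed_nodes = np.empty(0, dtype=np.int64)
    if fixed_dofs is not None:
        all_dofs.append(np.asarray(fixed_dofs, dtype=np.int64))
    if not all_dofs:
        raise SolverError("no constraints given")
    fixed_dofs = np.unique(np.concatenate(all_dofs))
    if len(fixed_dofs) < 3:
        raise SolverError("need at least three constrained dofs to remove rigid modes")

    n = system.n_dofs
    f = np.asarray(forces, dtype=float).reshape(-1)
    if f.shape[0] != n:
        raise InvalidParameterError("force array must have 2 entries per node")
    free = np.setdiff1d(np.arange(n), fixed_dofs)
    K = system.stiffness
    Kff = K[free][:, free].tocsc()
    ff = f[free]
    try:
        uf = spla.spsolve(Kff, ff)
    except Exception as exc:  # pragma: no cover
        raise SolverError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(uf)):
        raise SolverError("singular constrained system")

    u = np.zeros(n)
    u[free] = uf
    fn = np.linalg.norm(ff)
    residual = float(np.linalg.norm(Kff @ uf - ff) / fn) if fn > 0 else 0.0
    return DisplacementField(values=u.reshape(-1, 2), fixed_nodes=fixed_nodes, residual=residual)


def element_stress(
    mesh: Mesh, materials: MaterialTable, u: DisplacementField
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element (stress, strain) under the plane-stress law."""
    B, _ = _b_matrices(mesh)
    ue = u.values[mesh.triangles].reshape(mesh.n_elements, 6)
    strain = np.einsum("mij,mj->mi", B, ue)
    stress = np.empty_like(strain)
    for region in Region:
        mask = mesh.region == region
        if mask.any():
            mat = materials.for_region(region)
            D = _elasticity_matrix(mat.youngs_modulus, mat.poisson_ratio)
            stress[mask] = strain[mask] @ D.T
    return stress, strain


def strain_energy_density(
    mesh: Mesh, materials: MaterialTable, u: DisplacementField
) -> SEDField:
    """Per-element SED U = 1/2 sigma:epsilon (MPa), non-negative by construction."""
    stress, strain = element_stress(mesh, materials, u)
    sed = 0.5 * np.einsum("mi,mi->m", stress, strain)
    sed = np.maximum(sed, 0.0)  # clip -0.0 / roundoff
    return SEDField(
        sed=sed,
        centroids=mesh.centroids,
        areas=mesh.areas,
        region=mesh.region,
        stress=stress,
        strain=strain,
    )


def interface_band(mesh: Mesh, placed_stem, band_width: float = 3.0) -> np.ndarray:
    """Boolean mask of bone elements whose centroid is within ``band_width``
    mm of the stem contour."""
    if band_width <= 0.0:
        raise InvalidParameterError("band_width must be > 0")
    import shapely

    ring = placed_stem.contour.polygon.exterior
    shapely.prepare(ring)
    cents = mesh.centroids
    d = shapely.distance(ring, shapely.points(cents))
    bone = mesh.region != Region.IMPLANT
    return bone & (d <= band_width)
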