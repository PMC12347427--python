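"""Physiological load case: joint contact force, abductor reaction, fixation.

The joint contact force acts at the femoral head centre with magnitude
``joint_force_factor`` (default 2.38) times body weight, tilted by the
patient's Pauwels angle from the vertical toward medial and pointing
distally.  The abductor reaction acts at the greater trochanter; in the
default ``equilibrium`` mode it closes the single-leg-stance force balance
against the joint force and the partial body weight (5/6 BW), in ``fixed``
mode its magnitude and direction are configured constants.

Point loads are distributed onto the nodes of the nearest mesh element with
(clipped) barycentric weights, conserving the total force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .geometry import FemurGeometry
from .meshing import Mesh

__all__ = [
    "GRAVITY",
    "PointLoad",
    "LoadCase",
    "joint_force",
    "abductor_force",
    "build_load_case",
    "nodal_forces",
    "distal_fixed_nodes",
]

GRAVITY = 9.81  # m/s^2

_MEDIAL = np.array([-1.0, 0.0])  # +x is lateral for a right femur
_DISTAL = np.array([0.0, -1.0])


@dataclass(frozen=True)
class PointLoad:
    location: np.ndarray  # mm
    force: np.ndarray  # N
    label: str = ""

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.location)) and np.all(np.isfinite(self.force))):
            raise InvalidParameterError("point load must be finite")
        if float(np.hypot(*self.force)) <= 0.0:
            raise InvalidParameterError("point load magnitude must be > 0")

    @property
    def magnitude(self) -> float:
        return float(np.hypot(*self.force))


@dataclass(frozen=True)
class LoadCase:
    loads: list[PointLoad]
    body_weight: float  # kg
    pauwels_angle: float  # deg
    joint_force_factor: float = 2.38
    gravity: float = GRAVITY

    def __post_init__(self) -> None:
        if self.joint_force_factor <= 0.0:
            raise InvalidParameterError("joint_force_factor must be > 0")
        if not self.loads:
            raise InvalidParameterError("load case needs at least one point load")


def joint_force(
    body_weight: float,
    pauwels_angle: float,
    factor: float = 2.38,
    *,
    location: np.ndarray | None = None,
    gravity: float = GRAVITY,
) -> PointLoad:
    """Joint contact force at the head centre.

    |F| = factor * BW * g, tilted ``pauwels_angle`` degrees from the -y axis
    toward medial (-x), i.e. compressive into the head.
    """
    if body_weight <= 0.0:
        raise InvalidParameterError("body_weight must be > 0")
    if not 0.0 <= pauwels_angle <= 45.0:
        raise InvalidParameterError("pauwels_angle must lie in [0, 45] deg")
    if factor <= 0.0:
        raise InvalidParameterError("joint force factor must be > 0")
    mag = factor * body_weight * gravity
    theta = np.radians(pauwels_angle)
    direction = np.sin(theta) * _MEDIAL + np.cos(theta) * _DISTAL
    loc = np.zeros(2) if location is None else np.asarray(location, dtype=float)
    return PointLoad(location=loc, force=mag * direction, label="joint")


def abductor_force(
    body_weight: float,
    joint_load: PointLoad,
    mode: str = "equilibrium",
    *,
    location: np.ndarray | None = None,
    fixed_factor: float = 1.6,
    fixed_angle: float = 21.0,
    partial_weight_fraction: float = 5.0 / 6.0,
    gravity: float = GRAVITY,
) -> PointLoad:
    """Abductor muscle reaction at the greater trochanter.

    ``equilibrium``: F_A = -(F_J + W_partial) with W_partial = 5/6 BW * g
    acting distally (single-leg stance closure).  ``fixed``: magnitude
    ``fixed_factor`` * BW * g at ``fixed_angle`` degrees from +y toward
    medial.
    """
    if body_weight <= 0.0:
        raise InvalidParameterError("body_weight must be > 0")
    loc = np.zeros(2) if location is None else np.asarray(location, dtype=float)
    if mode == "equilibrium":
        w_partial = partial_weight_fraction * body_weight * gravity * _DISTAL
        force = -(joint_load.force + w_partial)
    elif mode == "fixed":
        alpha = np.radians(fixed_angle)
        direction = np.cos(alpha) * np.array([0.0, 1.0]) + np.sin(alpha) * _MEDIAL
        force = fixed_factor * body_weight * gravity * direction
    else:
        raise InvalidParameterError(f"unknown abductor mode {mode!r}")
    return PointLoad(location=loc, force=force, label="abductor")


def build_load_case(
    body_weight: float,
    femur: FemurGeometry,
    pauwels_angle: float = 16.0,
    *,
    joint_force_factor: float = 2.38,
    abductor_mode: str = "equilibrium",
    gravity: float = GRAVITY,
) -> LoadCase:
    """Joint + abductor point loads attached to the femur landmarks."""
    jf = joint_force(
        body_weight,
        pauwels_angle,
        joint_force_factor,
        location=femur.head_center,
        gravity=gravity,
    )
    ab = abductor_force(
        body_weight,
        jf,
        abductor_mode,
        location=femur.trochanter_apex,
        gravity=gravity,
    )
    return LoadCase(
        loads=[jf, ab],
        body_weight=body_weight,
        pauwels_angle=pauwels_angle,
        joint_force_factor=joint_force_factor,
        gravity=gravity,
    )


def distal_fixed_nodes(mesh: Mesh, tol: float = 1e-6) -> np.ndarray:
    """Nodes on the distal cut (minimal y) of the mesh; all dofs constrained."""
    y = mesh.nodes[:, 1]
    return np.nonzero(y <= y.min() + tol)[0]


def nodal_forces(
    mesh: Mesh,
    loads: list[PointLoad],
    region_preference: dict[str, "Region"] | None = None,
) -> np.ndarray:
    """Distribute point loads to mesh nodes, conserving each total force.

    Each load goes to the nodes of the element whose barycentric coordinates
    of the load location are most nearly inside (negative weights clipped to
    zero and renormalised); ties in the deficit resolve to the element with
    the closest centroid.  Locations outside the mesh, such as the prosthetic
    head centre beyond the resection plane, thereby attach to the nearest
    boundary element.  ``region_preference`` maps a load label to a Region
    whose elements are the only candidates (e.g. the joint force enters
    through the implant neck).
    """
    p = mesh.nodes[mesh.triangles]  # (m, 3, 2)
    cents = mesh.centroids
    f = np.zeros((mesh.n_nodes, 2))
    for load in loads:
        cand = np.arange(mesh.n_elements)
        if region_preference and load.label in region_preference:
            mask = mesh.region == region_preference[load.label]
            if mask.any():
                cand = np.nonzero(mask)[0]
        loc = np.asarray(load.location, dtype=float)
        lam = _barycentric(p[cand], loc)
        deficit = np.minimum(lam, 0.0).sum(axis=1)  # 0 when inside
        dist = np.hypot(*(cents[cand] - loc).T)
        best = int(np.lexsort((dist, -deficit))[0])
        w = np.clip(lam[best], 0.0, None)
        w /= w.sum()
        tri = mesh.triangles[cand[best]]
        for k in range(3):
            f[tri[k]] += w[k] * load.force
    return f


def _barycentric(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    v2 = q - p[:, 0]
    d00 = np.einsum("mi,mi->m", v0, v0)
    d01 = np.einsum("mi,mi->m", v0, v1)
    d11 = np.einsum("mi,mi->m", v1, v1)
    d20 = np.einsum("mi,mi->m", v2, v0)
    d21 = np.einsum("mi,mi->m", v2, v1)
    denom = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    u = 1.0 - v - w
    return np.stack([u, v, w], axis=1)
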