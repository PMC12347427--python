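"""Conforming triangulation of the bone/implant domain with material tags.

The mesher samples all region boundaries (periosteal, endosteal, stem) at a
target spacing, adds an interior point lattice, Delaunay-triangulates, and
then recovers any missing boundary segment by midpoint insertion so that
region interfaces are honoured as mesh edges.  Oversized elements are split
by centroid insertion until the requested size bound holds.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
import shapely
import shapely.ops
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Point

from .errors import InvalidParameterError, MeshingError
from .geometry import FemurGeometry, PlacedStem

__all__ = ["Region", "Mesh", "MaterialTable", "Material", "triangulate", "default_materials"]


class Region(enum.Enum):
    CORTICAL = 0
    CANCELLOUS = 1
    IMPLANT = 2


@dataclass(frozen=True)
class Mesh:
    """Triangle mesh with per-element region tags.

    ``nodes``: (n, 2) float array in mm; ``triangles``: (m, 3) int array of
    CCW node triples; ``region``: (m,) array of Region values.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    region: np.ndarray

    def __post_init__(self) -> None:
        if len(self.triangles) != len(self.region):
            raise InvalidParameterError("one region tag per triangle required")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @property
    def areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    @property
    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as sorted node pairs."""
        tri = self.triangles
        e = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def edge_incidence(self) -> dict[tuple[int, int], int]:
        tri = self.triangles
        counts: dict[tuple[int, int], int] = {}
        for a, b in np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]):
            key = (int(min(a, b)), int(max(a, b)))
            counts[key] = counts.get(key, 0) + 1
        return counts


@dataclass(frozen=True)
class Material:
    youngs_modulus: float  # MPa
    poisson_ratio: float
    density: float  # kg/m^3

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0.0:
            raise InvalidParameterError("Young's modulus must be > 0")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise InvalidParameterError("Poisson ratio must lie in (0, 0.5)")
        if self.density <= 0.0:
            raise InvalidParameterError("density must be > 0")


@dataclass(frozen=True)
class MaterialTable:
    cortical: Material
    cancellous: Material
    implant: Material

    def for_region(self, region: Region) -> Material:
        return {
            Region.CORTICAL: self.cortical,
            Region.CANCELLOUS: self.cancellous,
            Region.IMPLANT: self.implant,
        }[region]

    def with_overrides(self, overrides: dict) -> "MaterialTable":
        """Apply a nested ``{region: {property: value}}`` override mapping."""
        out = {}
        for name in ("cortical", "cancellous", "implant"):
            mat = getattr(self, name)
            if name in overrides:
                mat = replace(mat, **overrides[name])
            out[name] = mat
        return MaterialTable(**out)


def default_materials() -> MaterialTable:
    """Homogeneous per-class defaults (titanium-alloy implant), configurable."""
    return MaterialTable(
        cortical=Material(youngs_modulus=17_000.0, poisson_ratio=0.3, density=1800.0),
        cancellous=Material(youngs_modulus=1_000.0, poisson_ratio=0.3, density=600.0),
        implant=Material(youngs_modulus=110_000.0, poisson_ratio=0.3, density=4500.0),
    )


def _constraint_lines(femur: FemurGeometry, placed_stem: PlacedStem | None):
    """Region-boundary polylines, mutually split at intersection points.

    The endosteal ring may pass through the implant near the resection cut;
    the portion inside the implant is not a material interface and is
    dropped, and the stem ring is split at the crossing points so every
    constraint segment can be recovered as a Delaunay edge.
    """
    peri = femur.periosteal.polygon.exterior
    endo = femur.endosteal.polygon.exterior
    lines = [peri]
    if placed_stem is None:
        lines.append(endo)
    else:
        stem_poly = placed_stem.contour.polygon
        stem_ring = shapely.geometry.LineString(stem_poly.exterior.coords)
        endo_line = shapely.geometry.LineString(endo.coords)
        crossings = stem_ring.intersection(endo_line)
        if crossings.is_empty:
            lines.append(stem_ring)
            lines.append(endo_line)
        else:
            # split both rings at the same crossing coordinates so the shared
            # endpoints coincide exactly; endosteal pieces inside the implant
            # are not material interfaces and are dropped
            if crossings.geom_type == "Point":
                cross_pts = [(crossings.x, crossings.y)]
            else:
                cross_pts = [(g.x, g.y) for g in crossings.geoms]
            lines.extend(_split_ring_at(stem_ring, cross_pts))
            inner = stem_poly.buffer(-1e-9)
            for part in _split_ring_at(endo_line, cross_pts):
                if not inner.contains(part.interpolate(0.5, normalized=True)):
                    lines.append(part)
    return lines


def _split_ring_at(ring: "shapely.geometry.LineString", points) -> list:
    """Split a closed ring polyline at the given points (exact coordinates).

    Points are located by arc-length projection, inserted as vertices, and
    the ring is cut into open polylines between consecutive insertions.
    """
    from shapely.geometry import LineString

    coords = list(ring.coords)
    if coords[0] == coords[-1]:
        coords = coords[:-1]
    n = len(coords)
    cum = [0.0]
    for i in range(n):
        a, b = coords[i], coords[(i + 1) % n]
        cum.append(cum[-1] + math.hypot(b[0] - a[0], b[1] - a[1]))
    total = cum[-1]
    events = sorted(((ring.project(Point(p)) % total, tuple(p)) for p in points))

    # build augmented vertex list: (param, coord, is_cut)
    aug: list[tuple[float, tuple, bool]] = [(cum[i], coords[i], False) for i in range(n)]
    for s, pt in events:
        aug.append((s, pt, True))
    aug.sort(key=lambda t: (t[0], not t[2]))
    # drop original vertices that coincide with a cut point
    cleaned = []
    for s, pt, cut in aug:
        if cleaned and abs(s - cleaned[-1][0]) < 1e-9:
            if cut and not cleaned[-1][2]:
                cleaned[-1] = (s, pt, True)
            continue
        cleaned.append((s, pt, cut))
    cut_idx = [i for i, (_, _, c) in enumerate(cleaned) if c]
    if not cut_idx:
        return [LineString(coords + [coords[0]])]
    parts = []
    m = len(cleaned)
    for j, start in enumerate(cut_idx):
        end = cut_idx[(j + 1) % len(cut_idx)]
        seq = []
        i = start
        while True:
            seq.append(cleaned[i][1])
            if i == end and len(seq) > 1:
                break
            i = (i + 1) % m
        if len(seq) >= 2:
            parts.append(LineString(seq))
    return parts


def _build_pslg(lines, spacing: float):
    """Sample polylines at <= ``spacing`` and emit deduplicated points/segments."""
    points: list[tuple[float, float]] = []
    index: dict[tuple[float, float], int] = {}
    segments: list[tuple[int, int]] = []

    def add(pt) -> int:
        key = (round(float(pt[0]), 9), round(float(pt[1]), 9))
        if key not in index:
            index[key] = len(points)
            points.append((float(pt[0]), float(pt[1])))
        return index[key]

    for line in lines:
        dens = shapely.segmentize(line, spacing)
        coords = np.asarray(dens.coords)
        ids = [add(c) for c in coords]
        for a, b in zip(ids[:-1], ids[1:]):
            if a != b:
                segments.append((a, b))
    return np.asarray(points), segments


def triangulate(
    femur: FemurGeometry,
    placed_stem: PlacedStem | None = None,
    max_element_area: float = 1.0,
    *,
    max_recovery_rounds: int = 12,
) -> Mesh:
    """Triangulate the femur (and optional stem) into a tagged conforming mesh.

    Every region boundary is recovered as a chain of mesh edges; every
    triangle area is <= ``max_element_area``; tags come from a point-in-region
    test of centroids (nudged toward the incenter when on a boundary).
    """
    if max_element_area <= 0.0:
        raise InvalidParameterError("max_element_area must be > 0")

    domain = femur.periosteal.polygon
    h = math.sqrt(2.0 * max_element_area)
    lines = _constraint_lines(femur, placed_stem)
    pts, segments = _build_pslg(lines, h)

    # interior lattice (hexagonal offsets to avoid co-circular degeneracies)
    minx, miny, maxx, maxy = domain.bounds
    xs = np.arange(minx + 0.5 * h, maxx, h)
    ys = np.arange(miny + 0.5 * h, maxy, 0.866 * h)
    grid = []
    for row, y in enumerate(ys):
        shift = 0.25 * h if row % 2 else -0.25 * h
        for x in xs:
            grid.append((x + shift, y))
    grid = np.asarray(grid)
    if len(grid):
        inside = shapely.contains_xy(domain, grid[:, 0], grid[:, 1])
        tree = cKDTree(pts)
        d, _ = tree.query(grid)
        grid = grid[inside & (d >= 0.6 * h)]
    pts = np.vstack([pts, grid]) if len(grid) else pts
    try:
        m_pts, m_tris, m_segs = _delaunay_with_recovery(
            pts, segments, domain, max_recovery_rounds
        )
        m_pts, m_tris = _refine_to_area(
            (m_pts, m_tris), m_segs, domain, max_element_area, max_recovery_rounds
        )
    except MeshingError:
        raise
    except Exception as exc:  # pragma: no cover - qhull failures
        raise MeshingError(f"triangulation failed: {exc}") from exc

    region = _tag_regions((m_pts, m_tris), femur, placed_stem)
    return Mesh(nodes=m_pts, triangles=m_tris, region=region)


def _delaunay_with_recovery(pts, segments, domain, max_rounds):
    """Delaunay triangulation with constraint-segment recovery by midpoint split."""
    seg_pairs = [(a, b) for a, b in segments]
    for _ in range(max_rounds):
        tri = Delaunay(pts)
        edge_set = set()
        for simplex in tri.simplices:
            for i in range(3):
                a, b = simplex[i], simplex[(i + 1) % 3]
                edge_set.add((min(a, b), max(a, b)))
        missing = [
            (a, b) for a, b in seg_pairs if (min(a, b), max(a, b)) not in edge_set
        ]
        if not missing:
            kept_pts, kept_tris = _strip_exterior(pts, tri.simplices, domain)
            return kept_pts, kept_tris, seg_pairs
        new_pairs = [p for p in seg_pairs if p not in missing]
        new_pts = list(pts)
        for a, b in missing:
            mid = 0.5 * (pts[a] + pts[b])
            m = len(new_pts)
            new_pts.append(mid)
            new_pairs.append((a, m))
            new_pairs.append((m, b))
        pts = np.asarray(new_pts)
        seg_pairs = new_pairs
    raise MeshingError("failed to recover all boundary segments")


def _strip_exterior(pts, simplices, domain):
    cent = pts[simplices].mean(axis=1)
    keep = shapely.contains_xy(domain, cent[:, 0], cent[:, 1])
    tris = simplices[keep]
    # enforce CCW orientation and drop degenerate slivers
    p = pts[tris]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = area2 < 0
    tris[flip] = tris[flip][:, ::-1]
    keep2 = np.abs(area2) > 2e-9
    return pts, tris[keep2]


def _refine_to_area(mesh, segments, domain, max_area, max_rounds):
    """Split oversized triangles at their longest edge until the bound holds.

    Midpoints of constraint edges stay on the constraint, so recovery cannot
    be broken by refinement.
    """
    pts, tris = mesh
    seg_set = {(min(a, b), max(a, b)) for a, b in segments}
    for _ in range(25):
        p = pts[tris]
        areas = 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )
        big = np.nonzero(areas > max_area)[0]
        if len(big) == 0:
            return pts, tris
        new_pts = list(pts)
        split_edges: set[tuple[int, int]] = set()
        for t in big:
            tri = tris[t]
            lengths = [
                (np.hypot(*(pts[tri[(i + 1) % 3]] - pts[tri[i]])), i) for i in range(3)
            ]
            _, i = max(lengths)
            a, b = int(tri[i]), int(tri[(i + 1) % 3])
            key = (min(a, b), max(a, b))
            if key in split_edges:
                continue
            split_edges.add(key)
            m = len(new_pts)
            new_pts.append(0.5 * (pts[a] + pts[b]))
            if key in seg_set:
                seg_set.discard(key)
                seg_set.add((min(a, m), max(a, m)))
                seg_set.add((min(b, m), max(b, m)))
        pts = np.asarray(new_pts)
        pts, tris, new_segs = _delaunay_with_recovery(pts, list(seg_set), domain, max_rounds)
        seg_set = {(min(a, b), max(a, b)) for a, b in new_segs}
    raise MeshingError("area refinement did not converge")


def _tag_regions(mesh, femur: FemurGeometry, placed_stem: PlacedStem | None) -> np.ndarray:
    pts, tris = mesh
    p = pts[tris]
    cent = p.mean(axis=1)

    endo = femur.endosteal.polygon
    shapely.prepare(endo)
    if placed_stem is not None:
        stem_poly = placed_stem.contour.polygon
        shapely.prepare(stem_poly)

    region = np.empty(len(tris), dtype=object)
    for i in range(len(tris)):
        x, y = cent[i]
        probe = Point(x, y)
        # nudge ambiguous centroids toward the incenter for a deterministic tag
        if placed_stem is not None and stem_poly.exterior.distance(probe) < 1e-9:
            probe = Point(*_toward_incenter(p[i], cent[i]))
        if endo.exterior.distance(probe) < 1e-9:
            probe = Point(*_toward_incenter(p[i], cent[i]))
        if placed_stem is not None and stem_poly.contains(probe):
            region[i] = Region.IMPLANT
        elif endo.contains(probe):
            region[i] = Region.CANCELLOUS
        else:
            region[i] = Region.CORTICAL
    return region


def _toward_incenter(tri_pts: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    a = np.hypot(*(tri_pts[2] - tri_pts[1]))
    b = np.hypot(*(tri_pts[0] - tri_pts[2]))
    c = np.hypot(*(tri_pts[1] - tri_pts[0]))
    incenter = (a * tri_pts[0] + b * tri_pts[1] + c * tri_pts[2]) / (a + b + c)
    return centroid + 1e-6 * (incenter - centroid)
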