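"""Parametric 2D frontal-plane geometry of a proximal femur with a short stem.

Conventions (right femur): +x points laterally, +y points proximally, all
lengths in millimetres.  Contours are simple, closed, counter-clockwise
polygons.  The femoral head is resected; the retained neck ends at a planar
cut whose centre is the ``resection_point`` landmark.  The prosthetic head
centre lies beyond the cut along the neck axis and is kept as a load
landmark even though it is outside the meshed domain.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
import shapely
import shapely.affinity
from shapely.geometry import Point, Polygon

from .errors import InvalidParameterError, PlacementError

__all__ = [
    "Contour",
    "FemurParams",
    "FemurGeometry",
    "StemType",
    "StemParams",
    "StemGeometry",
    "Alignment",
    "PlacedStem",
    "ZoneMap",
    "build_femur_contour",
    "build_stem_contour",
    "place_stem",
    "partition_gruen_zones",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(v[0], v[1]))
    if n == 0.0:
        raise InvalidParameterError("zero-length direction vector")
    return v / n


class Contour:
    """Simple closed CCW polygon.

    The constructor re-orients clockwise input to counter-clockwise and
    rejects self-intersecting or degenerate vertex lists.
    """

    __slots__ = ("vertices", "_polygon")

    def __init__(self, vertices) -> None:
        arr = np.asarray(vertices, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
            raise InvalidParameterError("contour needs >=3 (x, y) vertices")
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError("contour vertices must be finite")
        # drop an explicitly repeated closing vertex
        if np.allclose(arr[0], arr[-1]):
            arr = arr[:-1]
        poly = Polygon(arr)
        if not poly.is_valid or poly.area <= 0.0:
            raise InvalidParameterError("contour is self-intersecting or degenerate")
        if self._signed_area(arr) < 0.0:
            arr = arr[::-1].copy()
            poly = Polygon(arr)
        self.vertices = arr
        self._polygon = poly

    @staticmethod
    def _signed_area(arr: np.ndarray) -> float:
        x, y = arr[:, 0], arr[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def area(self) -> float:
        return float(self._polygon.area)

    def contains(self, other: "Contour") -> bool:
        return self._polygon.buffer(1e-9).contains(other._polygon)

    def transformed(self, matrix: np.ndarray, offset: np.ndarray) -> "Contour":
        return Contour(self.vertices @ matrix.T + offset)

    def wkt(self) -> str:
        return self._polygon.wkt

    def __eq__(self, other) -> bool:
        return isinstance(other, Contour) and np.array_equal(self.vertices, other.vertices)

    def __repr__(self) -> str:
        return f"Contour({len(self.vertices)} vertices, area={self.area:.1f} mm^2)"


@dataclass(frozen=True)
class FemurParams:
    """Interpretable lengths (mm) and angles (deg) of the parametric femur."""

    shaft_length: float = 70.0
    shaft_width: float = 30.0
    cortical_thickness: float = 5.5
    metaphysis_height: float = 15.0
    neck_length: float = 40.0
    neck_width: float = 30.0
    head_offset: float = 20.0
    trochanter_height: float = 23.0
    trochanter_overhang: float = 5.0
    calcar_flare: float = 8.0
    ccd_angle: float = 130.0
    smoothing: int = 1

    _LENGTH_FIELDS = (
        "shaft_length",
        "shaft_width",
        "cortical_thickness",
        "metaphysis_height",
        "neck_length",
        "neck_width",
        "head_offset",
        "trochanter_height",
        "trochanter_overhang",
        "calcar_flare",
    )

    def scaled(self, factor: float) -> "FemurParams":
        """Scale every length by ``factor`` (angles untouched)."""
        return replace(self, **{f: getattr(self, f) * factor for f in self._LENGTH_FIELDS})

    def validate(self) -> None:
        for f in self._LENGTH_FIELDS:
            if getattr(self, f) <= 0.0:
                raise InvalidParameterError(f"{f} must be > 0")
        if not 110.0 <= self.ccd_angle <= 150.0:
            raise InvalidParameterError(
                f"ccd_angle {self.ccd_angle} outside the admissible range [110, 150] deg"
            )
        if self.cortical_thickness * 2.2 >= self.shaft_width:
            raise InvalidParameterError("cortical walls leave no medullary canal")


@dataclass(frozen=True)
class FemurGeometry:
    periosteal: Contour
    endosteal: Contour
    head_center: np.ndarray
    trochanter_apex: np.ndarray
    neck_axis_angle: float  # CCD-like angle, deg
    shaft_axis: np.ndarray  # unit vector, points proximally
    neck_axis: np.ndarray  # unit vector, points medio-proximally
    resection_point: np.ndarray
    params: FemurParams | None = None

    def __post_init__(self) -> None:
        if not 110.0 <= self.neck_axis_angle <= 150.0:
            raise InvalidParameterError("neck_axis_angle outside [110, 150] deg")
        if not self.periosteal.contains(self.endosteal):
            raise InvalidParameterError("endosteal contour must lie inside the periosteal contour")
        if not self.head_center[1] > self.trochanter_apex[1]:
            raise InvalidParameterError("head centre must lie proximal to the trochanter apex")

    def translated(self, offset) -> "FemurGeometry":
        off = np.asarray(offset, dtype=float)
        eye = np.eye(2)
        return replace(
            self,
            periosteal=self.periosteal.transformed(eye, off),
            endosteal=self.endosteal.transformed(eye, off),
            head_center=self.head_center + off,
            trochanter_apex=self.trochanter_apex + off,
            resection_point=self.resection_point + off,
        )


def build_femur_contour(params: FemurParams | None = None) -> FemurGeometry:
    """Construct the periosteal/endosteal contours and anatomical landmarks.

    The outline is a fixed sequence of control points derived linearly from
    the parameters, optionally rounded by Chaikin corner cutting; both steps
    are equivariant under uniform scaling of all length parameters.
    """
    p = params or FemurParams()
    p.validate()

    phi = math.radians(180.0 - p.ccd_angle)  # neck axis vs +y
    d = np.array([-math.sin(phi), math.cos(phi)])  # neck axis (medio-proximal)
    perp = np.array([math.cos(phi), math.sin(phi)])  # supero-lateral normal of the neck

    w = p.shaft_width / 2.0
    ys = p.shaft_length
    m_anchor = np.array([0.0, ys + p.metaphysis_height])
    resection = m_anchor + p.neck_length * d
    head = resection + p.head_offset * d
    hw = p.neck_width / 2.0
    r_lat = resection + hw * perp
    r_med = resection - hw * perp
    troch = np.array(
        [w + p.trochanter_overhang, ys + p.metaphysis_height + p.trochanter_height]
    )

    ctrl = [
        (w, 0.0),
        (w, 0.85 * ys),
        (w + 0.6 * p.trochanter_overhang, ys + 0.4 * p.metaphysis_height),
        (
            w + p.trochanter_overhang + 0.1 * p.shaft_width,
            ys + p.metaphysis_height + 0.45 * p.trochanter_height,
        ),
        tuple(troch),
        tuple(r_lat - 0.75 * p.neck_length * d),  # saddle on the superior neck line
        tuple(r_lat - 0.375 * p.neck_length * d),
        tuple(r_lat),
        tuple(resection),
        tuple(r_med),
        tuple(r_med - 0.4 * p.neck_length * d),  # calcar along the inferior neck line
        (-w - 0.5 * p.calcar_flare, ys + 0.25 * p.metaphysis_height),
        (-w, 0.8 * ys),
        (-w, 0.0),
    ]
    outline = np.array(ctrl, dtype=float)
    if p.smoothing > 0:
        # keep the distal cut and the resection edge sharp: smooth only the
        # lateral/medial runs between them
        outline = _chaikin_fixed(outline, p.smoothing, keep={0, 7, 8, 9, 13})
    periosteal = Contour(outline)

    inner = periosteal.polygon.buffer(
        -p.cortical_thickness, join_style="mitre", mitre_limit=8.0
    )
    if inner.geom_type == "MultiPolygon":
        inner = max(inner.geoms, key=lambda g: g.area)
    if inner.is_empty or inner.area <= 0.0:
        raise InvalidParameterError("cortical thickness swallows the whole section")
    endosteal = Contour(np.asarray(inner.exterior.coords)[:-1])

    return FemurGeometry(
        periosteal=periosteal,
        endosteal=endosteal,
        head_center=head,
        trochanter_apex=troch,
        neck_axis_angle=p.ccd_angle,
        shaft_axis=np.array([0.0, 1.0]),
        neck_axis=d,
        resection_point=resection,
        params=p,
    )


def _chaikin_fixed(pts: np.ndarray, iterations: int, keep: set[int]) -> np.ndarray:
    """Chaikin smoothing that pins selected control vertices."""
    tagged = [(tuple(pt), i in keep) for i, pt in enumerate(pts)]
    for _ in range(iterations):
        out = []
        n = len(tagged)
        for i, (pt, fixed) in enumerate(tagged):
            nxt, nxt_fixed = tagged[(i + 1) % n]
            a = np.asarray(pt)
            b = np.asarray(nxt)
            if fixed:
                out.append((pt, True))
            else:
                out.append((tuple(0.75 * a + 0.25 * b), False))
            if not (fixed and nxt_fixed) and not fixed and not nxt_fixed:
                out.append((tuple(0.25 * a + 0.75 * b), False))
        tagged = out
    return np.array([pt for pt, _ in tagged])


class StemType(enum.Enum):
    """Short-stem archetypes differing in length, taper and contact pattern."""

    PROXIMA = "proxima"  # shortest, lateral proximal flare
    COLLO_MIS = "collo_mis"  # slender, curved, neck-sparing
    MINIMA = "minima"  # longest, straight triple taper


@dataclass(frozen=True)
class StemParams:
    """Archetype dimensions (mm / deg).  Defaults depend on the stem type."""

    neck_angle: float = 130.0
    neck_length: float = 32.0
    neck_width: float = 22.0
    body_length: float = 50.0
    body_top_width: float = 16.0
    tip_width: float = 7.0
    lateral_flare: float = 0.0
    medial_bow: float = 0.0

    def validate(self) -> None:
        for name in ("neck_length", "neck_width", "body_length", "body_top_width", "tip_width"):
            if getattr(self, name) <= 0.0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.tip_width >= self.body_top_width:
            raise InvalidParameterError("stem must taper: tip_width < body_top_width")
        if not 110.0 <= self.neck_angle <= 150.0:
            raise InvalidParameterError("neck_angle outside [110, 150] deg")


_STEM_DEFAULTS: dict[StemType, StemParams] = {
    StemType.PROXIMA: StemParams(
        neck_length=30.0,
        neck_width=24.0,
        body_length=38.0,
        body_top_width=17.0,
        tip_width=8.0,
        lateral_flare=4.0,
    ),
    StemType.COLLO_MIS: StemParams(
        neck_length=34.0,
        neck_width=21.0,
        body_length=52.0,
        body_top_width=12.0,
        tip_width=6.0,
        medial_bow=3.0,
    ),
    StemType.MINIMA: StemParams(
        neck_length=32.0,
        neck_width=23.0,
        body_length=66.0,
        body_top_width=15.0,
        tip_width=5.0,
    ),
}


@dataclass(frozen=True)
class StemGeometry:
    """Stem contour in its local frame.

    The local origin is the anchor that coincides with the femoral
    ``resection_point`` at zero insertion depth; the body axis is the local
    +y direction and the tip is the contour point of minimal coordinate
    along it.
    """

    stem_type: StemType
    contour: Contour
    stem_axis: np.ndarray  # unit, points proximally along the body
    tip: np.ndarray
    length: float
    params: StemParams

    def __post_init__(self) -> None:
        if self.length <= 0.0:
            raise InvalidParameterError("stem length must be > 0")
        s = self.contour.vertices @ self.stem_axis
        if not math.isclose(float(s.min()), float(self.tip @ self.stem_axis), abs_tol=1e-9):
            raise InvalidParameterError("tip must be the contour point of minimal axial coordinate")


def build_stem_contour(stem_type: StemType | str, params: StemParams | None = None) -> StemGeometry:
    """Build one of the three stem archetypes in its local frame.

    The outline is generated by offsetting a two-segment centreline (neck
    segment along the neck axis, body segment along -y) by linearly
    interpolated half-widths, with the archetype-specific flare/bow applied.
    """
    if isinstance(stem_type, str):
        try:
            stem_type = StemType[stem_type.upper()]
        except KeyError as exc:
            raise InvalidParameterError(f"unknown stem type {stem_type!r}") from exc
    if not isinstance(stem_type, StemType):
        raise InvalidParameterError(f"unknown stem type {stem_type!r}")
    p = params or _STEM_DEFAULTS[stem_type]
    p.validate()

    phi = math.radians(180.0 - p.neck_angle)
    d = np.array([-math.sin(phi), math.cos(phi)])
    junction = -p.neck_length * d  # lateral-distal of the anchor
    tip_center = junction + np.array([0.0, -p.body_length])

    # stations along the centreline: (point, half_width, outward normal,
    # extra lateral flare); flare widens only the lateral side
    nrm_neck = np.array([math.cos(phi), math.sin(phi)])
    nrm_body = np.array([1.0, 0.0])
    stations = [
        (np.array([0.0, 0.0]), p.neck_width / 2.0, nrm_neck, 0.0),
        (
            0.55 * junction,
            0.5 * (p.neck_width + p.body_top_width) / 2.0,
            _unit(nrm_neck + nrm_body),
            0.25 * p.lateral_flare,
        ),
        (junction, p.body_top_width / 2.0, nrm_body, p.lateral_flare),
    ]
    n_body = 5
    for i in range(1, n_body + 1):
        t = i / n_body
        c = junction * (1 - t) + tip_center * t
        if p.medial_bow:
            c = c + np.array([-p.medial_bow * math.sin(math.pi * t), 0.0])
        hw = (p.body_top_width / 2.0) * (1 - t) + (p.tip_width / 2.0) * t
        flare = p.lateral_flare * max(0.0, 1.0 - 2.5 * t)
        stations.append((c, hw, nrm_body, flare))

    lateral, medial = [], []
    for c, hw, nrm, flare in stations:
        lateral.append(c + (hw + flare) * nrm)
        medial.append(c - hw * nrm)
    # rounded tip: single apex point below the last station
    apex = tip_center + np.array([0.0, -p.tip_width * 0.6])
    outline = lateral + [apex] + medial[::-1]
    contour = Contour(outline)

    s = contour.vertices @ np.array([0.0, 1.0])
    tip = contour.vertices[int(np.argmin(s))]
    return StemGeometry(
        stem_type=stem_type,
        contour=contour,
        stem_axis=np.array([0.0, 1.0]),
        tip=tip,
        length=p.neck_length + p.body_length,
        params=p,
    )


class Alignment(enum.Enum):
    VARUS = "varus"
    NEUTRAL = "neutral"
    VALGUS = "valgus"


@dataclass(frozen=True)
class PlacedStem:
    stem: StemGeometry
    alignment: Alignment
    alignment_angle: float  # deg, positive = varus (tip tilts laterally)
    pivot: np.ndarray
    contour: Contour  # stem contour in the femur frame after seating
    stem_axis: np.ndarray  # placed body axis (unit, proximal)
    tip: np.ndarray  # placed tip
    seat_depth: float  # insertion depth along the neck axis, mm

    def __post_init__(self) -> None:
        if (self.alignment is Alignment.NEUTRAL) != (self.alignment_angle == 0.0):
            raise InvalidParameterError("alignment_angle must be 0 iff alignment is NEUTRAL")


def _rotation(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s], [s, c]])


def place_stem(
    femur: FemurGeometry,
    stem: StemGeometry,
    alignment_angle: float = 0.0,
    *,
    max_depth: float = 30.0,
    clearance: float = 1.5,
) -> PlacedStem:
    """Rotate the stem about the resection point and seat it along the neck axis.

    Positive ``alignment_angle`` is varus (the tip tilts laterally), which in
    the CCW-positive frame is a clockwise rotation.  Seating pushes the stem
    distally along the (reversed) neck axis to the deepest insertion at which
    the contour still lies inside the periosteal contour, backed off by
    ``clearance`` mm.
    """
    if abs(alignment_angle) > 10.0:
        raise InvalidParameterError("|alignment_angle| must be <= 10 deg")

    # positive alignment = varus: the below-pivot tip tilts laterally (+x),
    # which for a point distal to the pivot is a CCW rotation in this frame
    rot = _rotation(alignment_angle)
    pivot = femur.resection_point
    base = stem.contour.vertices @ rot.T + pivot  # anchor at the resection point
    axis_rot = rot @ stem.stem_axis
    tip_local = rot @ stem.tip + pivot
    insert_dir = -femur.neck_axis

    bone = femur.periosteal.polygon.buffer(1e-9)
    canal = femur.endosteal.polygon.buffer(1e-9)
    shapely.prepare(bone)
    shapely.prepare(canal)

    def feasible(depth: float) -> bool:
        return bone.contains(Polygon(base + depth * insert_dir)) and canal.contains(
            Point(tip_local + depth * insert_dir)
        )

    # the feasible depths form one interval: too shallow and the slanted top
    # pokes out of the cut, too deep and the body penetrates the lateral
    # cortex; seat just past the shallow edge so the body stays centred
    step = 0.5
    coarse = np.arange(0.0, max_depth + step, step)
    flags = [feasible(t) for t in coarse]
    if not any(flags):
        raise PlacementError(
            f"no seating depth keeps the {stem.stem_type.value} stem inside the bone "
            f"at {alignment_angle:+.1f} deg"
        )
    first = min(i for i, ok in enumerate(flags) if ok)
    last = max(i for i, ok in enumerate(flags) if ok)

    def _bisect(lo: float, hi: float, want_inside_hi: bool) -> float:
        # shrink [lo, hi] keeping feasibility(hi side) == want_inside_hi
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if feasible(mid) == want_inside_hi:
                hi = mid
            else:
                lo = mid
        return hi

    if first == 0:
        d_lo = 0.0
    else:
        d_lo = _bisect(coarse[first - 1], coarse[first], True)
    if last == len(coarse) - 1:
        d_hi = coarse[last]
    else:
        d_hi = _bisect(coarse[last + 1], coarse[last], True)
    # seat mid-interval: the stem rests centred between the shallow limit
    # (top flush with the cut) and the deep limit (body against the cortex);
    # malalignment narrows the interval toward the contact side
    depth = max(0.5 * (d_lo + d_hi), min(d_lo + clearance, d_hi))
    if not feasible(depth):
        depth = 0.5 * (d_lo + d_hi)
    seated = Contour(base + depth * insert_dir)
    tip = tip_local + depth * insert_dir

    if alignment_angle > 0:
        alignment = Alignment.VARUS
    elif alignment_angle < 0:
        alignment = Alignment.VALGUS
    else:
        alignment = Alignment.NEUTRAL
    return PlacedStem(
        stem=stem,
        alignment=alignment,
        alignment_angle=float(alignment_angle),
        pivot=np.asarray(pivot, dtype=float),
        contour=seated,
        stem_axis=axis_rot,
        tip=tip,
        seat_depth=float(depth),
    )


@dataclass(frozen=True)
class ZoneMap:
    """Seven peri-implant bone regions (modified Gruen zones).

    1-3 run proximal-to-distal on the lateral side, 4 is the band distal to
    the stem tip, 5-7 run distal-to-proximal on the medial side.
    """

    zones: dict[int, shapely.geometry.base.BaseGeometry]
    bone: shapely.geometry.base.BaseGeometry

    def __post_init__(self) -> None:
        if set(self.zones) != set(range(1, 8)):
            raise InvalidParameterError("zone map must contain exactly zones 1..7")

    def zone_of(self, x: float, y: float) -> int | None:
        pt = Point(x, y)
        for zid, geom in self.zones.items():
            if geom.contains(pt):
                return zid
        return None


def partition_gruen_zones(
    femur: FemurGeometry,
    placed: PlacedStem,
    *,
    tip_band_factor: float = 1.0,
) -> ZoneMap:
    """Split the peri-implant bone into seven zones.

    Lateral and medial are separated by the placed stem axis; zones 1-3 and
    5-7 occupy proximal/middle/distal thirds of the stem span, and zone 4 is
    a band of ``tip_band_factor`` local stem widths distal to the tip.
    """
    bone = femur.periosteal.polygon.difference(placed.contour.polygon)
    axis = _unit(placed.stem_axis)
    perp = np.array([axis[1], -axis[0]])
    tip = placed.tip
    # orient 'perp' toward the lateral (trochanter) side
    if float((femur.trochanter_apex - tip) @ perp) < 0:
        perp = -perp

    verts = placed.contour.vertices
    s_vals = (verts - tip) @ axis
    reach = float(s_vals.max())
    if reach <= 0:
        raise InvalidParameterError("degenerate placed stem")
    # local stem width near the tip (max perpendicular spread of the distal third)
    distal = verts[s_vals < reach / 3.0]
    t_vals = (distal - tip) @ perp
    tip_width = float(t_vals.max() - t_vals.min())
    band = tip_band_factor * tip_width

    big = 10.0 * (reach + band + 100.0)

    def strip(s0: float, s1: float, t0: float, t1: float) -> Polygon:
        corners = [
            tip + s0 * axis + t0 * perp,
            tip + s1 * axis + t0 * perp,
            tip + s1 * axis + t1 * perp,
            tip + s0 * axis + t1 * perp,
        ]
        return Polygon(corners)

    thirds = [reach, 2.0 * reach / 3.0, reach / 3.0, 0.0]
    zones: dict[int, shapely.geometry.base.BaseGeometry] = {}
    for i in range(3):
        s_hi, s_lo = thirds[i], thirds[i + 1]
        zones[1 + i] = bone.intersection(strip(s_lo, s_hi, 0.0, big))  # lateral
        zones[7 - i] = bone.intersection(strip(s_lo, s_hi, -big, 0.0))  # medial
    zones[4] = bone.intersection(strip(-band, 0.0, -big, big))
    return ZoneMap(zones=zones, bone=bone)
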