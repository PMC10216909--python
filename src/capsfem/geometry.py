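"""Parametric capsule geometry, anatomical axes, and verification fixtures.

Patient-specific CT/MRI geometry is not available, so the capsule is emulated
as a triangulated surface of revolution-like tube spanning two rings: the
glenoid rim (with a labrum band at its edge) and the humeral insertion.
Elements are partitioned into the five capsule regions by their
circumferential clock position, following the clinical clock-face convention
(12 o'clock superior, 3 o'clock anterior on a right shoulder viewed from
lateral).

The local frame of the generated capsule is: +x anterior, +y superior, +z
lateral (pointing from the glenoid face toward the humerus).  For a right
shoulder these axes form a right-handed triad.

Closed-form verification fixtures (a flat membrane patch and a thin sphere)
are produced by ``make_fixture``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .materials import LABRUM, RegionMaterial, region_materials

__all__ = [
    "AnatomicalFrame",
    "CapsuleMesh",
    "ClockSector",
    "GeometryParams",
    "retroversion_angle",
    "build_anatomical_frame",
    "generate_capsule",
    "sector_nodes",
    "make_fixture",
    "rotate_about_axis",
    "clock_hours",
    "DEFAULT_REGION_SPANS",
    "external_rotation_axis",
]

#: Default angular extents of the five capsule regions, in clock hours
#: (start, end) running clockwise on the clock face.  The three inferior
#: ligamentous bands share the inferior half (3 to 9 o'clock through 6);
#: the antero-superior and posterior capsule split the superior half.
DEFAULT_REGION_SPANS: dict[str, tuple[float, float]] = {
    "antero_superior": (12.0, 3.0),
    "ab_ighl": (3.0, 5.0),
    "axillary_pouch": (5.0, 7.0),
    "pb_ighl": (7.0, 9.0),
    "posterior": (9.0, 12.0),
}


# ---------------------------------------------------------------------------
# Rotations and clock bookkeeping
# ---------------------------------------------------------------------------


def rotate_about_axis(points, axis, angle_rad, center=None):
    """Rodrigues rotation of ``points`` about ``axis`` through ``center``."""
    p = np.asarray(points, dtype=float)
    a = np.asarray(axis, dtype=float)
    na = np.linalg.norm(a)
    if na < 1e-12:
        raise ValueError("rotation axis is degenerate")
    a = a / na
    v = p if center is None else p - np.asarray(center, dtype=float)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rot = v * c + np.cross(np.broadcast_to(a, v.shape), v) * s + np.outer(
        np.atleast_2d(v) @ a, a
    ).reshape(v.shape) * (1.0 - c)
    if center is not None:
        rot = rot + np.asarray(center, dtype=float)
    return rot


def clock_hours(xy, handedness: str = "right") -> np.ndarray:
    """Clock hour in [0, 12) of in-plane points, 12 (=0) superior, 3 anterior.

    ``xy`` holds (anterior, superior) coordinates.  On a right shoulder
    viewed from lateral the hours run clockwise from superior (+y) through
    anterior (+x); a left shoulder mirrors the anterior direction.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    x = xy[:, 0] if handedness == "right" else -xy[:, 0]
    hours = (np.degrees(np.arctan2(x, xy[:, 1])) / 30.0) % 12.0
    return hours


@dataclass(frozen=True)
class ClockSector:
    """Clockwise arc on the glenoid clock face, e.g. 12 to 1 (antero-superior).

    Hours are taken modulo 12 (12 o'clock == 0); ``start == end`` after
    normalization denotes the full circle, matching the 0-12 idiom.
    """

    start_hour: float
    end_hour: float

    @property
    def span_hours(self) -> float:
        span = (self.end_hour - self.start_hour) % 12.0
        return 12.0 if span == 0.0 else span

    def contains(self, hours, tol: float = 1e-9) -> np.ndarray:
        h = np.asarray(hours, dtype=float) % 12.0
        delta = (h - self.start_hour) % 12.0
        span = self.span_hours
        if span >= 12.0 - tol:
            return np.ones_like(h, dtype=bool)
        # boundary-inclusive on both ends
        return (delta <= span + tol) | (delta >= 12.0 - tol)


# ---------------------------------------------------------------------------
# Anatomical frame
# ---------------------------------------------------------------------------


def retroversion_angle(bicipital_distance: float) -> float:
    """Humeral retroversion (degrees) from the bicipital distance (mm).

    Linear regression -2.33 * BD - 0.1; the negative sign denotes posterior
    angulation.
    """
    bd = float(bicipital_distance)
    if not np.isfinite(bd) or bd <= 0.0:
        raise ValueError(f"bicipital distance must be positive, got {bd!r}")
    return -2.33 * bd - 0.1


@dataclass(frozen=True)
class AnatomicalFrame:
    """Humeral rotation axes derived from epiphyseal-sphere landmarks."""

    rotation_center: np.ndarray
    humeral_axis: np.ndarray
    retroversion_axis: np.ndarray
    transepicondylar_axis: np.ndarray
    epiphyseal_radius: float
    retroversion_deg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("humeral_axis", "retroversion_axis", "transepicondylar_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a unit vector")
            object.__setattr__(self, name, v)
        object.__setattr__(
            self, "rotation_center", np.asarray(self.rotation_center, dtype=float)
        )
        if self.epiphyseal_radius <= 0.0:
            raise ValueError("epiphyseal radius must be positive")


def build_anatomical_frame(
    sphere_center,
    sphere_radius: float,
    humeral_axis,
    junction_line,
    bicipital_distance: float,
) -> AnatomicalFrame:
    """Construct humeral axes from the epiphyseal sphere and cartilage junction.

    The retroversion axis is perpendicular to the cartilage junction line
    within the transverse plane (the plane normal to the humeral axis through
    the sphere center); the trans-epicondylar axis is the retroversion axis
    rotated about the humeral axis by the retroversion angle.
    """
    c = np.asarray(sphere_center, dtype=float)
    a = np.asarray(humeral_axis, dtype=float)
    j = np.asarray(junction_line, dtype=float)
    if np.linalg.norm(a) < 1e-12 or np.linalg.norm(j) < 1e-12:
        raise ValueError("humeral axis and junction line must be non-degenerate")
    a = a / np.linalg.norm(a)
    j_proj = j - (j @ a) * a
    if np.linalg.norm(j_proj) < 1e-9 * np.linalg.norm(j):
        raise ValueError("junction line is collinear with the humeral axis")
    j_proj /= np.linalg.norm(j_proj)
    retro_axis = np.cross(j_proj, a)
    retro_axis /= np.linalg.norm(retro_axis)
    angle = retroversion_angle(bicipital_distance)
    te_axis = rotate_about_axis(retro_axis, a, np.radians(angle))
    te_axis = te_axis / np.linalg.norm(te_axis)
    return AnatomicalFrame(
        rotation_center=c,
        humeral_axis=a,
        retroversion_axis=retro_axis,
        transepicondylar_axis=te_axis,
        epiphyseal_radius=float(sphere_radius),
        retroversion_deg=angle,
    )


# ---------------------------------------------------------------------------
# Capsule mesh container
# ---------------------------------------------------------------------------


@dataclass
class CapsuleMesh:
    """Triangulated membrane surface with region labels and named node sets.

    ``nodes`` are (N, 3) coordinates in mm; ``triangles`` (E, 3) node index
    triples with consistent outward orientation; ``region_of_element`` string
    labels; ``thickness_of_element`` wall thickness in mm; ``node_sets`` maps
    names (``glenoid_ring``, ``humeral_ring``, ...) to node index arrays.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    region_of_element: np.ndarray
    thickness_of_element: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.region_of_element = np.asarray(self.region_of_element, dtype=object)
        self.thickness_of_element = np.asarray(self.thickness_of_element, dtype=float)
        self.node_sets = {
            k: np.asarray(v, dtype=np.int64) for k, v in self.node_sets.items()
        }

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def element_areas(self, nodes: np.ndarray | None = None) -> np.ndarray:
        x = self.nodes if nodes is None else nodes
        d1 = x[self.triangles[:, 1]] - x[self.triangles[:, 0]]
        d2 = x[self.triangles[:, 2]] - x[self.triangles[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(d1, d2), axis=1)

    def edge_counts(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for tri in self.triangles:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (min(a, b), max(a, b))
                counts[key] = counts.get(key, 0) + 1
        return counts

    def validate(self) -> None:
        if self.n_elements == 0 or self.n_nodes == 0:
            raise ValueError("mesh is empty")
        if self.triangles.min() < 0 or self.triangles.max() >= self.n_nodes:
            raise ValueError("triangle references an invalid node index")
        if len(self.region_of_element) != self.n_elements:
            raise ValueError("region label count does not match element count")
        if len(self.thickness_of_element) != self.n_elements:
            raise ValueError("thickness count does not match element count")
        if np.any(self.thickness_of_element <= 0.0):
            raise ValueError("element thicknesses must be positive")
        if np.any(self.element_areas() <= 0.0):
            raise ValueError("mesh contains zero-area triangles")
        bad = [e for e, c in self.edge_counts().items() if c > 2]
        if bad:
            raise ValueError(f"mesh is not edge-manifold: {len(bad)} bad edges")

    def regions(self) -> list[str]:
        seen: list[str] = []
        for r in self.region_of_element:
            if r not in seen:
                seen.append(r)
        return seen

    def elements_of_region(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.region_of_element == region)


# ---------------------------------------------------------------------------
# Capsule generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the synthetic capsule tube.

    Default dimensions are plausible adult values (glenoid rim ring 15 mm,
    humeral insertion ring 25 mm, 20 mm axial span, 3 mm outward bulge) and
    are configuration choices, not patient data.  ``n_circ`` x ``n_axial``
    is the structured resolution (2 * n_circ * n_axial triangles); the first
    axial element row at the glenoid edge forms the 4 mm labrum band.
    """

    glenoid_radius: float = 15.0
    humeral_radius: float = 25.0
    length: float = 20.0
    bulge: float = 3.0
    n_circ: int = 32
    n_axial: int = 8
    handedness: str = "right"
    region_spans: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_SPANS)
    )

    def __post_init__(self) -> None:
        if self.glenoid_radius <= 0 or self.humeral_radius <= 0:
            raise ValueError("ring radii must be positive")
        if self.length <= 0:
            raise ValueError("axial length must be positive")
        if self.n_circ < 8 or self.n_axial < 4:
            raise ValueError("resolution must be at least 8 x 4")
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")


def external_rotation_axis(params: GeometryParams) -> tuple[np.ndarray, np.ndarray]:
    """Default humeral rotation axis and center for external rotation.

    The humeral long axis at 90 degrees of abduction is inclined 60 degrees
    to the glenoid face normal (+z), tilted toward superior (+y).  The
    returned axis direction is oriented so that a POSITIVE rotation angle
    produces external rotation in its anatomical sense for this capsule
    abstraction — elongation of the anterior capsule, as in the apprehension
    position.  (On a straight tube without humeral-head wrap-around, that
    corresponds to the reversed sign of the literal right-handed shaft
    rotation; see the methods note.)
    """
    axis = -np.array([0.0, np.sin(np.radians(60.0)), np.cos(np.radians(60.0))])
    center = np.array([0.0, 0.0, 0.5 * params.length])
    return axis, center


def generate_capsule(
    params: GeometryParams | None = None,
    materials: Mapping[str, RegionMaterial] | None = None,
    rotation: np.ndarray | None = None,
) -> CapsuleMesh:
    """Generate the synthetic capsule tube between the glenoid and humeral rings.

    Elements are labelled by the clock hour of their centroid according to
    ``params.region_spans``; the first axial row is relabelled as the labrum
    band.  Per-element thickness comes from the regional material table.
    ``rotation`` optionally rigidly rotates the whole mesh (labels are
    assigned in the generator frame, so they rotate with the geometry).
    """
    if params is None:
        params = GeometryParams()
    if materials is None:
        materials = region_materials()
    nu, na = params.n_circ, params.n_axial

    t = np.arange(na + 1) / na
    radius = (
        (1.0 - t) * params.glenoid_radius
        + t * params.humeral_radius
        + params.bulge * np.sin(np.pi * t)
    )
    z = t * params.length
    alpha = 2.0 * np.pi * np.arange(nu) / nu  # clock angle from superior (+y)
    sx = 1.0 if params.handedness == "right" else -1.0
    x = sx * np.outer(np.ones(na + 1), np.sin(alpha)) * radius[:, None]
    y = np.outer(np.ones(na + 1), np.cos(alpha)) * radius[:, None]
    nodes = np.column_stack(
        [x.ravel(), y.ravel(), np.repeat(z, nu)]
    )

    def idx(i: int, j: int) -> int:
        return j * nu + (i % nu)

    tris = []
    hours = []
    rows = []
    for j in range(na):
        for i in range(nu):
            a, b = idx(i, j), idx(i + 1, j)
            c, d = idx(i, j + 1), idx(i + 1, j + 1)
            # outward orientation (normals point away from the joint cavity)
            tris.append((a, d, b))
            tris.append((a, c, d))
            h = (i + 0.5) * 12.0 / nu  # both triangles straddle the same strip
            hours.extend((h % 12.0, h % 12.0))
            rows.extend((j, j))
    triangles = np.array(tris, dtype=np.int64)
    hours = np.asarray(hours)
    rows = np.asarray(rows)

    region = np.empty(len(triangles), dtype=object)
    for name, (start, end) in params.region_spans.items():
        sector = ClockSector(start, end)
        # half-open on the end so adjacent spans do not double-claim a strip
        h = hours % 12.0
        delta = (h - (start % 12.0)) % 12.0
        mask = delta < sector.span_hours - 1e-9
        region[mask] = name
    if any(r is None for r in region):
        raise ValueError("region spans do not cover the full circumference")
    region[rows == 0] = LABRUM

    thickness = np.array([materials[r].thickness for r in region])

    node_sets = {
        "glenoid_ring": np.arange(nu, dtype=np.int64),
        "humeral_ring": np.arange(na * nu, (na + 1) * nu, dtype=np.int64),
    }
    if rotation is not None:
        rotation = np.asarray(rotation, dtype=float)
        nodes = nodes @ rotation.T

    mesh = CapsuleMesh(nodes, triangles, region, thickness, node_sets)
    mesh.validate()
    for name in list(params.region_spans) + [LABRUM]:
        if len(mesh.elements_of_region(name)) == 0:
            raise ValueError(f"region {name} is empty at this resolution")
    return mesh


def sector_nodes(
    mesh: CapsuleMesh,
    sector: ClockSector,
    ring: str = "glenoid_ring",
    handedness: str = "right",
) -> np.ndarray:
    """Nodes of a ring whose clock position falls inside ``sector``.

    Hours are measured in the ring's own plane about its centroid.  An empty
    selection means the mesh is too coarse for the sector and is an error.
    """
    if ring not in mesh.node_sets:
        raise ValueError(f"mesh has no node set named {ring!r}")
    ring_nodes = mesh.node_sets[ring]
    xy = mesh.nodes[ring_nodes, :2] - mesh.nodes[ring_nodes, :2].mean(axis=0)
    hours = clock_hours(xy, handedness=handedness)
    selected = ring_nodes[sector.contains(hours)]
    if len(selected) == 0:
        raise ValueError(
            f"sector {sector.start_hour}-{sector.end_hour} selects no nodes; "
            "mesh resolution is too coarse"
        )
    return selected


# ---------------------------------------------------------------------------
# Verification fixtures
# ---------------------------------------------------------------------------


def make_fixture(kind: str, **params) -> CapsuleMesh:
    """Closed-form verification meshes: ``flat_patch`` or ``thin_sphere``.

    flat_patch(n, size, thickness): structured n x n unit-square membrane in
    the z = 0 plane (2 n^2 triangles), single region ``patch``, node set
    ``boundary``.

    thin_sphere(radius, subdivisions, thickness): icosphere of uniform
    thickness, single region ``sphere``, outward-oriented, no ring sets.
    """
    if kind == "flat_patch":
        n = int(params.get("n", 4))
        size = float(params.get("size", 1.0))
        h = float(params.get("thickness", 1.0))
        if n < 1:
            raise ValueError("flat_patch needs n >= 1")
        g = np.linspace(0.0, size, n + 1)
        xx, yy = np.meshgrid(g, g, indexing="xy")
        nodes = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        tris = []
        for j in range(n):
            for i in range(n):
                a = j * (n + 1) + i
                b, c, d = a + 1, a + n + 1, a + n + 2
                tris.append((a, b, d))
                tris.append((a, d, c))
        triangles = np.array(tris, dtype=np.int64)
        boundary = np.flatnonzero(
            (np.isclose(nodes[:, 0], 0.0))
            | (np.isclose(nodes[:, 0], size))
            | (np.isclose(nodes[:, 1], 0.0))
            | (np.isclose(nodes[:, 1], size))
        )
        mesh = CapsuleMesh(
            nodes,
            triangles,
            np.array(["patch"] * len(triangles), dtype=object),
            np.full(len(triangles), h),
            {"boundary": boundary},
        )
    elif kind == "thin_sphere":
        import trimesh

        radius = float(params.get("radius", 10.0))
        k = int(params.get("subdivisions", 3))
        h = float(params.get("thickness", 0.1))
        ico = trimesh.creation.icosphere(subdivisions=k, radius=radius)
        mesh = CapsuleMesh(
            np.asarray(ico.vertices, dtype=float),
            np.asarray(ico.faces, dtype=np.int64),
            np.array(["sphere"] * len(ico.faces), dtype=object),
            np.full(len(ico.faces), h),
            {},
        )
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    mesh.validate()
    return mesh
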