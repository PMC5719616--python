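"""Synthetic lower-limb geometry, attachment patches and gait tables.

Generates the idealised anatomy the rest of the pipeline consumes: bone-like
capped tubes/frusta meshed with 4-node tetrahedra, named surface patches
standing in for muscle attachment areas, anatomical landmarks, a five-position
stance-phase gait table, and a subdivided muscle table.  Everything is
deterministic for a fixed seed and parameter set.

Units are fixed pipeline-wide: millimetres, newtons, megapascals
(1 MPa = 1 N/mm^2), kilograms and m/s^2, so that an inertial force
``mass * acceleration`` comes out directly in newtons.

Coordinate convention: ``y`` is vertical (distal->proximal, up positive),
``z`` postero-anterior (anterior positive), ``x`` medio-lateral.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MaterialSpec",
    "TetPartMesh",
    "BoneSpec",
    "PatchSpec",
    "GaitConfig",
    "GaitPosition",
    "gen_bone_mesh",
    "gen_box_mesh",
    "gen_attachment_patches",
    "patch_load_point",
    "gen_gait_table",
    "gen_muscle_table",
    "check_no_penetration",
    "build_limb",
    "DEFAULT_GRF_MAGNITUDES",
    "DEFAULT_KNEE_FLEXION",
    "THIGH_MASS",
    "LEG_FOOT_MASS",
]

# Default segment masses (kg) of the reference subject (62 kg body mass).
THIGH_MASS = 6.22
LEG_FOOT_MASS = 3.8

# Default ground-reaction-force magnitudes (N) at the five stance positions.
# The first peak is of the order of body weight; the value at the end of
# stance (toe-off) is near zero.
DEFAULT_GRF_MAGNITUDES = (253.0, 592.0, 483.0, 644.0, 15.0)

# Knee flexion angle (degrees) at the five positions.  Positions 4 and 5 are
# fixed by the reference gait trial (~14 deg at 50 % gait, 38 deg at 62 %);
# positions 1-3 are free configuration values.
DEFAULT_KNEE_FLEXION = (5.0, 15.0, 10.0, 14.0, 38.0)

# Default per-position acceleration-force components m*a (N) used to seed the
# segment accelerations; magnitudes are of the order of tens of newtons, small
# against the GRF, so the quasi-static premise holds by construction.
_DEFAULT_MA_THIGH = (
    (12.0, 4.0, 8.0),
    (-12.0, -4.0, -7.0),
    (-3.0, -11.0, -2.0),
    (12.0, 9.0, -7.0),
    (-15.0, 8.0, 2.0),
)
_DEFAULT_MA_LEG_FOOT = (
    (17.0, 13.0, -3.0),
    (-41.0, -10.0, 9.0),
    (4.0, -3.0, -4.0),
    (16.0, -1.0, -7.0),
    (30.0, -8.0, 2.0),
)


@dataclass(frozen=True)
class MaterialSpec:
    """Isotropic linear-elastic material: Young's modulus (MPa), Poisson ratio."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError(f"Poisson ratio must lie in [0, 0.5), got {self.nu}")


# Default material table: cortical bone, menisci, articular cartilage, tendon.
DEFAULT_MATERIALS = {
    "bone": MaterialSpec(17000.0, 0.3),
    "menisci": MaterialSpec(120.0, 0.45),
    "cartilage": MaterialSpec(15.0, 0.45),
    "tendon": MaterialSpec(900.0, 0.3),
}


class MeshError(ValueError):
    """Raised for invalid or degenerate mesh input."""


@dataclass
class TetPartMesh:
    """A named 4-node tetrahedral part with surface patches and landmarks.

    Attributes
    ----------
    name : part identifier (e.g. ``"femur"``).
    nodes : ``(n, 3)`` float array, coordinates in mm.
    tets : ``(m, 4)`` int array, 0-based connectivity with positive signed
        volume.
    patches : mapping patch name -> ``(k, 3)`` int array of boundary facets.
    landmarks : mapping landmark name -> 3-vector (mm).
    """

    name: str
    nodes: np.ndarray
    tets: np.ndarray
    patches: dict[str, np.ndarray] = field(default_factory=dict)
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    # -- geometry helpers -------------------------------------------------

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes of all tetrahedra (mm^3)."""
        x = self.nodes[self.tets]
        a, b, c = x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def boundary_facets(self) -> np.ndarray:
        """Boundary triangles (those appearing in exactly one tet), ``(k, 3)``."""
        faces = self.tets[:, [[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]]].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]

    def is_watertight(self) -> bool:
        """True when every boundary edge is shared by exactly two boundary facets."""
        bf = self.boundary_facets()
        edges = np.sort(bf[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def facet_areas(self, facets: np.ndarray) -> np.ndarray:
        p = self.nodes[facets]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def patch_area(self, patch: str) -> float:
        return float(self.facet_areas(self.patches[patch]).sum())

    def validate(self) -> None:
        """Check the part invariants; raise :class:`MeshError` on violation."""
        if not np.all(np.isfinite(self.nodes)):
            raise MeshError(f"{self.name}: non-finite node coordinates")
        vols = self.tet_volumes()
        if vols.size and vols.min() <= 0:
            raise MeshError(f"{self.name}: {int((vols <= 0).sum())} non-positive tets")
        boundary = {tuple(f) for f in np.sort(self.boundary_facets(), axis=1)}
        for pname, facets in self.patches.items():
            for f in np.sort(np.asarray(facets), axis=1):
                if tuple(f) not in boundary:
                    raise MeshError(f"{self.name}: patch {pname!r} facet off boundary")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TetPartMesh":
        """Return a rigidly moved copy (landmarks move with the part)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return TetPartMesh(
            name=self.name,
            nodes=self.nodes @ R.T + t,
            tets=self.tets.copy(),
            patches={k: v.copy() for k, v in self.patches.items()},
            landmarks={k: R @ v + t for k, v in self.landmarks.items()},
        )


@dataclass(frozen=True)
class BoneSpec:
    """Parameters of a bone-like capped hollow tube / frustum.

    ``taper`` scales both radii linearly from the distal (y=0) to the proximal
    (y=length) end, giving a frustum for values other than 1.
    """

    name: str
    length: float
    outer_radius: float
    inner_radius: float
    element_size: float
    taper: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.length, self.outer_radius, self.inner_radius, self.element_size) <= 0:
            raise MeshError(f"{self.name}: length, radii and element_size must be > 0")
        if self.inner_radius >= self.outer_radius:
            raise MeshError(
                f"{self.name}: inner radius {self.inner_radius} must be smaller "
                f"than outer radius {self.outer_radius}"
            )


# 6-tet decomposition of a hexahedron around the main diagonal v0-v6; the
# induced face diagonals conform between neighbouring grid cells.
_HEX_TO_TETS = (
    (0, 1, 2, 6),
    (0, 2, 3, 6),
    (0, 3, 7, 6),
    (0, 7, 4, 6),
    (0, 4, 5, 6),
    (0, 5, 1, 6),
)


def _hexes_to_tets(hexes: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    tets = hexes[:, _HEX_TO_TETS].reshape(-1, 4)
    x = nodes[tets]
    vol = np.einsum(
        "ij,ij->i", x[:, 1] - x[:, 0], np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 0])
    )
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    return tets


def gen_bone_mesh(spec: BoneSpec, seed: int = 0) -> TetPartMesh:
    """Generate a capped hollow-tube tet mesh with end landmarks.

    The tube axis runs along +y from ``spec.origin`` (distal end) to
    ``origin + (0, length, 0)`` (proximal end).  Landmarks ``distal_end`` and
    ``proximal_end`` are placed on the axis ends.  Generation is fully
    deterministic; the seed is accepted for interface symmetry with the other
    generators and reserved for optional perturbations.
    """
    del seed  # generation is deterministic by construction
    L, ro, ri, h = spec.length, spec.outer_radius, spec.inner_radius, spec.element_size
    nz = max(2, int(round(L / h)))
    nr = max(1, int(round((ro - ri) / h)))
    nt = max(8, int(round(2.0 * np.pi * ro / h)))

    zs = np.linspace(0.0, L, nz + 1)
    rs = np.linspace(ri, ro, nr + 1)
    thetas = 2.0 * np.pi * np.arange(nt) / nt

    iz, ir, it = np.meshgrid(
        np.arange(nz + 1), np.arange(nr + 1), np.arange(nt), indexing="ij"
    )
    scale = 1.0 + (spec.taper - 1.0) * zs[iz] / L
    r = rs[ir] * scale
    nodes = np.stack(
        [r * np.cos(thetas[it]), zs[iz] + 0.0 * r, r * np.sin(thetas[it])], axis=-1
    ).reshape(-1, 3)
    nodes += np.asarray(spec.origin, float)

    def nid(izv, irv, itv):
        return (izv * (nr + 1) + irv) * nt + (itv % nt)

    hexes = []
    for kz in range(nz):
        for kr in range(nr):
            for kt in range(nt):
                hexes.append(
                    [
                        nid(kz, kr, kt),
                        nid(kz, kr, kt + 1),
                        nid(kz, kr + 1, kt + 1),
                        nid(kz, kr + 1, kt),
                        nid(kz + 1, kr, kt),
                        nid(kz + 1, kr, kt + 1),
                        nid(kz + 1, kr + 1, kt + 1),
                        nid(kz + 1, kr + 1, kt),
                    ]
                )
    tets = _hexes_to_tets(np.asarray(hexes, dtype=np.int64), nodes)

    origin = np.asarray(spec.origin, float)
    mesh = TetPartMesh(
        name=spec.name,
        nodes=nodes,
        tets=tets,
        landmarks={
            "distal_end": origin.copy(),
            "proximal_end": origin + np.array([0.0, L, 0.0]),
        },
    )
    mesh.validate()
    return mesh


def gen_box_mesh(
    name: str,
    lengths: tuple[float, float, float],
    divisions: tuple[int, int, int],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> TetPartMesh:
    """Structured tet mesh of an axis-aligned box (verification fixture)."""
    lx, ly, lz = lengths
    nx, ny, nz = divisions
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X, Y, Z], axis=-1).reshape(-1, 3) + np.asarray(origin, float)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    hexes = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                hexes.append(
                    [
                        nid(i, j, k),
                        nid(i + 1, j, k),
                        nid(i + 1, j + 1, k),
                        nid(i, j + 1, k),
                        nid(i, j, k + 1),
                        nid(i + 1, j, k + 1),
                        nid(i + 1, j + 1, k + 1),
                        nid(i, j + 1, k + 1),
                    ]
                )
    tets = _hexes_to_tets(np.asarray(hexes, dtype=np.int64), nodes)
    mesh = TetPartMesh(name=name, nodes=nodes, tets=tets)
    mesh.validate()
    return mesh


@dataclass(frozen=True)
class PatchSpec:
    """Selector for an attachment patch: boundary facets whose centroid lies
    within ``radius`` of ``center`` (then restricted to the edge-connected
    component nearest the centre).  An optional outward ``normal`` direction
    with ``max_angle_deg`` restricts the selection to similarly oriented
    facets — e.g. an end-cap annulus without the adjacent wall."""

    name: str
    center: tuple[float, float, float]
    radius: float
    normal: tuple[float, float, float] | None = None
    max_angle_deg: float = 60.0


def gen_attachment_patches(mesh: TetPartMesh, patch_specs: list[PatchSpec]) -> TetPartMesh:
    """Attach named boundary patches to ``mesh`` (returned mesh is the input).

    Each patch is a non-empty, edge-connected set of boundary facets.  An empty
    selection raises with the offending patch name.
    """
    boundary = mesh.boundary_facets()
    pts = mesh.nodes[boundary]
    centroids = pts.mean(axis=1)
    normals = np.cross(pts[:, 1] - pts[:, 0], pts[:, 2] - pts[:, 0])
    normals /= np.linalg.norm(normals, axis=1)[:, None]
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    for ps in patch_specs:
        c = np.asarray(ps.center, float)
        if np.any(c < lo - ps.radius) or np.any(c > hi + ps.radius):
            raise MeshError(
                f"patch {ps.name!r}: centre {ps.center} lies outside the mesh "
                f"bounding box of part {mesh.name!r}"
            )
        keep = np.linalg.norm(centroids - c, axis=1) <= ps.radius
        if ps.normal is not None:
            n = np.asarray(ps.normal, float)
            n /= np.linalg.norm(n)
            keep &= normals @ n >= np.cos(np.deg2rad(ps.max_angle_deg))
        sel = np.where(keep)[0]
        if sel.size == 0:
            raise MeshError(
                f"patch {ps.name!r}: no boundary facets within {ps.radius} mm "
                f"of {ps.center} on part {mesh.name!r}"
            )
        mesh.patches[ps.name] = boundary[_connected_component(boundary, centroids, sel, c)]
    return mesh


def _connected_component(
    boundary: np.ndarray, centroids: np.ndarray, sel: np.ndarray, center: np.ndarray
) -> np.ndarray:
    """Edge-connected component of the selected facets nearest ``center``."""
    sel_set = set(int(s) for s in sel)
    edge_map: dict[tuple[int, int], list[int]] = {}
    for fi in sel:
        f = boundary[fi]
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edge_map.setdefault((min(a, b), max(a, b)), []).append(int(fi))
    start = int(sel[np.argmin(np.linalg.norm(centroids[sel] - center, axis=1))])
    comp, stack = {start}, [start]
    while stack:
        fi = stack.pop()
        f = boundary[fi]
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            for nb in edge_map.get((min(a, b), max(a, b)), ()):
                if nb in sel_set and nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
    return np.array(sorted(comp), dtype=np.int64)


def patch_load_point(mesh: TetPartMesh, patch: str) -> np.ndarray:
    """Equivalent application point of a uniform traction on the patch.

    Area-weighted mean of facet centroids: a uniform traction integrated with
    linear shape functions is statically equivalent to the total force acting
    at this point.
    """
    facets = mesh.patches[patch]
    areas = mesh.facet_areas(facets)
    centroids = mesh.nodes[facets].mean(axis=1)
    return (areas[:, None] * centroids).sum(axis=0) / areas.sum()


# ---------------------------------------------------------------------------
# Gait table
# ---------------------------------------------------------------------------


@dataclass
class GaitPosition:
    """One analysed stance instant."""

    index: int
    pct_gait: float
    knee_flexion: float  # degrees
    grf: np.ndarray  # N, 3-vector (force of the ground on the foot)
    cop: np.ndarray  # mm, 3-point (centre of pressure)
    segment_accel: dict[str, np.ndarray]  # m/s^2 per segment
    active_muscles: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class GaitConfig:
    """Configuration of the synthetic five-position stance-phase table."""

    body_mass: float = 62.0  # kg
    thigh_mass: float = THIGH_MASS
    leg_foot_mass: float = LEG_FOOT_MASS
    grf_magnitudes: tuple[float, ...] = DEFAULT_GRF_MAGNITUDES
    knee_flexion: tuple[float, ...] = DEFAULT_KNEE_FLEXION
    pct_gait: tuple[float, ...] = (2.0, 15.0, 30.0, 50.0, 62.0)
    # transverse direction fractions of the GRF (medio-lateral, postero-anterior)
    grf_dir_x: tuple[float, ...] = (0.05, 0.06, 0.05, 0.06, 0.05)
    grf_dir_z: tuple[float, ...] = (-0.17, -0.10, 0.02, 0.15, 0.20)
    # COP track under the foot, heel to toe (mm, model frame)
    cop_y: float = -20.0
    cop_z: tuple[float, ...] = (-40.0, -20.0, 0.0, 25.0, 45.0)
    accel_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError(f"body mass must be positive, got {self.body_mass}")


def gen_gait_table(config: GaitConfig = GaitConfig(), seed: int = 0) -> list[GaitPosition]:
    """Five stance positions with GRF, COP and segment accelerations.

    Accelerations are scaled so that every inertial force magnitude stays of
    the order of tens of newtons; over positions with appreciable ground
    contact the inertial-to-GRF ratio is <= 0.10 by construction, which is the
    quasi-static premise of the downstream static analyses.
    """
    del seed  # the default table is deterministic
    positions = []
    for i in range(5):
        mag = config.grf_magnitudes[i]
        d = np.array([config.grf_dir_x[i], 1.0, config.grf_dir_z[i]])
        d /= np.linalg.norm(d)
        accel = {
            "thigh": config.accel_scale
            * np.asarray(_DEFAULT_MA_THIGH[i], float)
            / config.thigh_mass,
            "leg_foot": config.accel_scale
            * np.asarray(_DEFAULT_MA_LEG_FOOT[i], float)
            / config.leg_foot_mass,
        }
        positions.append(
            GaitPosition(
                index=i + 1,
                pct_gait=config.pct_gait[i],
                knee_flexion=config.knee_flexion[i],
                grf=mag * d,
                cop=np.array([0.0, config.cop_y, config.cop_z[i]]),
                segment_accel=accel,
            )
        )
    return positions


# ---------------------------------------------------------------------------
# Penetration check
# ---------------------------------------------------------------------------


def _points_in_tets(points: np.ndarray, mesh: TetPartMesh) -> np.ndarray:
    """Boolean mask: which points lie strictly inside some tet of ``mesh``."""
    from scipy.spatial import cKDTree

    if points.size == 0 or mesh.tets.size == 0:
        return np.zeros(len(points), dtype=bool)
    cent = mesh.nodes[mesh.tets].mean(axis=1)
    x = mesh.nodes[mesh.tets]
    rad = np.linalg.norm(x - cent[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(cent)
    rmax = rad.max()
    inside = np.zeros(len(points), dtype=bool)
    for pi, p in enumerate(points):
        for ti in tree.query_ball_point(p, rmax * 1.001):
            if np.linalg.norm(p - cent[ti]) > rad[ti]:
                continue
            v = mesh.nodes[mesh.tets[ti]]
            T = np.column_stack([v[1] - v[0], v[2] - v[0], v[3] - v[0]])
            try:
                lam = np.linalg.solve(T, p - v[0])
            except np.linalg.LinAlgError:
                continue
            # solid inclusion with tolerance: points on internal element
            # faces count as inside; the depth filter excludes the surface
            if lam.min() > -1e-9 and lam.sum() < 1.0 + 1e-9:
                inside[pi] = True
                break
    return inside


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> float:
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    n = np.cross(ab, ac)
    nn = n / np.linalg.norm(n)
    # project into the triangle plane, clamp barycentrically
    d = ap @ nn
    q = p - d * nn
    # barycentric coordinates of q
    m = np.array([[ab @ ab, ab @ ac], [ab @ ac, ac @ ac]])
    rhs = np.array([ab @ (q - a), ac @ (q - a)])
    try:
        uv = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError:
        uv = np.array([-1.0, -1.0])
    u, v = uv
    if u >= 0 and v >= 0 and u + v <= 1:
        return abs(d)
    # otherwise nearest point lies on an edge
    best = np.inf
    for s, e in ((a, b), (b, c), (c, a)):
        t = np.clip((p - s) @ (e - s) / ((e - s) @ (e - s)), 0.0, 1.0)
        best = min(best, float(np.linalg.norm(p - (s + t * (e - s)))))
    return best


@dataclass
class PenetrationReport:
    """Nodes of each mesh strictly inside the other, deeper than ``tol``."""

    nodes_a_in_b: np.ndarray
    nodes_b_in_a: np.ndarray
    tol: float

    @property
    def empty(self) -> bool:
        return self.nodes_a_in_b.size == 0 and self.nodes_b_in_a.size == 0


def check_no_penetration(
    mesh_a: TetPartMesh, mesh_b: TetPartMesh, tol: float = 0.01
) -> PenetrationReport:
    """Report inter-penetrating nodes between two assembled parts.

    A node counts as penetrating when it lies strictly inside the other part
    and its distance to that part's boundary surface exceeds ``tol`` (mm).
    An empty report means the assembly is acceptable.
    """

    def one_way(src: TetPartMesh, dst: TetPartMesh) -> np.ndarray:
        from scipy.spatial import cKDTree

        inside = _points_in_tets(src.nodes, dst)
        idx = np.where(inside)[0]
        if idx.size == 0:
            return idx
        bf = dst.boundary_facets()
        cent = dst.nodes[bf].mean(axis=1)
        tree = cKDTree(cent)
        k = min(24, len(bf))
        deep = []
        for i in idx:
            _d, near = tree.query(src.nodes[i], k=k)
            near = np.atleast_1d(near)
            dmin = min(
                _point_triangle_distance(src.nodes[i], dst.nodes[bf[j]]) for j in near
            )
            if dmin > tol:
                deep.append(i)
        return np.asarray(deep, dtype=np.int64)

    return PenetrationReport(one_way(mesh_a, mesh_b), one_way(mesh_b, mesh_a), tol)


# ---------------------------------------------------------------------------
# Muscle table and the assembled synthetic limb
# ---------------------------------------------------------------------------

# The 29 lower-limb muscles spanning hip and/or knee.  Each entry:
# (muscle, origin part, insertion part, number of elements).  The adductor
# magnus and adductor brevis are further split into three recombination groups
# (distal/mid/proximal) each, so recombining all elements yields
# 27 + 2*3 = 33 applied forces; element counts sum to 122.
_MUSCLE_PLAN: list[tuple[str, str, str, int]] = [
    ("GluteusMaximus", "pelvis", "femur", 6),
    ("GluteusMedius", "pelvis", "femur", 6),
    ("GluteusMinimus", "pelvis", "femur", 6),
    ("Iliacus", "pelvis", "femur", 6),
    ("Piriformis", "pelvis", "femur", 2),
    ("Pectineus", "pelvis", "femur", 2),
    ("ObturatorInternus", "pelvis", "femur", 2),
    ("ObturatorExternus", "pelvis", "femur", 2),
    ("GemellusInferior", "pelvis", "femur", 2),
    ("GemellusSuperior", "pelvis", "femur", 2),
    ("QuadratusFemoris", "pelvis", "femur", 2),
    ("AdductorLongus", "pelvis", "femur", 4),
    ("AdductorBrevis", "pelvis", "femur", 6),  # 3 groups x 2 elements
    ("AdductorMagnus", "pelvis", "femur", 12),  # 3 groups x 4 elements
    ("TensorFasciaeLatae", "pelvis", "tibia", 2),
    ("Sartorius", "pelvis", "tibia", 2),
    ("Gracilis", "pelvis", "tibia", 2),
    ("BicepsFemorisCaputLongum", "pelvis", "fibula", 4),
    ("BicepsFemorisCaputBreve", "femur", "fibula", 4),
    ("Semimembranosus", "pelvis", "tibia", 4),
    ("Semitendinosus", "pelvis", "tibia", 4),
    ("RectusFemoris", "pelvis", "patella", 6),
    ("VastusIntermedius", "femur", "patella", 8),
    ("VastusLateralis", "femur", "patella", 8),
    ("VastusMedialis", "femur", "patella", 8),
    ("Popliteus", "femur", "tibia", 2),
    ("Plantaris", "femur", "calcaneus", 2),
    ("GastrocnemiusMedialis", "femur", "calcaneus", 3),
    ("GastrocnemiusLateralis", "femur", "calcaneus", 3),
]

_SUBDIVIDED = {"AdductorBrevis": 3, "AdductorMagnus": 3}


def muscle_group_names() -> list[str]:
    """The 33 recombination-group (output-slot) names."""
    names = []
    for muscle, _o, _i, _n in _MUSCLE_PLAN:
        if muscle in _SUBDIVIDED:
            names.extend(f"{muscle}{part}" for part in ("Distal", "Mid", "Proximal"))
        else:
            names.append(muscle)
    return names


# Angular placement (degrees, 0 = +x lateral, 90 = +z anterior) and height
# fractions used to lay the synthetic attachment sites around the bones.
_PLACEMENT: dict[str, tuple[float, float, float, float]] = {
    # muscle: (origin angle, origin height frac, insertion angle, insertion frac)
    # convention: 0 deg = +x (medial), 90 deg = +z (anterior), 180 = lateral,
    # 270 = posterior; insertion fractions run distal (0) to proximal (1)
    "GluteusMaximus": (215.0, 0.0, 225.0, 0.80),
    "GluteusMedius": (180.0, 0.0, 185.0, 0.93),
    "GluteusMinimus": (160.0, 0.0, 170.0, 0.90),
    "Iliacus": (60.0, 0.0, 315.0, 0.82),
    "Piriformis": (200.0, 0.0, 195.0, 0.92),
    "Pectineus": (35.0, 0.0, 330.0, 0.72),
    "ObturatorInternus": (250.0, 0.0, 205.0, 0.91),
    "ObturatorExternus": (280.0, 0.0, 215.0, 0.89),
    "GemellusInferior": (240.0, 0.0, 200.0, 0.90),
    "GemellusSuperior": (230.0, 0.0, 190.0, 0.915),
    "QuadratusFemoris": (300.0, 0.0, 235.0, 0.85),
    "AdductorLongus": (20.0, 0.0, 10.0, 0.55),
    "AdductorBrevis": (30.0, 0.0, 20.0, 0.70),
    "AdductorMagnus": (355.0, 0.0, 350.0, 0.40),
    "TensorFasciaeLatae": (150.0, 0.0, 160.0, 0.85),
    "Sartorius": (75.0, 0.0, 40.0, 0.80),
    "Gracilis": (10.0, 0.0, 25.0, 0.82),
    "BicepsFemorisCaputLongum": (260.0, 0.0, 250.0, 0.95),
    "BicepsFemorisCaputBreve": (255.0, 0.45, 250.0, 0.95),
    "Semimembranosus": (310.0, 0.0, 320.0, 0.85),
    "Semitendinosus": (320.0, 0.0, 335.0, 0.80),
    "RectusFemoris": (85.0, 0.0, 90.0, 0.5),
    "VastusIntermedius": (90.0, 0.60, 90.0, 0.5),
    "VastusLateralis": (130.0, 0.55, 90.0, 0.5),
    "VastusMedialis": (50.0, 0.55, 90.0, 0.5),
    "Popliteus": (300.0, 0.04, 280.0, 0.92),
    "Plantaris": (265.0, 0.06, 270.0, 0.0),
    "GastrocnemiusMedialis": (295.0, 0.03, 270.0, 0.0),
    "GastrocnemiusLateralis": (245.0, 0.03, 270.0, 0.0),
}


@dataclass(frozen=True)
class LimbConfig:
    """Geometry of the synthetic limb column (mm).

    The default proportions are deliberately stubby (length-to-radius ratio
    well below anatomical): the column is stiff in bending, so the elastic
    share of the model deformation stays small and the response is dominated
    by the rigid rotation about the femoral head that the weak stabilisation
    springs permit — the regime the full-anatomy model operates in.
    """

    femur_length: float = 220.0
    tibia_length: float = 200.0
    soft_length: float = 30.0
    outer_radius: float = 40.0
    inner_radius: float = 28.0
    element_size: float = 11.0
    fibula_length: float = 170.0
    fibula_outer_radius: float = 9.0
    fibula_inner_radius: float = 5.0
    fibula_offset_x: float = -55.0
    patella_size: float = 22.0
    patella_offset_z: float = 52.0
    pelvis_ring_radius: float = 50.0
    pelvis_ring_height: float = 60.0
    # default per-element muscle strength (N); the recruitment targets never
    # depend on its value, only feasibility does
    element_strength: float = 2500.0
    # horizontal spread (mm) of the rigid-stage element attachment points
    # around the patch load point; emulates the finite extent of real
    # attachment areas.  For muscles with off-model origins the spread has a
    # coherent sagittal bias, which leaves a small unbalanced moment for the
    # stabilisation springs to carry — the mechanism that rocks the model
    # about the femoral head.
    attachment_spread: float = 8.0


def gen_muscle_table(limb: "SyntheticLimb", config: LimbConfig, seed: int = 0):
    """Deferred to :func:`build_limb`; kept as a named entry point."""
    return limb.muscles


def build_limb(
    config: LimbConfig = LimbConfig(), flexion_deg: float = 0.0, seed: int = 0
) -> "SyntheticLimb":
    """Assemble the synthetic lower limb for one knee-flexion angle.

    The femur, a bonded soft interface layer and the tibia form a conforming
    stacked column (coincident node rings at the interfaces, so bonded contact
    can be realised by node merging).  The tibia, fibula and patella are
    rotated about the knee flexion axis (x, through the knee centre); the soft
    layer interpolates between the femur's horizontal distal ring and the
    rotated tibial proximal ring so the interface stays conforming.  Muscle
    elements, attachment patches, landmarks and remote-point anchors are laid
    out on the posed geometry.
    """
    from .rigid_statics import MuscleElement

    c = config
    phi = np.deg2rad(flexion_deg)
    knee_center = np.array([0.0, c.tibia_length + c.soft_length / 2.0, 0.0])
    Rx = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, np.cos(phi), -np.sin(phi)],
            [0.0, np.sin(phi), np.cos(phi)],
        ]
    )

    def pose_leg(p: np.ndarray) -> np.ndarray:
        return Rx @ (p - knee_center) + knee_center

    femur = gen_bone_mesh(
        BoneSpec(
            "femur",
            c.femur_length,
            c.outer_radius,
            c.inner_radius,
            c.element_size,
            origin=(0.0, c.tibia_length + c.soft_length, 0.0),
        )
    )
    tibia0 = gen_bone_mesh(
        BoneSpec("tibia", c.tibia_length, c.outer_radius, c.inner_radius, c.element_size)
    )
    tibia = tibia0.transformed(Rx, knee_center - Rx @ knee_center)

    soft = _soft_layer(femur, tibia0, tibia, c)

    fib0 = gen_bone_mesh(
        BoneSpec(
            "fibula",
            c.fibula_length,
            c.fibula_outer_radius,
            c.fibula_inner_radius,
            c.element_size * 0.8,
            origin=(c.fibula_offset_x, 20.0, 0.0),
        )
    )
    fibula = fib0.transformed(Rx, knee_center - Rx @ knee_center)

    pat0 = gen_bone_mesh(
        BoneSpec(
            "patella",
            c.patella_size,
            c.patella_size / 2.2,
            c.patella_size / 4.5,
            c.element_size * 0.6,
            origin=(0.0, c.tibia_length + c.soft_length + 8.0, c.patella_offset_z),
        )
    )
    patella = pat0  # the patella tracks the femoral groove

    # landmarks
    top = c.tibia_length + c.soft_length + c.femur_length
    femur.landmarks.update(
        {
            "femoral_head_center": np.array([0.0, top, 0.0]),
            "lateral_epicondyle": np.array(
                [-c.outer_radius, c.tibia_length + c.soft_length + 10.0, 0.0]
            ),
            "medial_epicondyle": np.array(
                [c.outer_radius, c.tibia_length + c.soft_length + 10.0, 0.0]
            ),
        }
    )
    tibia.landmarks.update(
        {
            "medial_malleolus": pose_leg(np.array([c.outer_radius, 2.0, 0.0])),
            "tibial_tuberosity": pose_leg(
                np.array([0.0, 0.82 * c.tibia_length, c.outer_radius])
            ),
            "cop_anchor": pose_leg(np.array([0.0, -20.0, 0.0])),
            "calcaneus_anchor": pose_leg(np.array([0.0, -10.0, -40.0])),
            # separated anchors of the three stabilisation springs on the
            # distal rim: no rigid-body mode escapes all three
            "stab_anchor_x": pose_leg(np.array([0.0, 2.0, c.outer_radius])),
            "stab_anchor_y": pose_leg(np.array([-c.outer_radius, 2.0, 0.0])),
            "stab_anchor_z": pose_leg(np.array([c.outer_radius, 2.0, 0.0])),
        }
    )

    parts = {m.name: m for m in (femur, soft, tibia, fibula, patella)}

    # functional patches
    ro = c.outer_radius
    gen_attachment_patches(
        femur,
        [PatchSpec("head", (0.0, top, 0.0), ro * 1.4)],
    )
    gen_attachment_patches(
        tibia,
        [
            PatchSpec("distal_end", tuple(pose_leg(np.array([0.0, 0.0, 0.0]))), ro * 1.4),
            PatchSpec(
                "tuberosity",
                tuple(pose_leg(np.array([0.0, 0.82 * c.tibia_length, ro]))),
                14.0,
            ),
        ],
    )
    gen_attachment_patches(
        patella,
        [
            PatchSpec(
                "tendon_distal",
                tuple(patella.landmarks["distal_end"]),
                c.patella_size / 1.8,
            )
        ],
    )

    # muscle attachment patches + elements
    rng = np.random.default_rng(seed)
    del rng  # layout is deterministic; generator kept for future perturbations
    muscles: list[MuscleElement] = []
    pelvis_points: dict[str, np.ndarray] = {}
    hip = femur.landmarks["femoral_head_center"]

    def ring_point(part: TetPartMesh, cfg_r: float, ang_deg: float, y: float) -> np.ndarray:
        a = np.deg2rad(ang_deg)
        return np.array([cfg_r * np.cos(a), y, cfg_r * np.sin(a)])

    def surface_patch(part: TetPartMesh, pname: str, ang_deg: float, frac: float, radius: float):
        if pname in part.patches:
            return
        if part.name == "femur":
            y0, length, r = c.tibia_length + c.soft_length, c.femur_length, c.outer_radius
            center = ring_point(part, r, ang_deg, y0 + frac * length)
        elif part.name == "tibia":
            center = pose_leg(ring_point(part, c.outer_radius, ang_deg, frac * c.tibia_length))
        elif part.name == "fibula":
            center = pose_leg(
                ring_point(part, c.fibula_outer_radius, ang_deg, 20.0 + frac * c.fibula_length)
                + np.array([c.fibula_offset_x, 0.0, 0.0])
            )
        elif part.name == "patella":
            base = patella.landmarks["distal_end"]
            center = base + np.array([0.0, frac * c.patella_size, 0.0])
        else:
            raise MeshError(f"no surface layout for part {part.name!r}")
        gen_attachment_patches(part, [PatchSpec(pname, tuple(center), radius)])

    n_groups = len(muscle_group_names())
    spread_dirs = [
        np.array([np.cos(a), 0.0, np.sin(a)])
        for a in np.linspace(0.0, 2 * np.pi, 8, endpoint=False)
    ]

    for mi, (muscle, opart, ipart, nelem) in enumerate(_MUSCLE_PLAN):
        oang, ofrac, iang, ifrac = _PLACEMENT[muscle]
        groups = (
            [f"{muscle}{g}" for g in ("Distal", "Mid", "Proximal")]
            if muscle in _SUBDIVIDED
            else [muscle]
        )
        per_group = nelem // len(groups)
        for gi, group in enumerate(groups):
            # origin
            if opart == "pelvis":
                a = np.deg2rad(oang + 8.0 * gi)
                origin_pt = hip + np.array(
                    [
                        c.pelvis_ring_radius * np.cos(a),
                        c.pelvis_ring_height,
                        c.pelvis_ring_radius * np.sin(a),
                    ]
                )
                pelvis_points[group] = origin_pt
                origin = ("pelvis", origin_pt)
            else:
                pname = f"{group}_origin"
                surface_patch(parts[opart], pname, oang, ofrac + 0.02 * gi, 14.0)
                origin = (opart, patch_load_point(parts[opart], pname))
            # insertion
            if ipart == "calcaneus":
                insertion = ("calcaneus", tibia.landmarks["calcaneus_anchor"])
            else:
                pname = f"{group}_insertion"
                surface_patch(parts[ipart], pname, iang, ifrac + 0.02 * gi, 14.0)
                insertion = (ipart, patch_load_point(parts[ipart], pname))
            # coherent sagittal bias of the attachment centroid for
            # off-model-origin muscles: the element points sit slightly off
            # the uniform-traction load point along the muscle's horizontal
            # direction, signed so the unbalanced moments accumulate about +x
            # (sagittal rocking) while the axial (y) moment error of each
            # element vanishes by construction.
            mean_off = np.zeros(3)
            if opart == "pelvis" and ipart != "calcaneus":
                u = origin[1] - insertion[1]
                u = u / np.linalg.norm(u)
                h = float(np.hypot(u[0], u[2]))
                if h > 1e-9:
                    sign = -np.sign(u[2]) if abs(u[2]) > 1e-12 else 1.0
                    mean_off = sign * c.attachment_spread * np.array(
                        [u[0], 0.0, u[2]]
                    ) / h
            for ei in range(per_group):
                # symmetric tangential spread around the (biased) centroid;
                # applied to both ends so paired muscles stay exactly
                # collinear element by element
                off = (
                    c.attachment_spread
                    * spread_dirs[(mi + 3 * gi + ei) % len(spread_dirs)]
                    * (ei - (per_group - 1) / 2.0)
                )
                muscles.append(
                    MuscleElement(
                        name=f"{group}_{ei + 1}",
                        group=group,
                        origin=(origin[0], origin[1] + off),
                        insertion=(insertion[0], insertion[1] + mean_off + off),
                        strength=c.element_strength,
                    )
                )
    assert len(muscles) == 122, len(muscles)
    assert len({m.group for m in muscles}) == n_groups == 33

    return SyntheticLimb(
        parts=parts,
        muscles=muscles,
        knee_center=knee_center,
        knee_axis=np.array([1.0, 0.0, 0.0]),
        hip_center=hip,
        flexion_deg=flexion_deg,
        config=c,
    )


def _soft_layer(
    femur: TetPartMesh, tibia0: TetPartMesh, tibia: TetPartMesh, c: LimbConfig
) -> TetPartMesh:
    """Conforming soft interface layer between the femur and the posed tibia.

    Node rings interpolate linearly between the femur's distal ring (top) and
    the rotated tibia's proximal ring (bottom); the end rings coincide exactly
    with the neighbouring parts so node merging realises the bonded contact.
    """
    h = c.element_size
    nr = max(1, int(round((c.outer_radius - c.inner_radius) / h)))
    nt = max(8, int(round(2.0 * np.pi * c.outer_radius / h)))
    nz = max(2, int(round(c.soft_length / (h / 2.0))))

    ring_n = (nr + 1) * nt
    top_ring = femur.nodes[:ring_n]  # iz = 0 layer of the femur grid
    # proximal ring of the posed tibia: its grid layer iz = nz_t
    nz_t = max(2, int(round(c.tibia_length / h)))
    bot_ring = tibia.nodes[nz_t * ring_n : (nz_t + 1) * ring_n]

    layers = [
        bot_ring + (top_ring - bot_ring) * (k / nz) for k in range(nz + 1)
    ]
    nodes = np.vstack(layers)

    def nid(iz, ir, it):
        return iz * ring_n + ir * nt + (it % nt)

    hexes = []
    for kz in range(nz):
        for kr in range(nr):
            for kt in range(nt):
                hexes.append(
                    [
                        nid(kz, kr, kt),
                        nid(kz, kr, kt + 1),
                        nid(kz, kr + 1, kt + 1),
                        nid(kz, kr + 1, kt),
                        nid(kz + 1, kr, kt),
                        nid(kz + 1, kr, kt + 1),
                        nid(kz + 1, kr + 1, kt + 1),
                        nid(kz + 1, kr + 1, kt),
                    ]
                )
    tets = _hexes_to_tets(np.asarray(hexes, dtype=np.int64), nodes)
    mesh = TetPartMesh(name="soft_layer", nodes=nodes, tets=tets)
    mesh.validate()
    return mesh


@dataclass
class SyntheticLimb:
    """The assembled synthetic limb for one position."""

    parts: dict[str, TetPartMesh]
    muscles: list  # list[MuscleElement]
    knee_center: np.ndarray
    knee_axis: np.ndarray
    hip_center: np.ndarray
    flexion_deg: float
    config: LimbConfig
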