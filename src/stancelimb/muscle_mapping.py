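"""Conversion of recruitment output into finite-element loads.

The rigid-body stage produces one force magnitude per muscle element (122 in
the default synthetic model).  For the FE stage these are recombined into one
applied force per muscle — except the adductor magnus and adductor brevis,
which keep their three subdivisions each, giving 33 applied forces for the
default 29-muscle set.  Muscles originating and inserting on modelled bones
are applied as action-reaction pairs (equal magnitude, opposite direction,
collinear), so they contribute no net force or moment.  Muscles originating
off-model (pelvis) contribute their insertion load only; their share of the
load path closes through the hip reaction.

Each applied force is distributed as a uniform traction over its attachment
patch (a concentrated load at the attachment centroid is known to produce
unrealistic local results), integrated to the nodes with linear shape
functions so the nodal loads sum exactly to the input force.

The module also provides the 3-point rigid registration used to position the
FE geometry on the rigid-body model's markers, and the frontal-plane
tibia-axis check applied after positioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_anatomy import TetPartMesh
from .rigid_statics import MuscleElement, RecruitmentSolution

__all__ = [
    "AppliedMuscleForce",
    "PatchLoad",
    "RigidTransform",
    "recombine_elements",
    "build_action_reaction",
    "distribute_traction",
    "register_3pt",
    "frontal_axis_angle",
]


@dataclass
class AppliedMuscleForce:
    """A recombined muscle force ready for FE application.

    ``force`` is the load applied at the insertion (vector sum of the group's
    element forces along their lines of action); the origin, when modelled,
    receives ``-force``.
    """

    name: str
    force: np.ndarray  # N, load at the insertion
    origin: tuple[str, str] | None  # (part, patch) or None when off-model
    insertion: tuple[str, str]
    paired: bool
    origin_point: np.ndarray | None = None
    insertion_point: np.ndarray | None = None


@dataclass
class PatchLoad:
    """A force routed to a named patch of a part (or to a remote anchor)."""

    part: str
    patch: str
    force: np.ndarray


def recombine_elements(
    elements: list[MuscleElement],
    forces: np.ndarray,
    grouping: dict[str, str] | None = None,
    patch_names: dict[str, tuple[str | None, str]] | None = None,
) -> list[AppliedMuscleForce]:
    """Vector-sum element forces into one applied force per recombination slot.

    Parameters
    ----------
    elements, forces:
        The muscle elements and their recruited force magnitudes.
    grouping:
        Optional map from element group label to output slot; defaults to the
        identity (each group is its own slot).  An element whose group is
        missing from the map raises ``KeyError``.
    patch_names:
        Optional map slot -> ``((origin patch or None), insertion patch)``.
        Defaults to ``"<slot>_origin"`` / ``"<slot>_insertion"`` with a
        ``None`` origin for off-model (pelvis) origins.

    Elements of one slot are summed as vectors; when a muscle's subdivisions
    have different lines of action the resultant direction is the vector sum
    (slots with cancelling elements are retained with zero force).
    """
    forces = np.asarray(forces, float)
    if len(forces) != len(elements):
        raise ValueError("forces and elements length mismatch")
    slots: dict[str, dict] = {}
    for el, f in zip(elements, forces):
        if grouping is not None:
            if el.group not in grouping:
                raise KeyError(f"unknown group label {el.group!r}")
            slot = grouping[el.group]
        else:
            slot = el.group
        rec = slots.setdefault(
            slot,
            {
                "force": np.zeros(3),
                "origin_part": el.origin[0],
                "insertion_part": el.insertion[0],
                "origin_point": np.zeros(3),
                "insertion_point": np.zeros(3),
                "n": 0,
            },
        )
        rec["force"] = rec["force"] + f * el.line_of_action()
        rec["origin_point"] = rec["origin_point"] + el.origin[1]
        rec["insertion_point"] = rec["insertion_point"] + el.insertion[1]
        rec["n"] += 1

    out = []
    for slot, rec in slots.items():
        off_model = rec["origin_part"] == "pelvis"
        if patch_names and slot in patch_names:
            opatch, ipatch = patch_names[slot]
        else:
            opatch = None if off_model else f"{slot}_origin"
            ipatch = f"{slot}_insertion"
        out.append(
            AppliedMuscleForce(
                name=slot,
                force=rec["force"],
                origin=None if opatch is None else (rec["origin_part"], opatch),
                insertion=(rec["insertion_part"], ipatch),
                paired=not off_model,
                origin_point=rec["origin_point"] / rec["n"],
                insertion_point=rec["insertion_point"] / rec["n"],
            )
        )
    return out


def build_action_reaction(
    applied: list[AppliedMuscleForce], modelled_parts: set[str]
) -> list[PatchLoad]:
    """Expand applied forces into per-patch loads with third-law pairing.

    For muscles whose both attachments lie on modelled parts, two collinear
    loads of equal magnitude and opposite direction are emitted, so each pair
    contributes zero net force and zero net moment.  Off-model origins emit
    the insertion load only.
    """
    loads = []
    for af in applied:
        loads.append(PatchLoad(af.insertion[0], af.insertion[1], af.force.copy()))
        if af.paired and af.origin is not None and af.origin[0] in modelled_parts:
            loads.append(PatchLoad(af.origin[0], af.origin[1], -af.force.copy()))
    return loads


def distribute_traction(
    force: np.ndarray, mesh: TetPartMesh, patch: str
) -> np.ndarray:
    """Distribute a force as uniform traction over a patch.

    Returns an ``(n_nodes, 3)`` nodal load array.  The uniform traction
    ``force / area`` is integrated facet by facet with linear shape functions
    (each facet node receives one third of the facet's share), so the nodal
    loads sum exactly to the input force.
    """
    force = np.asarray(force, float)
    facets = mesh.patches[patch]
    areas = mesh.facet_areas(facets)
    total = areas.sum()
    if total <= 0:
        raise ValueError(f"patch {patch!r} on part {mesh.name!r} has zero area")
    loads = np.zeros_like(mesh.nodes)
    share = areas / total / 3.0
    for f, s in zip(facets, share):
        loads[f] += s * force
    return loads


@dataclass
class RigidTransform:
    """Proper rigid transform ``x -> R x + t`` with fit residual (mm RMS)."""

    rotation: np.ndarray
    translation: np.ndarray
    residual: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-8 or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        self.rotation = R
        self.translation = np.asarray(self.translation, float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation


def _collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    a, b, c = np.asarray(points, float)
    n = np.linalg.norm(np.cross(b - a, c - a))
    scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a), 1.0)
    return n <= tol * scale * scale


def register_3pt(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping three landmarks onto three markers.

    Kabsch algorithm (SVD of the cross-covariance, no scaling).  Congruent
    triples are matched exactly; otherwise the RMS residual is reported.
    Collinear triples are rejected.
    """
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    if src.shape != (3, 3) or tgt.shape != (3, 3):
        raise ValueError("source and target must each be three 3D points")
    if _collinear(src) or _collinear(tgt):
        raise ValueError("landmark triples must be non-collinear")
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    U, _s, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, float(np.sign(np.linalg.det(Vt.T @ U.T)))])
    R = Vt.T @ D @ U.T
    t = ct - R @ cs
    residual = float(np.sqrt(np.mean(np.sum((src @ R.T + t - tgt) ** 2, axis=1))))
    return RigidTransform(rotation=R, translation=t, residual=residual)


def frontal_axis_angle(
    tibia_axis_fe: np.ndarray, tibia_axis_rb: np.ndarray, limit_deg: float = 3.0
) -> tuple[float, bool]:
    """Angle between two tibia axes projected onto the frontal (x-y) plane.

    Axes are undirected, so the angle is folded into [0, 90] degrees.  The
    returned flag is true when the angle is below ``limit_deg`` (default 3
    degrees, the alignment acceptance used after positioning).
    """
    angle = None
    proj = []
    for a in (tibia_axis_fe, tibia_axis_rb):
        a = np.asarray(a, float)
        if np.linalg.norm(a) < 1e-12:
            raise ValueError("zero axis")
        p = a[:2]  # frontal plane spans x (medio-lateral) and y (vertical)
        n = np.linalg.norm(p)
        if n < 1e-12:
            raise ValueError("axis has zero frontal-plane projection")
        proj.append(p / n)
    cosang = np.clip(abs(proj[0] @ proj[1]), 0.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    return angle, angle < limit_deg
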