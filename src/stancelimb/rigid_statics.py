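"""Per-position static analysis of the three-segment lower-limb linkage.

The linkage has a spherical hip, a revolute knee (single-axis rotation about
the flexion axis) and a rigid ankle, so the foot and the leg form one segment.
For each stance position the module books the segment inertial forces, checks
the quasi-static premise, assembles the static equilibrium of the linkage
under the ground reaction force, and solves the muscle-redundancy problem
with the min/max recruitment criterion:

    minimise   beta
    subject to f_i <= beta * N_i,   f_i >= 0,
               C f + R r = d        (equilibrium, reactions r free)

i.e. the peak muscle activation ``f_i / N_i`` is minimised subject to static
equilibrium.  Among beta-optimal solutions the returned one additionally
minimises the total muscle force (fixed secondary tie-break), which removes
LP degeneracy so results are reproducible across solvers.

Gravity is excluded from the load vector: the model is loaded by the GRF and
the muscle forces only, and the inertial terms are dropped after the
quasi-static check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .synthetic_anatomy import GaitPosition, LEG_FOOT_MASS, THIGH_MASS

__all__ = [
    "BodySegment",
    "MuscleElement",
    "RecruitmentSolution",
    "LimbLinkage",
    "EquilibriumSystem",
    "RecruitmentError",
    "inertial_force",
    "quasi_static_ratio",
    "assemble_equilibrium",
    "recruit_minmax",
    "hip_reaction",
    "solve_position",
]


class RecruitmentError(RuntimeError):
    """Raised when the recruitment LP is infeasible or unbounded."""


@dataclass
class BodySegment:
    """A rigid segment of the linkage (``thigh`` or ``leg_foot``)."""

    name: str
    mass: float  # kg
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))  # mm
    accel: np.ndarray = field(default_factory=lambda: np.zeros(3))  # m/s^2

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"segment {self.name}: mass must be positive")
        self.com = np.asarray(self.com, float)
        self.accel = np.asarray(self.accel, float)


@dataclass
class MuscleElement:
    """One muscle-force carrier: a straight line of action between two
    attachment points, each given as ``(part name, 3-point in mm)``.

    ``group`` is the recombination-group label (the parent muscle, or the
    parent muscle subdivision for the split adductors).  ``strength`` is the
    normalisation N_i of the recruitment criterion.
    """

    name: str
    group: str
    origin: tuple[str, np.ndarray]
    insertion: tuple[str, np.ndarray]
    strength: float

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise ValueError(f"muscle {self.name}: strength must be positive")
        self.origin = (self.origin[0], np.asarray(self.origin[1], float))
        self.insertion = (self.insertion[0], np.asarray(self.insertion[1], float))

    def line_of_action(self) -> np.ndarray:
        """Unit vector from insertion towards origin (direction of pull at
        the insertion)."""
        d = self.origin[1] - self.insertion[1]
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError(f"muscle {self.name}: zero-length line of action")
        return d / n


def inertial_force(segment: BodySegment) -> tuple[np.ndarray, float]:
    """Inertial force ``m * a`` of a segment in N and its magnitude.

    The magnitude is the Euclidean norm; round it to integer newtons for
    table-style reporting.
    """
    f = segment.mass * segment.accel
    return f, float(np.linalg.norm(f))


def quasi_static_ratio(
    gait_table: list[GaitPosition],
    thigh_mass: float = THIGH_MASS,
    leg_foot_mass: float = LEG_FOOT_MASS,
    grf_floor: float = 100.0,
) -> tuple[dict[int, float], bool]:
    """Per-position ratio of the largest segment inertial force to the GRF.

    Positions whose GRF magnitude does not exceed ``grf_floor`` (default
    100 N; near toe-off the GRF vanishes) are reported with an infinite ratio
    and excluded from the global negligibility flag.  The premise holds when
    every included ratio is <= 0.10.
    """
    if not gait_table:
        raise ValueError("empty gait table")
    masses = {"thigh": thigh_mass, "leg_foot": leg_foot_mass}
    ratios: dict[int, float] = {}
    ok = True
    for pos in gait_table:
        inert = max(
            np.linalg.norm(masses[s] * a) for s, a in pos.segment_accel.items()
        )
        grf = float(np.linalg.norm(pos.grf))
        if grf > grf_floor:
            ratios[pos.index] = inert / grf
            ok = ok and (inert / grf <= 0.10)
        else:
            ratios[pos.index] = np.inf
    return ratios, ok


@dataclass
class LimbLinkage:
    """Joint geometry and the part-to-segment map of the linkage.

    Parts mapped to ``None`` (e.g. the pelvis) are off-model: forces acting
    on them are taken by the ground and only enter through the reactions.
    """

    hip_center: np.ndarray
    knee_center: np.ndarray
    knee_axis: np.ndarray
    part_to_segment: dict[str, str | None] = field(
        default_factory=lambda: {
            "pelvis": None,
            "femur": "thigh",
            "tibia": "leg_foot",
            "fibula": "leg_foot",
            "patella": "leg_foot",
            "calcaneus": "leg_foot",
        }
    )

    def __post_init__(self) -> None:
        self.hip_center = np.asarray(self.hip_center, float)
        self.knee_center = np.asarray(self.knee_center, float)
        axis = np.asarray(self.knee_axis, float)
        self.knee_axis = axis / np.linalg.norm(axis)


@dataclass
class EquilibriumSystem:
    """Assembled static equilibrium ``C f + R r = d``.

    Rows 0-2: force balance of the leg+foot segment; rows 3-5: force balance
    of the thigh; rows 6-8: moment balance of the whole limb about the hip
    centre (hip reaction and internal knee reactions drop out); row 9: moment
    of the leg+foot about the knee flexion axis (the revolute knee transmits
    no moment about its own axis).  Reaction columns: knee force (3, rows
    0-5), hip force (3, rows 3-5).
    """

    C: np.ndarray  # (10, n_muscles)
    R: np.ndarray  # (10, 6)
    d: np.ndarray  # (10,)
    muscles: list[MuscleElement]
    reaction_labels: tuple[str, ...] = (
        "knee_fx",
        "knee_fy",
        "knee_fz",
        "hip_fx",
        "hip_fy",
        "hip_fz",
    )
    row_labels: tuple[str, ...] = (
        "leg_foot Fx",
        "leg_foot Fy",
        "leg_foot Fz",
        "thigh Fx",
        "thigh Fy",
        "thigh Fz",
        "limb Mx about hip",
        "limb My about hip",
        "limb Mz about hip",
        "leg_foot M about knee axis",
    )


def assemble_equilibrium(
    linkage: LimbLinkage,
    position: GaitPosition,
    muscles: list[MuscleElement],
) -> EquilibriumSystem:
    """Build the 10-row static equilibrium of the linkage for one position.

    The load vector ``d`` carries the ground reaction force applied at the
    centre of pressure; gravity and inertial forces are excluded.
    """
    n = len(muscles)
    C = np.zeros((10, n))
    R = np.zeros((10, 6))
    hip, knee, axis = linkage.hip_center, linkage.knee_center, linkage.knee_axis

    seg_rows = {"leg_foot": slice(0, 3), "thigh": slice(3, 6)}
    for j, m in enumerate(muscles):
        u = m.line_of_action()  # raises on zero length
        for (part, point), force_dir in ((m.insertion, u), (m.origin, -u)):
            seg = linkage.part_to_segment.get(part, None)
            if seg is None:
                continue
            C[seg_rows[seg], j] += force_dir
            C[6:9, j] += np.cross(point - hip, force_dir)
            if seg == "leg_foot":
                C[9, j] += axis @ np.cross(point - knee, force_dir)

    # reactions: knee force on the leg_foot (+), equal and opposite on thigh
    R[0:3, 0:3] = np.eye(3)
    R[3:6, 0:3] = -np.eye(3)
    R[3:6, 3:6] = np.eye(3)  # hip force on the thigh

    grf = np.asarray(position.grf, float)
    cop = np.asarray(position.cop, float)
    d = np.zeros(10)
    d[0:3] = -grf
    d[6:9] = -np.cross(cop - hip, grf)
    d[9] = -axis @ np.cross(cop - knee, grf)
    return EquilibriumSystem(C=C, R=R, d=d, muscles=muscles)


@dataclass
class RecruitmentSolution:
    """Solution of the min/max recruitment problem."""

    forces: np.ndarray  # f_i >= 0, N
    beta: float  # peak activation max_i f_i / N_i
    reactions: dict[str, np.ndarray]  # "hip", "knee" 3-vectors, N
    residual: float  # equilibrium residual norm
    strengths: np.ndarray


def recruit_minmax(
    system: EquilibriumSystem,
    strengths: np.ndarray | None = None,
    tol: float = 1e-9,
) -> RecruitmentSolution:
    """Solve min/max muscle recruitment with free joint reactions.

    Raises :class:`RecruitmentError` naming the worst-balanced equilibrium row
    when the system is infeasible, or reporting unboundedness (which indicates
    a missing reaction slot).
    """
    C, R, d = system.C, system.R, system.d
    n = C.shape[1]
    m_rows, n_r = C.shape[0], R.shape[1]
    if strengths is None:
        strengths = np.array([m.strength for m in system.muscles], float)
    strengths = np.asarray(strengths, float)

    # stage 1: minimise beta
    n_var = n + n_r + 1
    c_obj = np.zeros(n_var)
    c_obj[-1] = 1.0
    A_eq = np.hstack([C, R, np.zeros((m_rows, 1))])
    A_ub = np.hstack([np.eye(n), np.zeros((n, n_r)), -strengths[:, None]])
    bounds = [(0, None)] * n + [(None, None)] * n_r + [(0, None)]
    lp_opts = {
        "primal_feasibility_tolerance": 1e-10,
        "dual_feasibility_tolerance": 1e-10,
    }
    res = linprog(
        c_obj, A_ub=A_ub, b_ub=np.zeros(n), A_eq=A_eq, b_eq=d, bounds=bounds,
        method="highs", options=lp_opts,
    )
    if res.status == 2:
        raise RecruitmentError(
            "recruitment infeasible; worst-balanced row: "
            + _worst_row(system)
        )
    if res.status == 3:
        raise RecruitmentError(
            "recruitment unbounded: a reaction slot is missing from the system"
        )
    if not res.success:
        raise RecruitmentError(f"LP solver failed: {res.message}")
    beta = float(res.x[-1])

    # stage 2: fixed tie-break — among beta-optimal solutions minimise sum f_i
    c2 = np.concatenate([np.ones(n), np.zeros(n_r)])
    A_eq2 = np.hstack([C, R])
    ub = (beta + tol) * strengths + tol
    bounds2 = [(0, float(u)) for u in ub] + [(None, None)] * n_r
    res2 = linprog(
        c2, A_eq=A_eq2, b_eq=d, bounds=bounds2, method="highs", options=lp_opts
    )
    if not res2.success:  # numerically tight; fall back to the stage-1 point
        f = res.x[:n]
        r = res.x[n : n + n_r]
    else:
        f = res2.x[:n]
        r = res2.x[n : n + n_r]

    f = np.maximum(f, 0.0)
    residual = float(np.linalg.norm(C @ f + R @ r - d))
    beta_out = float(np.max(f / strengths)) if n else 0.0
    if n_r == 6:
        reactions = {"knee": r[0:3].copy(), "hip": r[3:6].copy()}
    else:
        reactions = {"free": r.copy()}
    return RecruitmentSolution(
        forces=f,
        beta=beta_out,
        reactions=reactions,
        residual=residual,
        strengths=strengths,
    )


def _worst_row(system: EquilibriumSystem) -> str:
    """Name the equilibrium row with the largest least-squares residual."""
    A = np.hstack([system.C, system.R])
    x, *_ = np.linalg.lstsq(A, system.d, rcond=None)
    resid = np.abs(A @ x - system.d)
    i = int(np.argmax(resid))
    label = system.row_labels[i] if i < len(system.row_labels) else f"row {i}"
    return f"{label} (residual {resid.max():.3g} N)"


def hip_reaction(solution: RecruitmentSolution) -> tuple[np.ndarray, float]:
    """Hip-reaction force vector of a solved system and its magnitude (N)."""
    r = solution.reactions["hip"]
    return r, float(np.linalg.norm(r))


def solve_position(
    linkage: LimbLinkage,
    position: GaitPosition,
    muscles: list[MuscleElement],
    strengths: np.ndarray | None = None,
) -> RecruitmentSolution:
    """Assemble and solve the recruitment problem for one gait position."""
    system = assemble_equilibrium(linkage, position, muscles)
    return recruit_minmax(system, strengths)
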