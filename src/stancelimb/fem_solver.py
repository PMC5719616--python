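"""Small-strain linear-elastic FE solver on 4-node tetrahedral meshes.

Implements the boundary machinery the lower-limb model needs: bonded
interfaces realised by merging coincident nodes of conforming part meshes,
grounded stiff springs (the spherical-joint surrogate at the femoral head,
1e9 N/mm), weak grounded stabilisation springs (1 N/mm, numerical
stabilisation only), axial tendon springs (k = E*A/L split over parallel
springs), and remote points that couple an off-mesh location (centre of
pressure, calcaneus) to a surface patch.

The element is the 4-node constant-strain tetrahedron: exact for constant
strain states (patch test), symmetric positive-semidefinite element matrices
with six rigid-body modes.  The global system is solved by direct sparse LU
factorisation with two steps of iterative refinement, which keeps the
relative residual near machine precision despite the 1e9..1 spread of spring
stiffnesses.

Remote points default to distributing (load-averaging) coupling: loads at the
remote point are spread over the patch statically equivalently (force and
moment preserved), and springs attached at the remote point act on the
average patch displacement, which does not artificially stiffen the surface.
Rigid coupling (patch moves as a rigid body with 6 extra degrees of freedom,
enforced by penalty) is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .synthetic_anatomy import MaterialSpec, TetPartMesh

__all__ = [
    "SpringElement",
    "RemotePoint",
    "FESystem",
    "FEResult",
    "SingularSystemError",
    "tendon_spring_stiffness",
    "tet4_stiffness",
    "assemble_system",
    "solve_static",
    "global_equilibrium_check",
    "make_ground_springs",
    "distribute_remote_load",
]


class SingularSystemError(RuntimeError):
    """The assembled system is singular or indefinite (unconstrained modes)."""


def tendon_spring_stiffness(
    E: float, A: float, L: float, n_springs: int = 1
) -> tuple[float, float]:
    """Axial tendon stiffness ``k = E*A/L`` and its equal split over
    ``n_springs`` parallel springs (N/mm).

    E in MPa, A in mm^2, L in mm.  The patellar tendon defaults
    (E=900, A=160, L=50, three springs) give 2880 and 960 N/mm.
    """
    if L == 0:
        raise ValueError("tendon length L must be non-zero")
    if min(E, A, L) <= 0:
        raise ValueError("E, A and L must be positive")
    if n_springs < 1:
        raise ValueError("n_springs must be >= 1")
    k_total = E * A / L
    return k_total, k_total / n_springs


def _elastic_D(material: MaterialSpec) -> np.ndarray:
    E, nu = material.E, material.nu
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def _tet_B_and_volume(x: np.ndarray) -> tuple[np.ndarray, float]:
    T = np.column_stack([x[1] - x[0], x[2] - x[0], x[3] - x[0]])
    vol = np.linalg.det(T) / 6.0
    if vol <= 0:
        raise ValueError(f"degenerate tetrahedron (signed volume {vol:.3g})")
    grads = np.zeros((4, 3))
    Tinv = np.linalg.inv(T)
    grads[1:] = Tinv  # rows are gradients of barycentric coords 1..3
    grads[0] = -grads[1:].sum(axis=0)
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B, vol


def tet4_stiffness(x: np.ndarray, material: MaterialSpec) -> np.ndarray:
    """12x12 stiffness of a 4-node constant-strain tetrahedron (N/mm).

    Symmetric positive-semidefinite with exactly six zero eigenvalues (the
    rigid-body modes).  Raises on degenerate (non-positive-volume) elements.
    """
    x = np.asarray(x, float)
    B, vol = _tet_B_and_volume(x)  # raises on non-positive volume
    K = vol * B.T @ _elastic_D(material) @ B
    return 0.5 * (K + K.T)


# ---------------------------------------------------------------------------
# Boundary machinery
# ---------------------------------------------------------------------------


@dataclass
class SpringElement:
    """A linear spring between two endpoints.

    Endpoint specs:
      ``("part_point", part, xyz)`` — the mesh node of ``part`` nearest xyz;
      ``("rp", name)``              — a remote point (average patch motion);
      ``("ground",)``               — the fixed ground.

    ``axis=None`` makes the spring isotropic (acts on all three displacement
    components, equivalent to three orthogonal axis springs); a unit vector
    makes it uniaxial.  ``axis="auto"`` resolves to the unit vector from
    endpoint A to endpoint B at assembly time (axial tendon spring).
    """

    name: str
    a: tuple
    b: tuple
    k: float
    axis: np.ndarray | str | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"spring {self.name}: stiffness must be positive")
        if self.axis is not None and not isinstance(self.axis, str):
            ax = np.asarray(self.axis, float)
            n = np.linalg.norm(ax)
            if n < 1e-12:
                raise ValueError(f"spring {self.name}: zero axis")
            self.axis = ax / n


@dataclass
class RemotePoint:
    """An off-mesh point coupled to a surface patch of a part."""

    name: str
    location: np.ndarray
    part: str
    patch: str
    coupling: str = "distributing"  # or "rigid"

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, float)
        if self.coupling not in ("distributing", "rigid"):
            raise ValueError(f"unknown coupling {self.coupling!r}")


def make_ground_springs(
    name: str, endpoint: tuple, k: float
) -> list[SpringElement]:
    """Three grounded axis springs (x, y, z) forming one reaction group."""
    axes = {"x": (1.0, 0, 0), "y": (0, 1.0, 0), "z": (0, 0, 1.0)}
    return [
        SpringElement(f"{name}:{lab}", ("ground",), endpoint, k, np.array(ax))
        for lab, ax in axes.items()
    ]


@dataclass
class _ResolvedSpring:
    name: str
    k: float
    axis: np.ndarray  # unit vector of this leg
    gvec: sp.csr_matrix  # (1, ndof): elongation = gvec @ u (B minus A side)
    grounded: bool


@dataclass
class FESystem:
    """Assembled global system: merged mesh, stiffness and bookkeeping."""

    nodes: np.ndarray
    tets: np.ndarray
    tet_part: np.ndarray  # part index per tet
    part_names: list[str]
    materials: list[MaterialSpec]  # per part
    patches: dict[str, np.ndarray]  # "part:patch" -> global facets
    node_maps: dict[str, np.ndarray]  # part -> local->global node map
    K: sp.csc_matrix
    springs: list[_ResolvedSpring]
    remote_points: dict[str, dict]
    fixed_dofs: np.ndarray
    ndof: int
    n_extra_dofs: int = 0

    # -- helpers ----------------------------------------------------------

    def patch_nodes(self, key: str) -> np.ndarray:
        return np.unique(self.patches[key])

    def nearest_node(self, point: np.ndarray) -> int:
        return int(np.argmin(np.linalg.norm(self.nodes - np.asarray(point), axis=1)))

    def rp_average(self, name: str, u: np.ndarray) -> np.ndarray:
        """Average displacement of the remote point's patch nodes."""
        rp = self.remote_points[name]
        return u[rp["nodes"]].T @ rp["weights"]


def _merge_nodes(parts: list[TetPartMesh], tol: float):
    from scipy.spatial import cKDTree

    all_nodes = np.vstack([p.nodes for p in parts])
    offsets = np.cumsum([0] + [len(p.nodes) for p in parts])
    n = len(all_nodes)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(all_nodes)
    for i, j in tree.query_pairs(tol):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(n)])
    uniq, remap = np.unique(roots, return_inverse=True)
    merged_nodes = all_nodes[uniq]
    node_maps = {
        p.name: remap[offsets[k] : offsets[k + 1]] for k, p in enumerate(parts)
    }
    return merged_nodes, node_maps


def assemble_system(
    parts: list[TetPartMesh],
    materials: dict[str, MaterialSpec],
    springs: list[SpringElement] | None = None,
    remote_points: list[RemotePoint] | None = None,
    merge_tol: float = 1e-6,
    fixed: list[tuple[str, int, int]] | None = None,
    rigid_penalty: float = 1e8,
) -> FESystem:
    """Assemble the global stiffness with bonded ties, springs and remote points.

    Bonded interfaces between conforming part meshes are realised by merging
    nodes closer than ``merge_tol`` (mm).  ``fixed`` lists hard supports as
    ``(part, local node index, dof axis)`` triples.  Rigid remote points add
    six extra degrees of freedom each, coupled to their patch by penalty.
    """
    springs = springs or []
    remote_points = remote_points or []
    nodes, node_maps = _merge_nodes(parts, merge_tol)
    nn = len(nodes)

    tets_list, tet_part = [], []
    part_names, mat_list = [], []
    patches: dict[str, np.ndarray] = {}
    for k, p in enumerate(parts):
        if p.name not in materials:
            raise KeyError(f"no material for part {p.name!r}")
        part_names.append(p.name)
        mat_list.append(materials[p.name])
        gmap = node_maps[p.name]
        tets_list.append(gmap[p.tets])
        tet_part.append(np.full(len(p.tets), k))
        for pname, facets in p.patches.items():
            patches[f"{p.name}:{pname}"] = gmap[np.asarray(facets)]
    tets = np.vstack(tets_list)
    tet_part_arr = np.concatenate(tet_part)

    # remote points: patch node sets and uniform weights
    rps: dict[str, dict] = {}
    n_extra = 0
    for rp in remote_points:
        key = f"{rp.part}:{rp.patch}"
        if key not in patches:
            raise KeyError(f"remote point {rp.name!r}: unknown patch {key!r}")
        pn = np.unique(patches[key])
        if pn.size == 0:
            raise ValueError(f"remote point {rp.name!r}: empty patch")
        w = np.full(pn.size, 1.0 / pn.size)
        entry = {
            "nodes": pn,
            "weights": w,
            "location": rp.location,
            "coupling": rp.coupling,
            "extra_offset": None,
        }
        if rp.coupling == "rigid":
            entry["extra_offset"] = 3 * nn + 6 * n_extra
            n_extra += 1
        rps[rp.name] = entry
    ndof = 3 * nn + 6 * n_extra

    # element stiffness assembly
    rows, cols, vals = [], [], []
    for ti, tet in enumerate(tets):
        x = nodes[tet]
        try:
            Ke = tet4_stiffness(x, mat_list[tet_part_arr[ti]])
        except ValueError as exc:
            raise ValueError(f"element {ti}: {exc}") from exc
        dofs = np.repeat(tet * 3, 3) + np.tile([0, 1, 2], 4)
        rows.append(np.repeat(dofs, 12))
        cols.append(np.tile(dofs, 12))
        vals.append(Ke.ravel())
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof),
    ).tocsc()

    # rigid-coupling penalties
    pen_rows, pen_cols, pen_vals = [], [], []
    for name, rp in rps.items():
        if rp["coupling"] != "rigid":
            continue
        off = rp["extra_offset"]
        r0 = rp["location"]
        for i, w in zip(rp["nodes"], rp["weights"]):
            rho = nodes[i] - r0
            Sx = np.array(
                [[0, -rho[2], rho[1]], [rho[2], 0, -rho[0]], [-rho[1], rho[0], 0]]
            )
            # residual = u_i - t + rho x theta  ->  A acts on (u_i, t, theta)
            A = np.hstack([np.eye(3), -np.eye(3), Sx])
            dofs = np.concatenate(
                [3 * i + np.arange(3), off + np.arange(3), off + 3 + np.arange(3)]
            )
            Kp = rigid_penalty * w * (A.T @ A)
            pen_rows.append(np.repeat(dofs, 9))
            pen_cols.append(np.tile(dofs, 9))
            pen_vals.append(Kp.ravel())
    if pen_rows:
        K = K + sp.coo_matrix(
            (np.concatenate(pen_vals), (np.concatenate(pen_rows), np.concatenate(pen_cols))),
            shape=(ndof, ndof),
        ).tocsc()

    system = FESystem(
        nodes=nodes,
        tets=tets,
        tet_part=tet_part_arr,
        part_names=part_names,
        materials=mat_list,
        patches=patches,
        node_maps=node_maps,
        K=K,
        springs=[],
        remote_points=rps,
        fixed_dofs=np.array([], dtype=np.int64),
        ndof=ndof,
        n_extra_dofs=n_extra,
    )

    # springs
    s_rows, s_cols, s_vals = [], [], []
    for spr in springs:
        for leg_axis in _spring_axes(spr, system):
            gvec = _endpoint_gvec(spr.b, leg_axis, system) - _endpoint_gvec(
                spr.a, leg_axis, system
            )
            grounded = spr.a[0] == "ground" or spr.b[0] == "ground"
            g = gvec.tocoo()
            for ri, vi in zip(g.col, g.data):
                for rj, vj in zip(g.col, g.data):
                    s_rows.append(ri)
                    s_cols.append(rj)
                    s_vals.append(spr.k * vi * vj)
            system.springs.append(
                _ResolvedSpring(
                    name=spr.name, k=spr.k, axis=leg_axis, gvec=gvec.tocsr(),
                    grounded=grounded,
                )
            )
    if s_rows:
        system.K = (
            system.K
            + sp.coo_matrix((s_vals, (s_rows, s_cols)), shape=(ndof, ndof)).tocsc()
        )

    # hard supports
    if fixed:
        fd = []
        for part, local, ax in fixed:
            fd.append(3 * int(node_maps[part][local]) + ax)
        system.fixed_dofs = np.unique(np.asarray(fd, dtype=np.int64))
    return system


def _spring_axes(spr: SpringElement, system: FESystem) -> list[np.ndarray]:
    if isinstance(spr.axis, str) and spr.axis == "auto":
        pa = _endpoint_location(spr.a, system)
        pb = _endpoint_location(spr.b, system)
        d = pb - pa
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError(f"spring {spr.name}: coincident endpoints, no axis")
        return [d / n]
    if spr.axis is None:
        return [np.eye(3)[i] for i in range(3)]
    return [spr.axis]


def _endpoint_location(ep: tuple, system: FESystem) -> np.ndarray:
    if ep[0] == "ground":
        raise ValueError("ground endpoint has no location")
    if ep[0] == "rp":
        return system.remote_points[ep[1]]["location"]
    if ep[0] == "part_point":
        g = system.node_maps[ep[1]][_nearest_local(system, ep[1], ep[2])]
        return system.nodes[g]
    raise ValueError(f"unknown endpoint spec {ep!r}")


def _nearest_local(system: FESystem, part: str, point) -> int:
    gmap = system.node_maps[part]
    pts = system.nodes[gmap]
    return int(np.argmin(np.linalg.norm(pts - np.asarray(point, float), axis=1)))


def _endpoint_gvec(ep: tuple, axis: np.ndarray, system: FESystem) -> sp.csr_matrix:
    """Row vector g with g @ u = axis-component of the endpoint displacement."""
    ndof = system.ndof
    if ep[0] == "ground":
        return sp.csr_matrix((1, ndof))
    if ep[0] == "rp":
        rp = system.remote_points[ep[1]]
        if rp["coupling"] == "rigid":
            off = rp["extra_offset"]
            cols = off + np.arange(3)
            return sp.csr_matrix((axis, (np.zeros(3, int), cols)), shape=(1, ndof))
        cols, vals = [], []
        for i, w in zip(rp["nodes"], rp["weights"]):
            for c in range(3):
                cols.append(3 * i + c)
                vals.append(w * axis[c])
        return sp.csr_matrix((vals, (np.zeros(len(cols), int), cols)), shape=(1, ndof))
    if ep[0] == "part_point":
        g = system.node_maps[ep[1]][_nearest_local(system, ep[1], ep[2])]
        cols = 3 * g + np.arange(3)
        return sp.csr_matrix((axis, (np.zeros(3, int), cols)), shape=(1, ndof))
    raise ValueError(f"unknown endpoint spec {ep!r}")


def distribute_remote_load(
    system: FESystem, rp_name: str, force: np.ndarray, moment: np.ndarray | None = None
) -> np.ndarray:
    """Nodal loads statically equivalent to a force (and moment) at a remote point.

    For distributing coupling the load is spread over the patch nodes so that
    the total force equals ``force`` and the total moment about the remote
    point equals ``moment`` (default zero).  For rigid coupling the load acts
    directly on the remote point's own degrees of freedom.
    Returns a flat ``(ndof,)`` load vector.
    """
    force = np.asarray(force, float)
    moment = np.zeros(3) if moment is None else np.asarray(moment, float)
    rp = system.remote_points[rp_name]
    f = np.zeros(system.ndof)
    if rp["coupling"] == "rigid":
        off = rp["extra_offset"]
        f[off : off + 3] = force
        f[off + 3 : off + 6] = moment
        return f
    nodes_idx, w, r0 = rp["nodes"], rp["weights"], rp["location"]
    x = system.nodes[nodes_idx]
    c = w @ x
    rho = x - c
    G = np.einsum("i,ij,ik->jk", w, rho, rho)
    G = np.trace(G) * np.eye(3) - G
    rhs = moment - np.cross(c - r0, force)
    b = np.linalg.solve(G, rhs)
    loads = w[:, None] * (force[None, :] + np.cross(b[None, :], rho))
    for i, li in zip(nodes_idx, loads):
        f[3 * i : 3 * i + 3] += li
    return f


# ---------------------------------------------------------------------------
# Solve and recovery
# ---------------------------------------------------------------------------


@dataclass
class FEResult:
    """Solved static response."""

    u: np.ndarray  # (n_nodes, 3) displacements, mm
    extra: np.ndarray  # rigid remote-point dofs, if any
    strains: np.ndarray  # (n_tets, 6): exx eyy ezz gxy gyz gzx
    spring_forces: dict[str, float]  # signed axial force per spring leg, N
    spring_force_vectors: dict[str, np.ndarray]  # force on the structure, N
    support_reactions: np.ndarray  # (ndof,) forces at hard supports, N
    residual: float
    system: FESystem = field(repr=False, default=None)

    @property
    def max_total_deformation(self) -> float:
        return float(np.linalg.norm(self.u, axis=1).max())

    def spring_group_force(self, prefix: str) -> np.ndarray:
        """Resultant force on the structure from all springs named
        ``prefix:*`` (e.g. a grounded x/y/z triple)."""
        total = np.zeros(3)
        for name, vec in self.spring_force_vectors.items():
            if name == prefix or name.startswith(prefix + ":"):
                total += vec
        return total

    def grounded_reaction(self, prefix: str) -> np.ndarray:
        """Reaction of the named grounded spring group: the force the ground
        exerts on the structure through it, i.e. minus the sum of the spring
        tension vectors (equal to :meth:`spring_group_force`)."""
        return self.spring_group_force(prefix)

    def max_principal_strain(self, part: str | None = None) -> float:
        s = self._part_strains(part)
        tensors = np.zeros((len(s), 3, 3))
        tensors[:, 0, 0] = s[:, 0]
        tensors[:, 1, 1] = s[:, 1]
        tensors[:, 2, 2] = s[:, 2]
        tensors[:, 0, 1] = tensors[:, 1, 0] = s[:, 3] / 2
        tensors[:, 1, 2] = tensors[:, 2, 1] = s[:, 4] / 2
        tensors[:, 0, 2] = tensors[:, 2, 0] = s[:, 5] / 2
        return float(np.abs(np.linalg.eigvalsh(tensors)).max()) if len(s) else 0.0

    def max_strain_component(self, part: str | None = None) -> float:
        s = self._part_strains(part)
        return float(np.abs(s).max()) if len(s) else 0.0

    def _part_strains(self, part: str | None) -> np.ndarray:
        if part is None:
            return self.strains
        sysm = self.system
        k = sysm.part_names.index(part)
        return self.strains[sysm.tet_part == k]


def solve_static(system: FESystem, loads: np.ndarray) -> FEResult:
    """Solve ``K u = f`` and recover strains, spring forces and reactions.

    ``loads`` may be ``(n_nodes, 3)`` or flat ``(ndof,)``.  The system must be
    constrained (ground springs, rigid supports or fixed dofs); otherwise a
    :class:`SingularSystemError` is raised before factorisation.
    """
    f = np.asarray(loads, float)
    if f.ndim == 2:
        full = np.zeros(system.ndof)
        full[: 3 * len(system.nodes)] = f.ravel()
        f = full
    if f.shape != (system.ndof,):
        raise ValueError(f"load vector has shape {f.shape}, expected ({system.ndof},)")

    grounded = any(s.grounded for s in system.springs)
    if not grounded and system.fixed_dofs.size == 0:
        raise SingularSystemError(
            "system has no ground springs and no fixed dofs: rigid-body modes "
            "are unconstrained"
        )

    free = np.ones(system.ndof, dtype=bool)
    free[system.fixed_dofs] = False
    Kff = system.K[free][:, free].tocsc()
    ff = f[free]
    try:
        lu = spla.splu(Kff)
    except RuntimeError as exc:
        raise SingularSystemError(f"factorisation failed: {exc}") from exc
    uf = lu.solve(ff)
    for _ in range(2):  # iterative refinement against the stiffness spread
        uf = uf + lu.solve(ff - Kff @ uf)
    if not np.all(np.isfinite(uf)):
        raise SingularSystemError("solution is not finite: singular system")
    rel = float(np.linalg.norm(Kff @ uf - ff) / max(1.0, np.linalg.norm(ff)))

    u_full = np.zeros(system.ndof)
    u_full[free] = uf

    nn = len(system.nodes)
    u = u_full[: 3 * nn].reshape(nn, 3)
    extra = u_full[3 * nn :]

    strains = np.zeros((len(system.tets), 6))
    for ti, tet in enumerate(system.tets):
        B, _ = _tet_B_and_volume(system.nodes[tet])
        strains[ti] = B @ u[tet].ravel()

    spring_forces: dict[str, float] = {}
    spring_vectors: dict[str, np.ndarray] = {}
    for s in system.springs:
        delta = float((s.gvec @ u_full)[0])
        fmag = s.k * delta  # positive = tension pulling B towards A side
        spring_forces[s.name] = fmag
        # force applied by the spring on its B endpoint (the structure side
        # for ground springs, which have A = ground)
        vec = -fmag * s.axis
        spring_vectors[s.name] = spring_vectors.get(s.name, np.zeros(3)) + vec

    resid_vec = system.K @ u_full - f
    support = np.zeros(system.ndof)
    support[system.fixed_dofs] = resid_vec[system.fixed_dofs]

    return FEResult(
        u=u,
        extra=extra,
        strains=strains,
        spring_forces=spring_forces,
        spring_force_vectors=spring_vectors,
        support_reactions=support,
        residual=rel,
        system=system,
    )


def global_equilibrium_check(result: FEResult, applied_loads: np.ndarray) -> float:
    """Residual of Newton's first law for the solved model (N).

    Sums the applied loads, the forces the grounded springs exert on the
    structure, and the hard-support reactions; the norm must vanish to solver
    precision (<= 1e-6 relative to the applied resultant).
    """
    f = np.asarray(applied_loads, float)
    if f.ndim == 2:
        total_applied = f.sum(axis=0)
    else:
        total_applied = f[: 3 * len(result.system.nodes)].reshape(-1, 3).sum(axis=0)

    spring_total = np.zeros(3)
    for s in result.system.springs:
        if s.grounded:
            spring_total += -result.spring_forces[s.name] * s.axis

    support_total = result.support_reactions[: 3 * len(result.system.nodes)].reshape(
        -1, 3
    ).sum(axis=0)
    return float(np.linalg.norm(total_applied + spring_total + support_total))
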