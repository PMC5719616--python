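"""FE solver verification: element matrices, boundary machinery, solves.

The constant-strain tetrahedron is cross-checked against an independent
4-point Gauss-quadrature integration of B^T D B, the solver against the
patch test (exact for constant strain), the spring/remote-point machinery
against closed forms, and bending against the Euler-Bernoulli beam formula.
"""

import numpy as np
import pytest

from stancelimb.fem_solver import (
    RemotePoint,
    SingularSystemError,
    SpringElement,
    assemble_system,
    distribute_remote_load,
    global_equilibrium_check,
    make_ground_springs,
    solve_static,
    tendon_spring_stiffness,
    tet4_stiffness,
)
from stancelimb.synthetic_anatomy import (
    BoneSpec,
    MaterialSpec,
    gen_bone_mesh,
    gen_box_mesh,
)

BONE = MaterialSpec(17000.0, 0.3)


class TestTendonStiffness:
    def test_published_patellar_tendon_values(self):
        # E = 900 MPa, A = 160 mm^2, L = 50 mm over three parallel springs
        k_total, k_spring = tendon_spring_stiffness(900.0, 160.0, 50.0, 3)
        assert k_total == pytest.approx(2880.0)
        assert k_spring == pytest.approx(960.0)

    def test_doubling_area_doubles_stiffness(self):
        k1, _ = tendon_spring_stiffness(900.0, 160.0, 50.0, 3)
        k2, _ = tendon_spring_stiffness(900.0, 320.0, 50.0, 3)
        assert k2 == pytest.approx(2 * k1)

    def test_formula_identity_single_spring(self):
        assert tendon_spring_stiffness(17000.0, 100.0, 100.0, 1) == (17000.0, 17000.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            tendon_spring_stiffness(900.0, 160.0, 0.0, 3)


def quadrature_stiffness(x, material):
    """Independent oracle: 4-point Gauss quadrature of B^T D B on the tet."""
    E, nu = material.E, material.nu
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    a = (5 - np.sqrt(5)) / 20
    b = (5 + 3 * np.sqrt(5)) / 20
    gauss = [
        np.array([b, a, a, a]),
        np.array([a, b, a, a]),
        np.array([a, a, b, a]),
        np.array([a, a, a, b]),
    ]
    T = np.column_stack([x[1] - x[0], x[2] - x[0], x[3] - x[0]])
    vol = abs(np.linalg.det(T)) / 6.0
    grads = np.zeros((4, 3))
    grads[1:] = np.linalg.inv(T)
    grads[0] = -grads[1:].sum(axis=0)
    K = np.zeros((12, 12))
    for w in gauss:  # B is constant; quadrature still integrates exactly
        B = np.zeros((6, 12))
        for node in range(4):
            gx, gy, gz = grads[node]
            c = 3 * node
            B[0, c] = gx
            B[1, c + 1] = gy
            B[2, c + 2] = gz
            B[3, c] = gy
            B[3, c + 1] = gx
            B[4, c + 1] = gz
            B[4, c + 2] = gy
            B[5, c] = gz
            B[5, c + 2] = gx
        K += 0.25 * vol * B.T @ D @ B
    return K


class TestTet4Stiffness:
    def test_symmetric_with_six_rigid_modes(self, rng):
        x = rng.normal(size=(4, 3)) * 10
        if np.linalg.det(np.column_stack([x[1] - x[0], x[2] - x[0], x[3] - x[0]])) < 0:
            x[[1, 2]] = x[[2, 1]]
        K = tet4_stiffness(x, BONE)
        assert np.allclose(K, K.T, atol=1e-12 * np.abs(K).max())
        w = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(w) < 1e-6 * w.max()) == 6
        assert w.min() > -1e-9 * w.max()

    def test_rigid_translation_in_null_space(self):
        x = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], float)
        K = tet4_stiffness(x, BONE)
        for axis in range(3):
            u = np.zeros(12)
            u[axis::3] = 1.0
            assert np.linalg.norm(K @ u) < 1e-9 * np.abs(K).max()

    def test_matches_quadrature_oracle(self):
        x = np.array(
            [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
             [0.5, np.sqrt(3) / 6, np.sqrt(2 / 3)]]
        )
        mat = MaterialSpec(1.0, 1e-12)  # nu = 0 limit
        K = tet4_stiffness(x, mat)
        K_oracle = quadrature_stiffness(x, mat)
        assert np.allclose(K, K_oracle, atol=1e-10)

    def test_degenerate_tet_rejected(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="degenerate"):
            tet4_stiffness(x, BONE)


def fix_face(mesh, axis, value, dofs=(0, 1, 2)):
    nodes = np.where(np.abs(mesh.nodes[:, axis] - value) < 1e-9)[0]
    return [(mesh.name, int(i), c) for i in nodes for c in dofs]


class TestAssembleAndTies:
    def test_two_stacked_bars_merge_to_one_continuous_bar(self):
        # analytic oracle: sigma = F/A uniform through both halves
        bar_lo = gen_box_mesh("lo", (10.0, 20.0, 10.0), (2, 4, 2))
        bar_hi = gen_box_mesh("hi", (10.0, 20.0, 10.0), (2, 4, 2), origin=(0, 20.0, 0))
        mats = {"lo": BONE, "hi": BONE}
        # roller support at the base (free lateral contraction) + minimal pins
        fixed = fix_face(bar_lo, 1, 0.0, dofs=(1,))
        base = np.where(np.abs(bar_lo.nodes[:, 1]) < 1e-9)[0]
        fixed += [("lo", int(base[0]), 0), ("lo", int(base[0]), 2),
                  ("lo", int(base[-1]), 0)]
        sys_ = assemble_system([bar_lo, bar_hi], mats, fixed=fixed)
        # shared interface nodes merged away
        assert len(sys_.nodes) == len(bar_lo.nodes) + len(bar_hi.nodes) - 3 * 3
        F = 1000.0
        top = np.where(np.abs(sys_.nodes[:, 1] - 40.0) < 1e-9)[0]
        bf = bar_hi.boundary_facets()
        f = np.zeros(sys_.ndof)
        gmap = sys_.node_maps["hi"]
        area = 10.0 * 10.0
        for tri in bf:
            p = bar_hi.nodes[tri]
            if np.all(np.abs(p[:, 1] - 40.0) < 1e-9):
                a = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
                for n in tri:
                    f[3 * gmap[n] + 1] += F / area * a / 3
        res = solve_static(sys_, f)
        sigma = F / area
        eyy = res.strains[:, 1]
        assert np.allclose(eyy, sigma / BONE.E, rtol=1e-8)
        assert res.u[top, 1].mean() == pytest.approx(
            sigma / BONE.E * 40.0, rel=1e-8
        )

    def test_grounded_spring_groups_stabilise_free_part(self):
        mesh = gen_box_mesh("blk", (10.0, 10.0, 10.0), (2, 2, 2))
        rp = RemotePoint("pin", [5.0, 10.0, 5.0], "blk", "top")
        mesh.patches["top"] = mesh.boundary_facets()[
            np.all(np.abs(mesh.nodes[mesh.boundary_facets()][:, :, 1] - 10.0) < 1e-9, axis=1)
        ]
        springs = make_ground_springs("g", ("rp", "pin"), 1e9)
        springs += [
            SpringElement(
                f"s:{lab}", ("ground",), ("part_point", "blk", [x, 0.0, z]), 1.0, ax
            )
            for lab, ax, x, z in (
                ("x", np.array([1.0, 0, 0]), 0.0, 10.0),
                ("y", np.array([0, 1.0, 0]), 10.0, 0.0),
                ("z", np.array([0, 0, 1.0]), 0.0, 0.0),
            )
        ]
        sys_ = assemble_system([mesh], {"blk": BONE}, springs, [rp])
        f = np.zeros(sys_.ndof)
        f[3 * 0 + 0] = 100.0
        res = solve_static(sys_, f)  # solvable: positive definite
        assert np.isfinite(res.max_total_deformation)

    def test_unconstrained_part_reports_singular(self):
        mesh = gen_box_mesh("blk", (10.0, 10.0, 10.0), (1, 1, 1))
        sys_ = assemble_system([mesh], {"blk": BONE})
        with pytest.raises(SingularSystemError):
            solve_static(sys_, np.zeros(sys_.ndof))


class TestSolveStatic:
    def test_uniaxial_patch_test_exact(self):
        # constant-strain state reproduced to near machine precision
        mesh = gen_box_mesh("bar", (20.0, 10.0, 10.0), (4, 2, 2))
        fixed = fix_face(mesh, 0, 0.0, dofs=(0,))
        left = np.where(np.abs(mesh.nodes[:, 0]) < 1e-9)[0]
        fixed += [("bar", int(left[0]), 1), ("bar", int(left[0]), 2),
                  ("bar", int(left[-1]), 1)]
        sys_ = assemble_system([mesh], {"bar": MaterialSpec(1000.0, 0.3)}, fixed=fixed)
        sigma = 2.0
        f = np.zeros(sys_.ndof)
        for tri in mesh.boundary_facets():
            p = mesh.nodes[tri]
            if np.all(p[:, 0] > 20 - 1e-9):
                a = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
                for n in tri:
                    f[3 * n] += sigma * a / 3
        res = solve_static(sys_, f)
        assert np.allclose(res.strains[:, 0], sigma / 1000.0, atol=1e-10)
        assert np.abs(res.strains[:, 3:]).max() < 1e-10
        assert res.residual < 1e-10

    def test_single_grounded_spring_closed_form(self):
        # one spring k with force F: displacement F/k, reaction -F
        # nearly massless/forceless elastic block so the spring dominates
        mesh = gen_box_mesh("blk", (5.0, 5.0, 5.0), (1, 1, 1))
        k = 250.0
        springs = make_ground_springs("g", ("part_point", "blk", [0.0, 0.0, 0.0]), k)
        # anchor remaining modes rigidly
        fixed = [("blk", i, c) for i in range(len(mesh.nodes)) for c in range(3)
                 if not np.allclose(mesh.nodes[i], [0, 0, 0])]
        soft = MaterialSpec(1e-9, 0.0)
        sys_ = assemble_system([mesh], {"blk": soft}, springs, fixed=fixed)
        n0 = int(np.where(np.all(np.abs(mesh.nodes) < 1e-9, axis=1))[0][0])
        F = 40.0
        f = np.zeros(sys_.ndof)
        f[3 * n0 + 1] = F
        res = solve_static(sys_, f)
        assert res.u[n0, 1] == pytest.approx(F / k, rel=1e-6)
        assert res.grounded_reaction("g") == pytest.approx([0, -F, 0], abs=1e-6)

    def test_linearity_in_load(self, rng):
        mesh = gen_box_mesh("bar", (20.0, 10.0, 10.0), (2, 1, 1))
        sys_ = assemble_system(
            [mesh], {"bar": BONE}, fixed=fix_face(mesh, 0, 0.0)
        )
        f = np.zeros(sys_.ndof)
        f[rng.integers(0, sys_.ndof, 5)] = rng.normal(size=5) * 100
        u1 = solve_static(sys_, f).u
        u2 = solve_static(sys_, 2.5 * f).u
        assert np.allclose(u2, 2.5 * u1, atol=1e-10 * np.abs(u1).max())

    def test_rigid_rotation_strain_is_second_order(self):
        # small rigid rotation imposed via fixed dofs produces strain ~ theta^2
        mesh = gen_box_mesh("blk", (10.0, 10.0, 10.0), (2, 2, 2))
        theta = 1e-4
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        u_imposed = mesh.nodes @ R.T - mesh.nodes
        from stancelimb.fem_solver import _tet_B_and_volume

        for tet in mesh.tets[:20]:
            B, _ = _tet_B_and_volume(mesh.nodes[tet])
            eps = B @ u_imposed[tet].ravel()
            assert np.abs(eps).max() <= theta**2 * 1.01

    def test_cantilever_tube_matches_beam_formula(self):
        # Euler-Bernoulli oracle P L^3 / 3 E I at the default mesh density
        E, P, L, ro, ri = 17000.0, 100.0, 300.0, 15.0, 10.0
        I = np.pi / 4 * (ro**4 - ri**4)
        euler = P * L**3 / (3 * E * I)
        mesh = gen_bone_mesh(BoneSpec("tube", L, ro, ri, 8.0))
        sys_ = assemble_system(
            [mesh], {"tube": MaterialSpec(E, 0.3)}, fixed=fix_face(mesh, 1, 0.0)
        )
        tip = np.where(mesh.nodes[:, 1] > L - 1e-9)[0]
        f = np.zeros(sys_.ndof)
        f[3 * tip + 2] = P / len(tip)
        res = solve_static(sys_, f)
        tip_def = res.u[tip, 2].mean()
        assert abs(tip_def - euler) / euler < 0.15


class TestRemotePoints:
    def _patched_tube(self):
        mesh = gen_bone_mesh(BoneSpec("tube", 60.0, 12.0, 8.0, 6.0))
        bf = mesh.boundary_facets()
        cap = bf[np.all(np.abs(mesh.nodes[bf][:, :, 1] - 60.0) < 1e-9, axis=1)]
        mesh.patches["cap"] = cap
        return mesh

    def test_distributing_load_preserves_force_and_moment(self):
        mesh = self._patched_tube()
        rp = RemotePoint("cop", [5.0, 80.0, -3.0], "tube", "cap")
        sys_ = assemble_system(
            [mesh], {"tube": BONE}, fixed=fix_face(mesh, 1, 0.0), remote_points=[rp]
        )
        F = np.array([30.0, -50.0, 20.0])
        f = distribute_remote_load(sys_, "cop", F)
        nodal = f[: 3 * len(sys_.nodes)].reshape(-1, 3)
        assert np.allclose(nodal.sum(axis=0), F, atol=1e-10)
        M = np.cross(sys_.nodes - rp.location, nodal).sum(axis=0)
        assert np.allclose(M, 0.0, atol=1e-8)

    def test_grounding_at_remote_point_acts_as_pin(self):
        # reaction of order 2e3 N over k = 1e9 N/mm: the coupled patch moves
        # by ~1e-6 mm, i.e. the femoral head is effectively pinned
        mesh = self._patched_tube()
        rp = RemotePoint("head", [0.0, 60.0, 0.0], "tube", "cap")
        springs = make_ground_springs("grounding", ("rp", "head"), 1e9)
        springs += [
            SpringElement(
                f"stab:{lab}", ("ground",), ("part_point", "tube", p), 1.0, ax
            )
            for lab, ax, p in (
                ("x", np.array([1.0, 0, 0]), [0.0, 0.0, 12.0]),
                ("y", np.array([0, 1.0, 0]), [-12.0, 0.0, 0.0]),
                ("z", np.array([0, 0, 1.0]), [12.0, 0.0, 0.0]),
            )
        ]
        sys_ = assemble_system([mesh], {"tube": BONE}, springs, [rp])
        f = np.zeros(sys_.ndof)
        bottom = np.where(mesh.nodes[:, 1] < 1e-9)[0]
        f[3 * bottom + 1] = 2000.0 / len(bottom)
        res = solve_static(sys_, f)
        u_rp = sys_.rp_average("head", res.u)
        assert np.linalg.norm(u_rp) <= 1e-5
        assert res.grounded_reaction("grounding")[1] == pytest.approx(
            -2000.0, rel=1e-3
        )

    def test_rigid_coupling_available_by_flag(self):
        mesh = self._patched_tube()
        rp = RemotePoint("head", [0.0, 60.0, 0.0], "tube", "cap", coupling="rigid")
        sys_ = assemble_system(
            [mesh], {"tube": BONE}, fixed=fix_face(mesh, 1, 0.0), remote_points=[rp]
        )
        F = np.array([0.0, -500.0, 0.0])
        f = distribute_remote_load(sys_, "head", F)
        res = solve_static(sys_, f)
        assert np.isfinite(res.max_total_deformation)
        assert res.max_total_deformation > 0


class TestGlobalEquilibrium:
    def test_solved_case_balances(self, solved_pos4):
        assert solved_pos4["report"].equilibrium_ok

    def test_zero_loads_zero_residual(self):
        mesh = gen_box_mesh("blk", (10.0, 10.0, 10.0), (1, 1, 1))
        sys_ = assemble_system([mesh], {"blk": BONE}, fixed=fix_face(mesh, 1, 0.0))
        res = solve_static(sys_, np.zeros(sys_.ndof))
        assert global_equilibrium_check(res, np.zeros(sys_.ndof)) < 1e-12

    def test_randomised_loads_balance(self, rng):
        mesh = gen_box_mesh("bar", (20.0, 10.0, 10.0), (2, 1, 1))
        sys_ = assemble_system([mesh], {"bar": BONE}, fixed=fix_face(mesh, 0, 0.0))
        for _ in range(10):
            f = np.zeros(sys_.ndof)
            idx = rng.integers(0, sys_.ndof, size=6)
            f[idx] = rng.normal(size=6) * 200
            res = solve_static(sys_, f)
            resid = global_equilibrium_check(res, f)
            total = np.linalg.norm(f.reshape(-1, 3).sum(axis=0))
            assert resid <= 1e-6 * max(1.0, total)
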