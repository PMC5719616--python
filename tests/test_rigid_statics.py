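"""Rigid-body statics: inertial bookkeeping, equilibrium, min/max recruitment.

The recruitment implementation (a linear program) is cross-checked against an
independent brute-force oracle: bisection on the peak activation with
feasibility decided by enumerating the vertices of the box-constrained
equality polytope.
"""

from itertools import combinations, product

import numpy as np
import pytest

from stancelimb.rigid_statics import (
    BodySegment,
    EquilibriumSystem,
    LimbLinkage,
    MuscleElement,
    RecruitmentError,
    assemble_equilibrium,
    hip_reaction,
    inertial_force,
    quasi_static_ratio,
    recruit_minmax,
)
from stancelimb.synthetic_anatomy import GaitPosition


def make_position(grf, cop, index=1, flexion=10.0):
    return GaitPosition(
        index=index,
        pct_gait=10.0,
        knee_flexion=flexion,
        grf=np.asarray(grf, float),
        cop=np.asarray(cop, float),
        segment_accel={"thigh": np.zeros(3), "leg_foot": np.zeros(3)},
    )


# ---------------------------------------------------------------------------
# Inertial forces and the quasi-static premise
# ---------------------------------------------------------------------------


class TestInertialForce:
    @pytest.mark.parametrize(
        "components,expected",
        [
            ((-3.0, -11.0, -2.0), 12),  # thigh, mid-stance
            ((-41.0, -10.0, 9.0), 43),  # leg+foot, early stance peak
            ((17.0, 13.0, -3.0), 22),  # leg+foot, heel strike
            ((-15.0, 8.0, 2.0), 17),  # thigh, toe-off
        ],
    )
    def test_magnitudes_match_reference_cells(self, components, expected):
        # segment chosen so that mass * accel reproduces the target components
        seg = BodySegment("thigh", 6.22, accel=np.asarray(components) / 6.22)
        f, mag = inertial_force(seg)
        assert np.allclose(f, components)
        assert round(mag) == expected

    def test_zero_acceleration_gives_zero_force(self):
        f, mag = inertial_force(BodySegment("thigh", 6.22))
        assert np.allclose(f, 0.0) and mag == 0.0

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            BodySegment("thigh", 0.0)


class TestQuasiStaticRatio:
    def test_printed_magnitude_pair_gives_ratio(self):
        # inertial 43 N (leg+foot) against a 592 N GRF
        pos = make_position([0, 592.0, 0], [0, 0, 0])
        pos.segment_accel["leg_foot"] = np.array([-41.0, -10.0, 9.0]) / 3.8
        ratios, ok = quasi_static_ratio([pos])
        assert ratios[1] == pytest.approx(0.0729, abs=5e-4)
        assert ok

    def test_zero_accelerations_flag_true(self):
        pos = make_position([0, 500.0, 0], [0, 0, 0])
        ratios, ok = quasi_static_ratio([pos])
        assert ratios[1] == 0.0 and ok

    def test_zero_grf_position_excluded(self):
        pos = make_position([0, 0.0, 0], [0, 0, 0])
        pos.segment_accel["thigh"] = np.array([10.0, 0, 0])
        ratios, ok = quasi_static_ratio([pos])
        assert np.isinf(ratios[1]) and ok

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            quasi_static_ratio([])


# ---------------------------------------------------------------------------
# Equilibrium assembly
# ---------------------------------------------------------------------------


def simple_linkage():
    return LimbLinkage(
        hip_center=[0.0, 500.0, 0.0],
        knee_center=[0.0, 250.0, 0.0],
        knee_axis=[1.0, 0.0, 0.0],
    )


class TestAssembleEquilibrium:
    def test_no_muscles_zero_grf_gives_zero_load(self):
        sys_ = assemble_equilibrium(simple_linkage(), make_position([0, 0, 0], [0, 0, 0]), [])
        assert np.allclose(sys_.d, 0.0)
        assert sys_.C.shape == (10, 0)

    def test_single_knee_muscle_moment_row_coefficient(self):
        # muscle inserting 30 mm anterior of the knee and pulling straight up
        # has a knee-axis moment arm of exactly -30 mm
        linkage = simple_linkage()
        m = MuscleElement(
            "m", "m",
            origin=("femur", [0.0, 400.0, 30.0]),
            insertion=("tibia", [0.0, 200.0, 30.0]),
            strength=100.0,
        )
        sys_ = assemble_equilibrium(linkage, make_position([0, 0, 0], [0, 0, 0]), [m])
        # moment about x at knee: r x u with r = (0, -50, 30), u = (0, 1, 0)
        assert sys_.C[9, 0] == pytest.approx(-30.0)

    def test_planar_two_muscle_system_matches_hand_derivation(self):
        # two parallel vertical muscles inserting at z = +a and z = -b below
        # the knee: hand-derived force rows are unit y, knee-moment row -a, +b
        linkage = simple_linkage()
        a, b = 40.0, 25.0
        muscles = [
            MuscleElement(
                "ant", "ant", ("femur", [0, 400.0, a]), ("tibia", [0, 200.0, a]), 1.0
            ),
            MuscleElement(
                "post", "post", ("femur", [0, 400.0, -b]), ("tibia", [0, 200.0, -b]), 1.0
            ),
        ]
        sys_ = assemble_equilibrium(linkage, make_position([0, 0, 0], [0, 0, 0]), muscles)
        expected_legfoot_rows = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        assert np.allclose(sys_.C[0:3], expected_legfoot_rows)
        assert np.allclose(sys_.C[9], [-a, b])
        # both ends on the limb and collinear: whole-limb hip moments cancel
        assert np.allclose(sys_.C[6:9], 0.0, atol=1e-12)

    def test_zero_length_muscle_rejected(self):
        m = MuscleElement(
            "bad", "bad", ("femur", [0, 300.0, 0]), ("tibia", [0, 300.0, 0]), 1.0
        )
        with pytest.raises(ValueError, match="zero-length"):
            assemble_equilibrium(
                simple_linkage(), make_position([0, 0, 0], [0, 0, 0]), [m]
            )


# ---------------------------------------------------------------------------
# Min/max recruitment against the brute-force oracle
# ---------------------------------------------------------------------------


def toy_system(C, d, R=None):
    C = np.asarray(C, float)
    R = np.zeros((C.shape[0], 0)) if R is None else np.asarray(R, float)
    return EquilibriumSystem(C=C, R=R, d=np.asarray(d, float), muscles=[])


def minmax_bruteforce(C, R, d, N, iters=80):
    """Independent oracle: bisection on beta; feasibility of
    {C f + R r = d, 0 <= f <= beta N} by vertex enumeration after projecting
    out the free reactions."""
    C, R, d, N = (np.asarray(a, float) for a in (C, R, d, N))
    U, s, _ = np.linalg.svd(R) if R.size else (np.eye(C.shape[0]), np.zeros(0), None)
    rank = int((s > 1e-10).sum())
    P = U[:, rank:].T  # rows orthogonal to the reaction range
    A, b = P @ C, P @ d
    m = np.linalg.matrix_rank(A) if A.size else 0
    n = C.shape[1]

    def feasible(beta):
        ub = beta * N
        scale = max(1.0, np.abs(b).max() if b.size else 0.0)
        if m == 0:
            return np.allclose(b, 0.0, atol=1e-9 * scale)
        for free in combinations(range(n), m):
            bound_vars = [i for i in range(n) if i not in free]
            Af = A[:, list(free)]
            if np.linalg.matrix_rank(Af) < m:
                continue
            for vals in product((0.0, 1.0), repeat=len(bound_vars)):
                f = np.zeros(n)
                for i, v in zip(bound_vars, vals):
                    f[i] = v * ub[i]
                rhs = b - A[:, bound_vars] @ f[bound_vars] if bound_vars else b
                sol, res, *_ = np.linalg.lstsq(Af, rhs, rcond=None)
                f[list(free)] = sol
                if (
                    np.all(f >= -1e-9 * max(1, ub.max()))
                    and np.all(f <= ub + 1e-9 * max(1, ub.max()))
                    and np.linalg.norm(A @ f - b) <= 1e-8 * scale
                ):
                    return True
        return False

    hi = 1.0
    while not feasible(hi):
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("oracle: infeasible system")
    lo = 0.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return hi


class TestRecruitMinmax:
    def test_single_muscle_single_equation(self):
        # moment arm r = 20 mm, required moment M = 500 N*mm, strength 100 N
        sol = recruit_minmax(toy_system([[20.0]], [500.0]), np.array([100.0]))
        assert sol.forces[0] == pytest.approx(25.0, abs=1e-8)
        assert sol.beta == pytest.approx(0.25, abs=1e-9)

    def test_two_identical_parallel_muscles_share_equally(self):
        # 1-D grid-search oracle: min over s in [0,1] of max(s, 1-s) is s=1/2
        M, r, N = 600.0, 30.0, 200.0
        splits = np.linspace(0, 1, 100001)
        oracle = splits[np.argmin(np.maximum(splits, 1 - splits))]
        sol = recruit_minmax(toy_system([[r, r]], [M]), np.array([N, N]))
        assert oracle == pytest.approx(0.5, abs=1e-4)
        assert sol.forces == pytest.approx([M / (2 * r)] * 2, abs=1e-6)

    def test_three_muscle_planar_case_matches_bisection_oracle(self):
        C = np.array([[15.0, 25.0, 40.0], [1.0, 1.0, -1.0]])
        d = np.array([900.0, 5.0])
        N = np.array([100.0, 200.0, 400.0])
        sol = recruit_minmax(toy_system(C, d), N)
        expected = minmax_bruteforce(C, np.zeros((2, 0)), d, N)
        assert sol.beta == pytest.approx(expected, abs=1e-6)

    def test_random_small_systems_match_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 5))
            m = int(rng.integers(1, 4))
            n_r = int(rng.integers(0, 2))
            C = rng.normal(size=(m, n))
            R = rng.normal(size=(m, n_r))
            f0 = rng.uniform(0, 5, size=n)
            r0 = rng.normal(size=n_r)
            d = C @ f0 + (R @ r0 if n_r else 0.0)
            N = rng.uniform(1.0, 10.0, size=n)
            sol = recruit_minmax(toy_system(C, d, R), N)
            expected = minmax_bruteforce(C, R, d, N)
            assert sol.beta == pytest.approx(expected, abs=1e-6), (C, R, d, N)

    def test_equilibrium_residual_invariant(self, rng):
        for _ in range(10):
            C = rng.normal(size=(3, 4))
            f0 = rng.uniform(0, 5, size=4)
            d = C @ f0
            sol = recruit_minmax(toy_system(C, d), np.full(4, 10.0))
            assert sol.residual <= 1e-8 * max(1.0, np.linalg.norm(d))
            assert np.all(sol.forces >= -1e-12)
            assert sol.beta == pytest.approx(
                np.max(sol.forces / 10.0), abs=1e-9
            )

    def test_load_scaling_scales_solution(self):
        C = np.array([[15.0, 25.0, 40.0], [1.0, 1.0, -1.0]])
        d = np.array([900.0, 5.0])
        N = np.array([100.0, 200.0, 400.0])
        sol1 = recruit_minmax(toy_system(C, d), N)
        sol3 = recruit_minmax(toy_system(C, 3.0 * d), N)
        # to LP tolerance (the tie-break stage allows a 1e-9 slack on beta)
        assert sol3.beta == pytest.approx(3.0 * sol1.beta, rel=1e-7, abs=1e-8)
        assert sol3.forces == pytest.approx(3.0 * sol1.forces, abs=1e-6)

    def test_redundant_duplicate_muscle_never_increases_beta(self, rng):
        for _ in range(10):
            C = rng.normal(size=(2, 3))
            d = C @ rng.uniform(0, 5, size=3)
            N = rng.uniform(1, 10, size=3)
            base = recruit_minmax(toy_system(C, d), N).beta
            C2 = np.hstack([C, C[:, :1]])
            N2 = np.concatenate([N, N[:1]])
            dup = recruit_minmax(toy_system(C2, d), N2).beta
            assert dup <= base + 1e-9

    def test_infeasible_system_raises_named_error(self):
        # one muscle that cannot produce a negative moment
        with pytest.raises(RecruitmentError, match="infeasible"):
            recruit_minmax(toy_system([[1.0]], [-5.0]), np.array([10.0]))


class TestHipReaction:
    def test_zero_loads_zero_reaction(self):
        linkage = simple_linkage()
        sys_ = assemble_equilibrium(linkage, make_position([0, 0, 0], [0, 0, 0]), [])
        sol = recruit_minmax(sys_, np.zeros(0))
        vec, mag = hip_reaction(sol)
        assert np.allclose(vec, 0.0) and mag == 0.0

    def test_vertical_toy_case_balances_net_vertical_load(self):
        # vertical GRF of 600 N through the joint centres, no muscles:
        # the hip reaction carries exactly the net vertical load
        linkage = simple_linkage()
        pos = make_position([0.0, 600.0, 0.0], [0.0, 0.0, 0.0])
        sys_ = assemble_equilibrium(linkage, pos, [])
        sol = recruit_minmax(sys_, np.zeros(0))
        vec, mag = hip_reaction(sol)
        assert vec == pytest.approx([0.0, -600.0, 0.0], abs=1e-7)
        assert mag == pytest.approx(600.0, abs=1e-7)

    def test_reaction_closes_equilibrium_by_definition(self, solved_pos4):
        sol = solved_pos4["recruitment"]
        assert sol.residual <= 1e-7
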