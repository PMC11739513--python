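"""Hemodynamics: Murray radii, Hagen-Poiseuille resistance, the 0D linear
system, bisection calibration of the super-lobule resistance, and wall
shear stress."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hepavasc.errors import ArgumentError, InfeasibilityError, SolverError, TopologyError
from hepavasc.growth import VascularTree, ConnectedNetworkTopology
from hepavasc.hemodynamics import (
    ML_MIN_TO_MM3_S,
    SUPER_LOBULE,
    VESSEL,
    BoundaryConditions,
    Fluid,
    FlowNetwork,
    RadiusPolicy,
    assemble_system,
    assign_radii,
    build_network,
    find_sl_resistance,
    hp_resistance,
    solve_flow,
    two_branch_fixture,
    wall_shear_stress,
)

FLUID = Fluid(mu_cP=3.5)


class TestHagenPoiseuille:
    def test_zero_length_zero_resistance(self):
        assert hp_resistance(0.0, 1.0, FLUID) == 0.0

    def test_inverse_fourth_power_scaling(self):
        assert hp_resistance(10.0, 2.0, FLUID) == pytest.approx(
            hp_resistance(10.0, 1.0, FLUID) / 16.0
        )

    def test_reference_value(self):
        # 8 * 3.5e-4 * 10 / pi = 8.913e-3 dyn*s/mm^5
        assert hp_resistance(10.0, 1.0, FLUID) == pytest.approx(
            8.913e-3, rel=1e-3
        )

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ArgumentError):
            hp_resistance(1.0, 0.0, FLUID)


class TestWallShearStress:
    def test_zero_flow_zero_stress(self):
        assert wall_shear_stress(0.0, 1.0, FLUID) == 0.0

    def test_inverse_cubic_scaling(self):
        assert wall_shear_stress(100.0, 0.5, FLUID) == pytest.approx(
            8.0 * wall_shear_stress(100.0, 1.0, FLUID)
        )

    def test_reference_value(self):
        # 4 * 3.5e-4 * 100 / pi = 4.456e-2 dyn/mm^2
        assert wall_shear_stress(100.0, 1.0, FLUID) == pytest.approx(
            4.456e-2, rel=1e-3
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.1, 1e4), st.floats(0.05, 20.0))
    def test_positive_and_symmetric_in_flow_sign(self, q, r):
        assert wall_shear_stress(-q, r, FLUID) == wall_shear_stress(q, r, FLUID) > 0


def tree_from_parents(parents, terminals, label="inlet"):
    """Tiny tree with unit-spaced dummy positions for radius tests."""
    n = len(parents)
    rng = np.random.default_rng(0)
    return VascularTree(
        positions=rng.normal(size=(n, 3)),
        parents=parents,
        label=label,
        terminal_map=dict(terminals),
    )


class TestMurrayRadii:
    def test_unbranched_chain_keeps_root_radius(self):
        tree = tree_from_parents([-1, 0, 1], {0: 2})
        radii, _ = assign_radii(tree, r_root=7.5, gamma=3.0)
        np.testing.assert_allclose(radii, 7.5)

    def test_symmetric_bifurcation(self):
        tree = tree_from_parents([-1, 0, 1, 1], {0: 2, 1: 3})
        radii, _ = assign_radii(tree, r_root=1.0, gamma=3.0)
        # edge 0 is the trunk; edges to the two terminals get 2^(-1/3)
        assert radii[0] == pytest.approx(1.0)
        np.testing.assert_allclose(radii[1:], 2 ** (-1 / 3), rtol=1e-12)

    def test_trifurcation_partitions_cubed_radii(self):
        # children serve 1, 2, 3 of 6 super lobules
        parents = [-1, 0,  0, 2,  0, 4, 4,  2, 7, 7]
        #           0  1   2 3   4  5 6   7  8  9
        # node1: terminal SL0 (1); node2 subtree: nodes 3 (SL5) and 7->8,9
        parents = [-1, 0, 0, 2, 0, 4, 4, 3, 7, 7]
        terminals = {0: 1, 1: 5, 2: 6, 3: 7, 4: 8, 5: 9}
        # subtree SL counts: child edge (0,1) -> 1; (0,2) -> 3; (0,4) -> 2
        tree = tree_from_parents(parents, terminals)
        radii, n_edge = assign_radii(tree, r_root=1.0, gamma=3.0)
        edges = tree.edges
        by_child = dict(zip(edges[:, 1], radii**3))
        assert by_child[1] == pytest.approx(1 / 6)
        assert by_child[4] == pytest.approx(2 / 6)
        assert by_child[2] == pytest.approx(3 / 6)
        assert by_child[1] + by_child[2] + by_child[4] == pytest.approx(1.0)

    def test_generated_model_murray_conservation(self, bundle10):
        """At every branch: omega sums to 1 and r^gamma is conserved."""
        net = bundle10.network
        gamma = bundle10.config.flow.gamma
        vm = net.kind == VESSEL
        children_of = {}
        for e in np.flatnonzero(vm):
            children_of.setdefault(int(net.prox[e]), []).append(e)
        incoming = {int(net.dist[e]): e for e in np.flatnonzero(vm)}
        n_branches = 0
        for node, kids in children_of.items():
            if len(kids) < 2 or node not in incoming:
                continue
            n_branches += 1
            parent = incoming[node]
            omega = net.n_downstream_sl[kids] / net.n_downstream_sl[parent]
            assert omega.sum() == pytest.approx(1.0, rel=1e-12)
            assert (net.r[kids] ** gamma).sum() == pytest.approx(
                net.r[parent] ** gamma, rel=1e-10
            )
        assert n_branches > 0


def raw_bc(P_in, Q_target=1.0, P_out=0.0):
    return BoundaryConditions(P_in=P_in, P_out=P_out, Q_target=Q_target)


class TestLinearSystem:
    def single_vessel(self, R=2.0):
        return FlowNetwork(
            prox=np.array([0]),
            dist=np.array([1]),
            kind=np.array([VESSEL]),
            L=np.ones(1),
            r=np.ones(1),
            R=np.array([R]),
            n_nodes=2,
            inlet_node=0,
            outlet_node=1,
        )

    def test_single_vessel_ohms_law(self):
        sol = solve_flow(self.single_vessel(R=2.0), raw_bc(P_in=10.0), R_SL=0.0)
        assert sol.Q_in == pytest.approx(5.0)
        assert sol.network.n == 3

    def test_row_count_equals_n(self, bundle10):
        net = bundle10.network
        system = assemble_system(net, raw_bc(P_in=1.0), R_SL=1.0)
        assert system.A.shape == (net.n, net.n)
        assert net.n == net.j + net.k + net.l

    def test_disconnected_network_refused(self):
        net = self.single_vessel()
        net.n_nodes = 3  # node 2 floats free
        with pytest.raises(TopologyError, match="disconnected"):
            net.validate_connected()
        with pytest.raises(SolverError):
            solve_flow(net, raw_bc(P_in=1.0), R_SL=0.0)

    @pytest.mark.parametrize(
        "R1, R2, R_SL, Q1, Q2, R_eq",
        [
            (1, 1, 0, 0.5, 0.5, 1.0),
            (1, 1, 100, 0.5, 0.5, 51.0),
            (1, 10, 0, 0.91, 0.09, 1.82),
            (1, 10, 100, 0.54, 0.46, 55.14),
        ],
    )
    def test_two_branch_reference_rows(self, R1, R2, R_SL, Q1, Q2, R_eq):
        """The worked two-branch circuit: imposed Q_in=1, solved flow split
        and equivalent resistance at printed two-decimal precision."""
        net = two_branch_fixture(R1, R2)
        sol = solve_flow(net, raw_bc(P_in=0.0, Q_target=1.0), R_SL, drive="flow")
        assert round(float(sol.Q_sl[0]), 2) == Q1
        assert round(float(sol.Q_sl[1]), 2) == Q2
        assert round(sol.R_eq, 2) == R_eq
        assert sol.dP == pytest.approx(sol.R_eq, rel=1e-12)  # Q_in = 1

    def test_flow_evenness_increases_with_sl_resistance(self):
        spreads = [
            np.ptp(
                solve_flow(
                    two_branch_fixture(1, 10),
                    raw_bc(P_in=0.0, Q_target=1.0),
                    rsl,
                    drive="flow",
                ).Q_sl
            )
            for rsl in (0.0, 10.0, 100.0, 1000.0)
        ]
        assert spreads == sorted(spreads, reverse=True)


class TestSeriesParallelOracle:
    """R_eq from the linear solve must match recursive series/parallel
    reduction on random mirrored tree-SL-tree networks (<= 30 elements)."""

    @staticmethod
    def random_network(rng):
        # random inlet tree; the outlet tree mirrors it so the network is
        # series-parallel reducible
        n_leaves = rng.integers(2, 7)
        parents = [-1]
        # grow a random tree until it has n_leaves leaves
        while True:
            leaves = [
                i for i in range(len(parents))
                if i not in parents
            ]
            if len(leaves) >= n_leaves:
                break
            parents.append(int(rng.choice(len(parents))))
        R_in = rng.uniform(0.1, 10.0, size=len(parents) - 1)
        R_out = rng.uniform(0.1, 10.0, size=len(parents) - 1)
        R_SL = rng.uniform(0.0, 50.0)
        return parents, R_in, R_out, R_SL, leaves

    @staticmethod
    def reduce_eq(parents, R_in, R_out, R_SL, leaves):
        children = {}
        for child in range(1, len(parents)):
            children.setdefault(parents[child], []).append(child)

        def resist(node):
            if node in leaves and node not in children:
                return R_SL
            return 1.0 / sum(
                1.0 / (R_in[c - 1] + resist(c) + R_out[c - 1])
                for c in children[node]
            )

        return resist(0)

    @staticmethod
    def to_network(parents, R_in, R_out, R_SL, leaves):
        n = len(parents)
        prox, dist, R, kind = [], [], [], []
        # inlet nodes 0..n-1, outlet nodes n..2n-1 (mirrored), SLs at leaves
        for child in range(1, n):
            prox.append(parents[child]); dist.append(child)
            R.append(R_in[child - 1]); kind.append(VESSEL)
            prox.append(n + child); dist.append(n + parents[child])
            R.append(R_out[child - 1]); kind.append(VESSEL)
        for leaf in leaves:
            prox.append(leaf); dist.append(n + leaf)
            R.append(0.0); kind.append(SUPER_LOBULE)
        m = len(prox)
        return FlowNetwork(
            prox=np.asarray(prox),
            dist=np.asarray(dist),
            kind=np.asarray(kind),
            L=np.ones(m),
            r=np.ones(m),
            R=np.asarray(R),
            n_nodes=2 * n,
            inlet_node=0,
            outlet_node=n,
        ), R_SL

    def test_equivalent_resistance_matches_reduction(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            parts = self.random_network(rng)
            expected = self.reduce_eq(*parts)
            net, R_SL = self.to_network(*parts)
            sol = solve_flow(net, raw_bc(P_in=1.0), R_SL)
            assert sol.R_eq == pytest.approx(expected, rel=1e-10)
            assert sol.kcl_residual() <= 1e-10


class TestCalibration:
    def test_single_sl_ohm_inversion(self):
        net = FlowNetwork(
            prox=np.array([0]),
            dist=np.array([1]),
            kind=np.array([SUPER_LOBULE]),
            L=np.zeros(1),
            r=np.full(1, np.nan),
            R=np.zeros(1),
            n_nodes=2,
            inlet_node=0,
            outlet_node=1,
        )
        R = find_sl_resistance(net, raw_bc(P_in=10.0, Q_target=2.0), tol=1e-10)
        assert R == pytest.approx(5.0, abs=1e-8)

    def test_two_branch_inverse_recovers_reference(self):
        net = two_branch_fixture(1.0, 10.0)
        R = find_sl_resistance(
            net, raw_bc(P_in=12240.0 / 222.0, Q_target=1.0), tol=1e-8
        )
        assert abs(R - 100.0) < 1e-6

    def test_infeasible_when_vessels_alone_too_resistive(self):
        net = two_branch_fixture(1.0, 1.0)
        # vessel-only equivalent resistance is 1, so dP=1 passes at most Q=1
        with pytest.raises(InfeasibilityError, match="non-negative R_SL"):
            find_sl_resistance(net, raw_bc(P_in=1.0, Q_target=2.0))

    def test_monotone_in_boundary_conditions(self):
        net = two_branch_fixture(1.0, 10.0)

        def rsl(dp, q):
            return find_sl_resistance(net, raw_bc(P_in=dp, Q_target=q), tol=1e-10)

        # at fixed dP, R_SL decreases with target flow
        assert rsl(100.0, 1.0) > rsl(100.0, 2.0) > rsl(100.0, 4.0)
        # at fixed flow, R_SL increases with dP
        assert rsl(50.0, 1.0) < rsl(100.0, 1.0) < rsl(200.0, 1.0)


class TestGeneratedModel:
    def test_kcl_and_ohm_residuals(self, solution10):
        assert solution10.kcl_residual() <= 1e-10
        assert solution10.ohm_residual() <= 1e-10

    def test_flow_conservation_through_super_lobules(self, solution10):
        assert solution10.Q_sl.sum() == pytest.approx(
            solution10.Q_in, rel=1e-12
        )
        net = solution10.network
        out = solution10.Q[net.dist == net.outlet_node].sum() - solution10.Q[
            net.prox == net.outlet_node
        ].sum()
        assert out == pytest.approx(solution10.Q_in, rel=1e-12)

    def test_calibration_meets_bulk_targets(self, bundle10, solution10):
        cfg = bundle10.config.flow
        q_ml_min = solution10.Q_in / ML_MIN_TO_MM3_S
        assert abs(q_ml_min - cfg.Q_target_ml_min) <= cfg.bisect_tol
        mean_q_sl = solution10.Q_sl.mean() / ML_MIN_TO_MM3_S
        assert mean_q_sl == pytest.approx(
            cfg.Q_target_ml_min / bundle10.partition.k, abs=1e-8
        )

    def test_equal_sl_resistance_identities(self, solution10):
        s = solution10.summary()
        assert s["R_SL_eq"] == pytest.approx(s["R_SL"] / s["n_SL"], rel=1e-12)
        # per-element Ohm: dP_SL = R_SL * Q_SL
        np.testing.assert_allclose(
            solution10.dP_sl,
            solution10.R_SL * solution10.Q_sl,
            rtol=1e-9,
            atol=1e-12,
        )

    def test_sl_elements_have_degree_two(self, bundle10):
        net = bundle10.network
        sl = net.kind == SUPER_LOBULE
        assert sl.sum() == 10
        # each SL endpoint is a tree terminal: exactly one vessel plus the SL
        for node in np.r_[net.prox[sl], net.dist[sl]]:
            degree = int((net.prox == node).sum() + (net.dist == node).sum())
            assert degree == 2
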