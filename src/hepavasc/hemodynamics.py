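"""Lumped-parameter (0D) hemodynamics on the connected vascular network.

Radii follow a downstream-weighted Murray's law: at each branch point

    r_child,i = (omega_i * r_parent^gamma)^(1/gamma),   sum_i omega_i = 1,

where omega_i is the fraction of super lobules served (inlet tree) or
drained (outlet tree) through child i, so r_parent^gamma = sum r_child^gamma
is conserved and radii are constant along unbranched chains. Each vessel is
a Hagen-Poiseuille resistor R = 8*mu*L/(pi*r^4); super lobules share one
lumped resistance R_SL.

The steady state is the electrical analogy: unknowns x = [Q_vessels,
Q_superlobules, P_nodes] of size n = j + k + l; rows are Ohm's law for each
of the j+k elements, Kirchhoff's current law at the l-2 interior nodes, and
two boundary rows (either both pressures, or an imposed inlet flow plus the
outlet pressure). The sparse system is solved by LU factorization.

R_SL is not known a priori; it is calibrated by bisection so the solved
inlet flow at the prescribed pressure drop matches the target flow rate.

Internal units are mm-dyn-s: pressure dyn/mm^2, flow mm^3/s, resistance
dyn*s/mm^5, viscosity dyn*s/mm^2. I/O helpers use mmHg, mL/min and cP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    ArgumentError,
    InfeasibilityError,
    SolverError,
    TopologyError,
)
from .growth import ConnectedNetworkTopology

__all__ = [
    "MMHG_TO_DYN_MM2",
    "ML_MIN_TO_MM3_S",
    "CP_TO_DYN_S_MM2",
    "Fluid",
    "RadiusPolicy",
    "BoundaryConditions",
    "FlowNetwork",
    "LinearSystem",
    "FlowSolution",
    "hp_resistance",
    "wall_shear_stress",
    "assign_radii",
    "build_network",
    "two_branch_fixture",
    "assemble_system",
    "solve_flow",
    "find_sl_resistance",
]

MMHG_TO_DYN_MM2 = 13.332237          # 1 mmHg = 133.32237 Pa = 13.332237 dyn/mm^2
ML_MIN_TO_MM3_S = 1000.0 / 60.0      # 1 mL/min in mm^3/s
CP_TO_DYN_S_MM2 = 1e-4               # 1 cP = 1e-3 Pa*s = 1e-4 dyn*s/mm^2

VESSEL, SUPER_LOBULE = 0, 1


@dataclass
class Fluid:
    """Newtonian perfusate. `mu_cP` is the dynamic viscosity in centipoise."""

    mu_cP: float = 3.5

    def __post_init__(self) -> None:
        if self.mu_cP <= 0:
            raise ArgumentError(f"viscosity must be positive, got {self.mu_cP}")

    @property
    def mu(self) -> float:
        """Viscosity in internal units, dyn*s/mm^2."""
        return self.mu_cP * CP_TO_DYN_S_MM2


@dataclass
class RadiusPolicy:
    """Murray-law radius assignment policy.

    gamma = 3 is the laminar-flow Murray exponent; the 15 mm root diameter
    matches the portal/hepatic vein trunks.
    """

    gamma: float = 3.0
    r_root_inlet: float = 7.5
    r_root_outlet: float = 7.5

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ArgumentError(f"gamma must be positive, got {self.gamma}")


@dataclass
class BoundaryConditions:
    """Bulk boundary conditions in internal units (dyn/mm^2, mm^3/s).

    `flow_unit` is the internal flow per reporting unit; the bisection
    tolerance is applied to flow expressed in the reporting unit so results
    are scale-stable (mL/min for clinical conditions, raw for fixtures).
    """

    P_in: float
    P_out: float
    Q_target: float
    flow_unit: float = 1.0

    @classmethod
    def clinical(
        cls,
        P_in_mmHg: float = 5.8,
        P_out_mmHg: float = 0.0,
        Q_target_ml_min: float = 767.0,
    ) -> "BoundaryConditions":
        """Portal-vein pressure in mmHg, inlet flow in mL/min."""
        if P_in_mmHg <= P_out_mmHg:
            raise ArgumentError(
                f"P_in ({P_in_mmHg} mmHg) must exceed P_out ({P_out_mmHg})"
            )
        if Q_target_ml_min <= 0:
            raise ArgumentError(
                f"Q_target must be positive, got {Q_target_ml_min}"
            )
        return cls(
            P_in=P_in_mmHg * MMHG_TO_DYN_MM2,
            P_out=P_out_mmHg * MMHG_TO_DYN_MM2,
            Q_target=Q_target_ml_min * ML_MIN_TO_MM3_S,
            flow_unit=ML_MIN_TO_MM3_S,
        )


@dataclass
class FlowNetwork:
    """Vessels + super-lobule elements between the two boundary nodes.

    Element arrays are aligned: entries with ``kind == VESSEL`` are pipe
    segments (geometry in `L`, `r`; resistance in `R`); entries with
    ``kind == SUPER_LOBULE`` share the calibrated lumped resistance and the
    per-super-lobule volume. Element orientation is proximal -> distal;
    solved flow may be negative (the perfusion module re-orients by sign).
    """

    prox: np.ndarray
    dist: np.ndarray
    kind: np.ndarray
    L: np.ndarray
    r: np.ndarray
    R: np.ndarray
    n_nodes: int
    inlet_node: int
    outlet_node: int
    sl_volume: float = 0.0
    node_positions: np.ndarray | None = None
    n_downstream_sl: np.ndarray | None = None

    @property
    def n_elements(self) -> int:
        return len(self.prox)

    @property
    def j(self) -> int:
        return int((self.kind == VESSEL).sum())

    @property
    def k(self) -> int:
        return int((self.kind == SUPER_LOBULE).sum())

    @property
    def l(self) -> int:
        return self.n_nodes

    @property
    def n(self) -> int:
        return self.n_elements + self.n_nodes

    @property
    def vessel_volumes(self) -> np.ndarray:
        return np.pi * self.r**2 * self.L

    @property
    def element_volumes(self) -> np.ndarray:
        V = self.vessel_volumes.copy()
        V[self.kind == SUPER_LOBULE] = self.sl_volume
        return V

    def validate_connected(self) -> None:
        """Union-find connectivity audit of the element graph."""
        parent = np.arange(self.n_nodes)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in zip(self.prox, self.dist):
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[ra] = rb
        roots = {find(i) for i in range(self.n_nodes)}
        if len(roots) != 1:
            raise TopologyError(
                f"network is disconnected: {len(roots)} components"
            )


def hp_resistance(L: float, r, fluid: Fluid):
    """Hagen-Poiseuille resistance 8*mu*L/(pi*r^4), dyn*s/mm^5."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ArgumentError("vessel radius must be positive")
    if np.any(np.asarray(L) < 0):
        raise ArgumentError("vessel length must be non-negative")
    out = 8.0 * fluid.mu * np.asarray(L, dtype=float) / (np.pi * r**4)
    return out if out.ndim else float(out)


def wall_shear_stress(Q, r, fluid: Fluid):
    """Poiseuille wall shear stress tau = 4*mu*|Q|/(pi*r^3), dyn/mm^2."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ArgumentError("vessel radius must be positive")
    out = 4.0 * fluid.mu * np.abs(np.asarray(Q, dtype=float)) / (np.pi * r**3)
    return out if out.ndim else float(out)


def _downstream_sl_counts(tree) -> np.ndarray:
    """Per-node count of super-lobule terminals in the subtree at that node.

    For the outlet tree "downstream" still means toward the leaves of its
    own rooted structure, i.e. the super lobules it drains.
    """
    counts = np.zeros(tree.n_nodes, dtype=np.int64)
    for node in tree.terminal_map.values():
        counts[node] += 1
    # parents precede children, so a reverse sweep accumulates subtrees
    for child in range(tree.n_nodes - 1, -1, -1):
        p = tree.parents[child]
        if p >= 0:
            counts[p] += counts[child]
    return counts


def assign_radii(tree, r_root: float, gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge radii by downstream-weighted Murray's law.

    Returns (radii, n_downstream_sl) aligned with ``tree.edges``. Because
    omega compounds multiplicatively along any root-to-edge path, the radius
    of an edge serving n of the N super lobules is r_root * (n/N)^(1/gamma).
    """
    counts = _downstream_sl_counts(tree)
    edges = tree.edges
    n_total = int(sum(counts[r] for r in tree.roots))
    if n_total == 0:
        raise TopologyError(f"{tree.label} tree reaches no super lobules")
    n_edge = counts[edges[:, 1]]
    if np.any(n_edge == 0):
        raise TopologyError(
            f"{tree.label} tree has branches serving 0 super lobules; "
            "prune before assigning radii"
        )
    radii = r_root * (n_edge / n_total) ** (1.0 / gamma)
    return radii, n_edge


def build_network(
    topology: ConnectedNetworkTopology,
    policy: RadiusPolicy,
    fluid: Fluid,
    sl_volume: float = 0.0,
) -> FlowNetwork:
    """Assemble the element arrays from the two trees and their linkage.

    Every space colonization edge becomes one vessel segment; super-lobule
    elements connect the matching inlet/outlet terminals. Global node ids:
    inlet-tree nodes first, then outlet-tree nodes.
    """
    inlet, outlet = topology.inlet, topology.outlet
    off = inlet.n_nodes

    prox, dist, kind, L, r, n_down = [], [], [], [], [], []
    for tree, r_root, shift in (
        (inlet, policy.r_root_inlet, 0),
        (outlet, policy.r_root_outlet, off),
    ):
        radii, n_edge = assign_radii(tree, r_root, policy.gamma)
        edges = tree.edges
        lengths = np.linalg.norm(
            tree.positions[edges[:, 1]] - tree.positions[edges[:, 0]], axis=1
        )
        prox.append(edges[:, 0] + shift)
        dist.append(edges[:, 1] + shift)
        kind.append(np.full(len(edges), VESSEL))
        L.append(lengths)
        r.append(radii)
        n_down.append(n_edge)

    sl_prox = np.array(
        [inlet.terminal_map[i] for i in range(topology.n_sl)], dtype=np.int64
    )
    sl_dist = np.array(
        [outlet.terminal_map[i] + off for i in range(topology.n_sl)],
        dtype=np.int64,
    )
    prox.append(sl_prox)
    dist.append(sl_dist)
    kind.append(np.full(topology.n_sl, SUPER_LOBULE))
    L.append(np.zeros(topology.n_sl))
    r.append(np.full(topology.n_sl, np.nan))
    n_down.append(np.ones(topology.n_sl, dtype=np.int64))

    Lc = np.concatenate(L)
    rc = np.concatenate(r)
    kc = np.concatenate(kind)
    R = np.zeros(len(kc))
    vmask = kc == VESSEL
    R[vmask] = hp_resistance(Lc[vmask], rc[vmask], fluid)

    net = FlowNetwork(
        prox=np.concatenate(prox),
        dist=np.concatenate(dist),
        kind=kc,
        L=Lc,
        r=rc,
        R=R,
        n_nodes=inlet.n_nodes + outlet.n_nodes,
        inlet_node=int(inlet.roots[0]),
        outlet_node=int(outlet.roots[0]) + off,
        sl_volume=sl_volume,
        node_positions=np.vstack([inlet.positions, outlet.positions]),
        n_downstream_sl=np.concatenate(n_down),
    )
    net.validate_connected()
    return net


def two_branch_fixture(R1: float, R2: float) -> FlowNetwork:
    """Two parallel branches, each vessel R_i -- super lobule -- vessel R_i.

    The minimal circuit demonstrating how the shared super-lobule resistance
    redistributes flow between asymmetric branches; resistances are set
    directly (unit-agnostic).
    """
    # nodes: 0 inlet, 1-2 branch 1 interior, 3-4 branch 2 interior, 5 outlet
    return FlowNetwork(
        prox=np.array([0, 2, 0, 4, 1, 3]),
        dist=np.array([1, 5, 3, 5, 2, 4]),
        kind=np.array([VESSEL, VESSEL, VESSEL, VESSEL, SUPER_LOBULE, SUPER_LOBULE]),
        L=np.ones(6),
        r=np.ones(6),
        R=np.array([R1, R1, R2, R2, 0.0, 0.0]),
        n_nodes=6,
        inlet_node=0,
        outlet_node=5,
        sl_volume=1.0,
    )


@dataclass
class LinearSystem:
    """Assembled sparse system A x = b with the documented unknown ordering
    x = [Q_elements (j vessels then k super lobules), P_nodes (l)]."""

    A: sp.csr_matrix
    b: np.ndarray
    network: FlowNetwork
    R_SL: float
    drive: str


def assemble_system(
    network: FlowNetwork,
    bc: BoundaryConditions,
    R_SL: float,
    drive: str = "pressure",
) -> LinearSystem:
    """Build the n x n system: j+k Ohm rows, l-2 KCL rows, 2 boundary rows.

    drive="pressure" imposes P at both boundary nodes; drive="flow" imposes
    the inlet flow rate and the outlet pressure (the configuration used when
    a flow is prescribed and the pressure drop is a result).
    """
    if R_SL < 0:
        raise ArgumentError(f"R_SL must be non-negative, got {R_SL}")
    m, l = network.n_elements, network.n_nodes
    n = m + l
    R = np.where(network.kind == SUPER_LOBULE, R_SL, network.R)
    elem = np.arange(m)
    b = np.zeros(n)

    # Ohm's law per element: P_prox - P_dist - R*Q = 0
    rows = [elem, elem, elem]
    cols = [m + network.prox, m + network.dist, elem]
    vals = [np.ones(m), -np.ones(m), -R]

    # KCL at interior nodes: sum Q_in - sum Q_out = 0
    node_row = np.full(l, -1, dtype=np.int64)
    interior = np.setdiff1d(
        np.arange(l), [network.inlet_node, network.outlet_node]
    )
    node_row[interior] = m + np.arange(len(interior))
    for ends, sign in ((network.prox, -1.0), (network.dist, 1.0)):
        nr = node_row[ends]
        has = nr >= 0
        rows.append(nr[has])
        cols.append(elem[has])
        vals.append(np.full(int(has.sum()), sign))
    row = m + len(interior)

    # boundary rows
    if drive == "pressure":
        rows.append([row, row + 1])
        cols.append([m + network.inlet_node, m + network.outlet_node])
        vals.append([1.0, 1.0])
        b[row] = bc.P_in
        b[row + 1] = bc.P_out
    elif drive == "flow":
        at_out = elem[network.prox == network.inlet_node]
        at_in = elem[network.dist == network.inlet_node]
        rows.append(np.full(len(at_out) + len(at_in) + 1, row))
        cols.append(np.r_[at_out, at_in, m + network.outlet_node])
        vals.append(np.r_[np.ones(len(at_out)), -np.ones(len(at_in)), 0.0])
        rows.append([row + 1])
        cols.append([m + network.outlet_node])
        vals.append([1.0])
        b[row] = bc.Q_target
        b[row + 1] = bc.P_out
    else:
        raise ArgumentError(f"unknown drive mode {drive!r}")

    A = sp.csr_matrix(
        (
            np.concatenate([np.asarray(v, dtype=float) for v in vals]),
            (
                np.concatenate([np.asarray(r_, dtype=np.int64) for r_ in rows]),
                np.concatenate([np.asarray(c, dtype=np.int64) for c in cols]),
            ),
        ),
        shape=(n, n),
    )
    return LinearSystem(A=A, b=b, network=network, R_SL=R_SL, drive=drive)


@dataclass
class FlowSolution:
    """Solved per-element flows and per-node pressures (internal units)."""

    Q: np.ndarray
    P: np.ndarray
    network: FlowNetwork
    R_SL: float
    fluid: Fluid | None = None

    @property
    def Q_in(self) -> float:
        """Net flow leaving the inlet boundary node, mm^3/s."""
        net = self.network
        out = self.Q[net.prox == net.inlet_node].sum()
        back = self.Q[net.dist == net.inlet_node].sum()
        return float(out - back)

    @property
    def dP(self) -> float:
        return float(
            self.P[self.network.inlet_node] - self.P[self.network.outlet_node]
        )

    @property
    def R_eq(self) -> float:
        """Equivalent resistance of the whole network, dP/Q_in."""
        return self.dP / self.Q_in

    @property
    def Q_sl(self) -> np.ndarray:
        return self.Q[self.network.kind == SUPER_LOBULE]

    @property
    def dP_sl(self) -> np.ndarray:
        sl = self.network.kind == SUPER_LOBULE
        return (
            self.P[self.network.prox[sl]] - self.P[self.network.dist[sl]]
        )

    def kcl_residual(self) -> float:
        """Max interior-node flow imbalance relative to the inlet flow."""
        net = self.network
        resid = np.zeros(net.n_nodes)
        np.subtract.at(resid, net.prox, self.Q)
        np.add.at(resid, net.dist, self.Q)
        resid[[net.inlet_node, net.outlet_node]] = 0.0
        return float(np.abs(resid).max() / abs(self.Q_in))

    def ohm_residual(self, R_SL: float | None = None) -> float:
        net = self.network
        R = np.where(
            net.kind == SUPER_LOBULE,
            self.R_SL if R_SL is None else R_SL,
            net.R,
        )
        drop = self.P[net.prox] - self.P[net.dist] - R * self.Q
        scale = max(abs(self.dP), np.abs(self.P).max(), 1e-300)
        return float(np.abs(drop).max() / scale)

    def wall_shear(self) -> np.ndarray:
        """WSS per vessel segment (NaN for super-lobule elements)."""
        net = self.network
        tau = np.full(net.n_elements, np.nan)
        vm = net.kind == VESSEL
        tau[vm] = wall_shear_stress(self.Q[vm], net.r[vm], self.fluid)
        return tau

    def summary(self) -> dict:
        """Reporting-unit summary (mmHg, mL/min, dyn*s/mm^5)."""
        k = self.network.k
        return {
            "R_SL": self.R_SL,
            "R_SL_eq": self.R_SL / k if k else float("nan"),
            "n_SL": k,
            "Q_in_ml_min": self.Q_in / ML_MIN_TO_MM3_S,
            "dP_mmHg": self.dP / MMHG_TO_DYN_MM2,
            "R_eq": self.R_eq,
            "mean_dP_SL_mmHg": float(self.dP_sl.mean()) / MMHG_TO_DYN_MM2
            if k
            else float("nan"),
            "mean_Q_SL_ml_min": float(self.Q_sl.mean()) / ML_MIN_TO_MM3_S
            if k
            else float("nan"),
            "max_wss_dyn_mm2": float(np.nanmax(self.wall_shear()))
            if self.fluid is not None
            else float("nan"),
            "kcl_residual": self.kcl_residual(),
            "ohm_residual": self.ohm_residual(),
        }


def solve_flow(
    network: FlowNetwork,
    bc: BoundaryConditions,
    R_SL: float,
    drive: str = "pressure",
    fluid: Fluid | None = None,
) -> FlowSolution:
    """Assemble and LU-solve the 0D system; audit Ohm/KCL residuals."""
    system = assemble_system(network, bc, R_SL, drive=drive)
    try:
        lu = spla.splu(sp.csc_matrix(system.A))
        x = lu.solve(system.b)
    except RuntimeError as err:  # singular factorization
        raise SolverError(
            "linear system is singular; the network likely contains "
            "disconnected components"
        ) from err
    if not np.all(np.isfinite(x)):
        raise SolverError(
            "linear solve produced non-finite values; the network likely "
            "contains disconnected components"
        )
    m = network.n_elements
    sol = FlowSolution(
        Q=x[:m], P=x[m:], network=network, R_SL=R_SL, fluid=fluid
    )
    if sol.kcl_residual() > 1e-8 or sol.ohm_residual() > 1e-8:
        raise SolverError(
            f"solution failed the residual audit: KCL {sol.kcl_residual():.2e}, "
            f"Ohm {sol.ohm_residual():.2e}"
        )
    return sol


def find_sl_resistance(
    network: FlowNetwork,
    bc: BoundaryConditions,
    tol: float = 1e-8,
    bounds: tuple[float, float] = (0.0, 1.0),
    max_iter: int = 400,
    fluid: Fluid | None = None,
) -> float:
    """Bisect for the R_SL whose solved inlet flow matches the target.

    The prescribed pressures drive the network; the inlet flow decreases
    monotonically with R_SL. Feasibility requires the vessel-only network
    (R_SL = 0) to pass *more* than the target flow. The upper bound is
    doubled until it brackets the root, then standard halving runs until
    |Q_in - Q_target| <= tol in the reporting flow unit.
    """
    target = bc.Q_target / bc.flow_unit

    def flow_at(R):
        return solve_flow(network, bc, R, drive="pressure").Q_in / bc.flow_unit

    try:
        f0 = flow_at(bounds[0])
    except SolverError:
        # a zero-resistance path between the boundary nodes: infinite flow,
        # so any positive target is feasible
        f0 = np.inf
    if f0 < target - tol:
        raise InfeasibilityError(
            "no non-negative R_SL admits the prescribed flow: with R_SL = "
            f"{bounds[0]:g} the network passes only {f0:.6g} (target "
            f"{target:.6g}) at dP = {(bc.P_in - bc.P_out) / MMHG_TO_DYN_MM2:.4g} "
            f"mmHg; the minimum achievable operating point is "
            f"(dP*Q) = ({(bc.P_in - bc.P_out) / MMHG_TO_DYN_MM2:.4g} mmHg, "
            f"{f0:.6g})"
        )
    if abs(f0 - target) <= tol:
        return float(bounds[0])

    lo, hi = float(bounds[0]), max(float(bounds[1]), 1e-12)
    while flow_at(hi) > target:
        hi *= 2.0
        if hi > 1e300:
            raise SolverError("failed to bracket R_SL")

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = flow_at(mid)
        if abs(fm - target) <= tol:
            return mid
        if fm > target:
            lo = mid
        else:
            hi = mid
    raise SolverError(
        f"bisection did not converge to tol={tol} in {max_iter} iterations "
        f"(last interval [{lo:.6g}, {hi:.6g}])"
    )
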