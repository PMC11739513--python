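"""Space colonization growth of the inlet and outlet vascular trees.

The portal-vein (inlet) and hepatic-vein (outlet) trees are grown by an
attractor-based iterative algorithm. Each iteration:

1. every *active* attractor is associated with its nearest growable node,
   provided that node lies within the sphere-of-influence radius ``d_i``;
2. every node with associated attractors adds a child at step distance ``D``
   along the normalized mean of the unit vectors toward its attractors;
3. non-target attractors within the kill radius ``d_k`` of any node are
   deactivated.

*Target attractors* (the super-lobule centroids) cannot be deactivated by
proximity: when a node's only associated attractor is a target within
distance ``D``, a child is placed exactly at the target and the target is
marked reached. Growth terminates when every target is reached; branches not
on a target-to-root path are then pruned. Nodes snapped onto a target are
terminal caps and do not grow further, so after pruning the leaves of the
tree are exactly the super-lobule terminals.

Well-behaved parameter sets satisfy ``D < d_k < d_i``; smaller values give
more tortuous trees, larger values more direct ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ArgumentError, GeometryError, GrowthError, TopologyError

__all__ = [
    "GrowthParams",
    "AttractorSet",
    "VascularTree",
    "ConnectedNetworkTopology",
    "grow_tree",
    "prune_tree",
    "initialize_major_branches",
    "connect_trees",
]

_SNAP_EPS = 1e-9


@dataclass
class GrowthParams:
    """Space colonization parameters (all lengths in mm)."""

    D: float = 5.0
    d_k: float = 10.0
    d_i: float = 15.0
    max_iterations: int = 2000
    #: terminal edges shorter than this are re-rooted at an ancestor so no
    #: vanishing-volume vessel is created (None -> 0.25 * D)
    min_terminal_length: float | None = None

    @property
    def l_min(self) -> float:
        return 0.25 * self.D if self.min_terminal_length is None else self.min_terminal_length

    def __post_init__(self) -> None:
        if self.D <= 0 or self.d_k <= 0 or self.d_i <= 0:
            raise ArgumentError(
                f"growth distances must be positive: "
                f"D={self.D}, d_k={self.d_k}, d_i={self.d_i}"
            )
        if not (self.D < self.d_k < self.d_i):
            warnings.warn(
                f"growth parameters violate the recommended ordering "
                f"D < d_k < d_i (got D={self.D}, d_k={self.d_k}, "
                f"d_i={self.d_i}); growth may behave poorly",
                stacklevel=2,
            )


@dataclass
class AttractorSet:
    """Attractor cloud: guidance points plus mandatory targets.

    ``target_ids[i]`` is the super-lobule id for target attractors and -1
    for plain attractors. Targets stay active until explicitly reached.
    """

    positions: np.ndarray
    is_target: np.ndarray
    active: np.ndarray = field(default=None)  # type: ignore[assignment]
    target_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.is_target = np.asarray(self.is_target, dtype=bool)
        if self.active is None:
            self.active = np.ones(len(self.positions), dtype=bool)
        if self.target_ids is None:
            ids = np.full(len(self.positions), -1, dtype=np.int64)
            ids[self.is_target] = np.arange(int(self.is_target.sum()))
            self.target_ids = ids

    @classmethod
    def build(
        cls, cloud_points: np.ndarray, target_positions: np.ndarray
    ) -> "AttractorSet":
        """Plain attractors from `cloud_points`, targets appended in order
        (target k gets super-lobule id k)."""
        cloud_points = np.asarray(cloud_points, dtype=float).reshape(-1, 3)
        target_positions = np.asarray(target_positions, dtype=float).reshape(-1, 3)
        positions = np.vstack([cloud_points, target_positions])
        is_target = np.zeros(len(positions), dtype=bool)
        is_target[len(cloud_points):] = True
        return cls(positions=positions, is_target=is_target)


@dataclass
class VascularTree:
    """Rooted tree grown by space colonization.

    Parent indices always point to earlier nodes, so node order is a
    topological order from the roots outward.
    """

    positions: np.ndarray
    parents: np.ndarray
    label: str
    terminal_map: dict[int, int] = field(default_factory=dict)
    growable: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_fixed: int = 0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.parents = np.asarray(self.parents, dtype=np.int64)
        if self.growable is None:
            self.growable = np.ones(len(self.positions), dtype=bool)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def roots(self) -> np.ndarray:
        return np.flatnonzero(self.parents < 0)

    @property
    def edges(self) -> np.ndarray:
        """(parent, child) pairs, one per non-root node."""
        child = np.flatnonzero(self.parents >= 0)
        return np.column_stack([self.parents[child], child])

    def path_length(self) -> float:
        """Total tree length, mm — Σ edge lengths (tortuosity proxy)."""
        e = self.edges
        if len(e) == 0:
            return 0.0
        return float(
            np.linalg.norm(
                self.positions[e[:, 1]] - self.positions[e[:, 0]], axis=1
            ).sum()
        )


@dataclass
class ConnectedNetworkTopology:
    """Inlet tree + outlet tree joined by one super-lobule element per SL."""

    inlet: VascularTree
    outlet: VascularTree
    n_sl: int


def grow_tree(
    attractors: AttractorSet,
    params: GrowthParams,
    *,
    roots: np.ndarray | None = None,
    tree: VascularTree | None = None,
    label: str = "inlet",
    seed: int = 0,
    cap_terminals: bool = True,
    trace: list | None = None,
) -> VascularTree:
    """Grow (or continue growing) a tree until all targets are reached.

    Parameters
    ----------
    roots
        Root node positions, used when starting a fresh tree.
    tree
        An existing tree to continue from (two-stage growth). Exactly one of
        `roots` / `tree` must be given.
    cap_terminals
        If True, nodes snapped onto targets cannot grow children (final
        stage). The primary-branch stage passes False so the primary tips
        remain growable.
    trace
        Optional list; per iteration a dict with the active plain-attractor
        count, unreached-target count and node count is appended.
    """
    if (roots is None) == (tree is None):
        raise ArgumentError("provide exactly one of roots= or tree=")
    rng = np.random.default_rng(seed)
    attr = attractors

    if tree is not None:
        pos = [p for p in tree.positions]
        parents = list(tree.parents)
        growable = list(tree.growable)
        terminal_map = dict(tree.terminal_map)
        n_fixed = tree.n_fixed
    else:
        root_arr = np.atleast_2d(np.asarray(roots, dtype=float))
        if len(root_arr) < 1:
            raise ArgumentError("at least one root position is required")
        pos = [p for p in root_arr]
        parents = [-1] * len(root_arr)
        growable = [True] * len(root_arr)
        terminal_map = {}
        n_fixed = 0

    has_targets = bool(attr.is_target.any())

    for _ in range(params.max_iterations):
        unreached = attr.active & attr.is_target
        # targets all reached ends growth; with no targets at all, growth
        # runs until the attractor cloud is consumed
        if (not unreached.any()) if has_targets else (not attr.active.any()):
            break
        if trace is not None:
            trace.append(
                {
                    "active_plain": int((attr.active & ~attr.is_target).sum()),
                    "unreached_targets": int(unreached.sum()),
                    "n_nodes": len(pos),
                }
            )

        P = np.asarray(pos)
        grow_idx = np.flatnonzero(growable)
        kdt_grow = cKDTree(P[grow_idx])
        act = np.flatnonzero(attr.active)
        dist, local_nn = kdt_grow.query(attr.positions[act])
        within = dist <= params.d_i
        assoc_attr = act[within]
        assoc_node = grow_idx[local_nn[within]]
        assoc_dist = dist[within]

        added = 0
        reached_this_iter = 0
        order = np.argsort(assoc_node, kind="stable")
        assoc_node = assoc_node[order]
        assoc_attr = assoc_attr[order]
        assoc_dist = assoc_dist[order]
        if len(assoc_node):
            starts = np.flatnonzero(
                np.r_[True, assoc_node[1:] != assoc_node[:-1]]
            )
            bounds = np.r_[starts, len(assoc_node)]
        else:
            bounds = np.zeros(1, dtype=np.int64)
        for s, e in zip(bounds[:-1], bounds[1:]):
            node = int(assoc_node[s])
            a_idx = assoc_attr[s:e]
            a_dist = assoc_dist[s:e]
            node_pos = P[node]

            if (
                len(a_idx) == 1
                and attr.is_target[a_idx[0]]
                and a_dist[0] <= params.D
            ):
                # sole attractor is a target within a step: snap onto it
                a = int(a_idx[0])
                sl = int(attr.target_ids[a])
                if a_dist[0] <= _SNAP_EPS:
                    terminal_map[sl] = node
                    if cap_terminals:
                        growable[node] = False
                else:
                    # keep the terminal edge from degenerating: attach to an
                    # ancestor if the triggering node is too close
                    attach = node
                    target_pos = attr.positions[a]
                    while (
                        np.linalg.norm(pos[attach] - target_pos) < params.l_min
                        and parents[attach] >= 0
                    ):
                        attach = int(parents[attach])
                    pos.append(target_pos.copy())
                    parents.append(attach)
                    growable.append(not cap_terminals)
                    terminal_map[sl] = len(pos) - 1
                    added += 1
                attr.active[a] = False
                reached_this_iter += 1
                continue

            dirs = attr.positions[a_idx] - node_pos
            lens = np.linalg.norm(dirs, axis=1)
            ok = lens > _SNAP_EPS
            if not ok.any():
                continue

            def tie_break():
                # toward the smallest-index attractor, tiny jitter to break
                # exact symmetry (opposing or oscillating attractor pairs)
                j = int(np.argmin(a_idx))
                return dirs[j] / lens[j] + rng.normal(
                    scale=1e-6 * params.D, size=3
                )

            mean_dir = (dirs[ok] / lens[ok, None]).mean(axis=0)
            nm = np.linalg.norm(mean_dir)
            if nm < 1e-8:
                mean_dir = tie_break()
                nm = np.linalg.norm(mean_dir)
                if nm < 1e-12:
                    continue
            new_pos = node_pos + params.D * mean_dir / nm
            kdt_nodes = cKDTree(P)
            d_exist, _ = kdt_nodes.query(new_pos)
            if d_exist <= 1e-6 * params.D:
                mean_dir = tie_break()
                nm = np.linalg.norm(mean_dir)
                new_pos = node_pos + params.D * mean_dir / nm
                d_exist, _ = kdt_nodes.query(new_pos)
                if d_exist <= 1e-6 * params.D:
                    continue
            pos.append(new_pos)
            parents.append(node)
            growable.append(True)
            added += 1

        # deactivate plain attractors approached by any node (old or new)
        P = np.asarray(pos)
        kdt_all = cKDTree(P)
        plain = np.flatnonzero(attr.active & ~attr.is_target)
        if len(plain):
            d_plain, _ = kdt_all.query(attr.positions[plain])
            attr.active[plain[d_plain <= params.d_k]] = False

        if added == 0 and reached_this_iter == 0:
            if not has_targets:
                break  # remaining plain attractors are simply out of reach
            unreached_ids = sorted(
                int(i) for i in attr.target_ids[attr.active & attr.is_target]
            )
            raise GrowthError(
                f"growth stagnated with {len(unreached_ids)} unreached "
                f"targets: {unreached_ids}",
                unreached=unreached_ids,
            )
    else:
        unreached_ids = sorted(
            int(i) for i in attr.target_ids[attr.active & attr.is_target]
        )
        if unreached_ids:
            raise GrowthError(
                f"max_iterations={params.max_iterations} exceeded with "
                f"{len(unreached_ids)} unreached targets: {unreached_ids}",
                unreached=unreached_ids,
            )

    return VascularTree(
        positions=np.asarray(pos),
        parents=np.asarray(parents, dtype=np.int64),
        label=label,
        terminal_map=terminal_map,
        growable=np.asarray(growable, dtype=bool),
        n_fixed=n_fixed if tree is not None else len(pos),
    )


def prune_tree(tree: VascularTree) -> VascularTree:
    """Remove every branch not on a terminal-to-root path.

    Traverses the tree in reverse from each super-lobule terminal to its
    root; nodes never traversed are dropped. Terminal positions and the
    terminal map are preserved (indices remapped).
    """
    if not tree.terminal_map:
        raise GrowthError("cannot prune a tree with no reached targets")
    keep = np.zeros(tree.n_nodes, dtype=bool)
    for node in tree.terminal_map.values():
        i = node
        while i >= 0 and not keep[i]:
            keep[i] = True
            i = int(tree.parents[i])
    keep[tree.roots] = True
    new_index = np.cumsum(keep) - 1
    kept = np.flatnonzero(keep)
    parents = tree.parents[kept]
    remapped = np.where(parents >= 0, new_index[np.clip(parents, 0, None)], -1)
    return VascularTree(
        positions=tree.positions[kept],
        parents=remapped.astype(np.int64),
        label=tree.label,
        terminal_map={
            sl: int(new_index[n]) for sl, n in tree.terminal_map.items()
        },
        growable=tree.growable[kept],
        n_fixed=int(keep[: tree.n_fixed].sum()),
    )


def initialize_major_branches(
    model,
    label: str,
    root: np.ndarray,
    primary_targets: np.ndarray,
    params: GrowthParams,
    seed: int = 0,
) -> VascularTree:
    """First-stage colonization toward the primary vessel targets.

    Anatomically these are the left/right portal veins on the inlet tree and
    the left/middle/right hepatic veins on the outlet tree. Only the primary
    targets act as attractors; the resulting nodes are fixed (never pruned
    into different topology) during the main growth stage.
    """
    primary_targets = np.atleast_2d(np.asarray(primary_targets, dtype=float))
    inside = model.contains(primary_targets)
    if not inside.all():
        bad = np.flatnonzero(~inside).tolist()
        raise GeometryError(
            f"primary target(s) {bad} for the {label} tree lie outside the "
            "organ volume"
        )
    attr = AttractorSet.build(
        np.zeros((0, 3)), target_positions=primary_targets
    )
    tree = grow_tree(
        attr,
        params,
        roots=np.atleast_2d(np.asarray(root, dtype=float)),
        label=label,
        seed=seed,
        cap_terminals=False,
    )
    # primary terminal map belongs to this stage only; the main stage maps
    # super-lobule ids onto fresh terminals
    tree.terminal_map = {}
    tree.n_fixed = tree.n_nodes
    return tree


def connect_trees(
    inlet: VascularTree,
    outlet: VascularTree,
    n_sl: int,
) -> ConnectedNetworkTopology:
    """Join the two trees with one super-lobule element per centroid."""
    expected = set(range(n_sl))
    for t in (inlet, outlet):
        missing = sorted(expected - set(t.terminal_map))
        if missing:
            raise TopologyError(
                f"{t.label} tree is missing terminals for super lobules "
                f"{missing}"
            )
        extra = sorted(set(t.terminal_map) - expected)
        if extra:
            raise TopologyError(
                f"{t.label} tree has unexpected terminal ids {extra}"
            )
    return ConnectedNetworkTopology(inlet=inlet, outlet=outlet, n_sl=n_sl)
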