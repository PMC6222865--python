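"""Synchronous-stability threshold and the iterative stabilization loop.

A connected component of a coupled weighted network is synchronously stable
when every edge weight exceeds a lower limit ε derived from ring-lattice
synchronization theory.  For a ring of 2K-adjacent nodes coupled with
strength a = s·λ2 (0 < s < 1, λ2 the algebraic connectivity) the limit is

    ε = (a / n) · (n / 2K)^3 · (1 + (65/4) · K/n)

In the fully connected limit n = 2K with s = 0.28 this collapses to
ε = 2.555·λ2/n.  For a component that is not a clique the same form is
applied with K replaced by m = (size of a greedy maximum clique)/2, which
only raises the limit and therefore remains a valid (conservative)
stability condition.

Stabilization repeatedly processes every unstable component: cliques drop
all edges at or below ε in one batch; other components first shed hanging
(degree-1) nodes, and only once none remain drop sub-threshold edges.  The
loop ends when every multi-node component satisfies w > ε.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .network import (
    GeneNetwork,
    NetworkComponent,
    NetworkValidationError,
    algebraic_connectivity,
)

__all__ = [
    "DEFAULT_S",
    "DEFAULT_S_GRID",
    "ring_lattice_threshold",
    "edge_weight_threshold",
    "max_clique_greedy",
    "find_hanging_nodes",
    "stabilize",
    "loss_proportion",
    "select_coupling_factor",
    "StabilizationTrace",
    "CouplingSelection",
]

log = logging.getLogger(__name__)

#: Default coupling-factor multiplier, the depression point of the mean
#: information-loss curve where its gradient first approaches zero.
DEFAULT_S = 0.28

#: Default sweep grid for the coupling-factor selection, s = 0.01 ... 0.99.
DEFAULT_S_GRID = tuple(round(0.01 * i, 2) for i in range(1, 100))

# Coefficient of the half-neighbour correction term in the ring-lattice
# stability bound; at the fully connected limit 1 + (65/4)·(K/n) = 1 + 65/8.
_RING_CORRECTION = 65.0 / 4.0


def ring_lattice_threshold(lambda2: float, n: int, m: float, s: float = DEFAULT_S) -> float:
    """Edge-weight lower limit ε for a component of *n* nodes.

    *m* is half the clique size used in place of the ring half-neighbour
    count K (m = n/2 recovers the fully connected form).  *m* may be a
    non-integral half for odd cliques; it only enters analytically.
    """
    if n < 2:
        raise NetworkValidationError("threshold undefined for singleton components")
    if not (0.0 < s < 1.0):
        raise ValueError(f"coupling factor s must lie in (0, 1), got {s}")
    if m <= 0:
        raise ValueError(f"half clique size m must be positive, got {m}")
    a = s * lambda2
    return (a / n) * (n / (2.0 * m)) ** 3 * (1.0 + _RING_CORRECTION * m / n)


def max_clique_greedy(component: NetworkComponent) -> set[str]:
    """Greedy maximum clique with one restart per seed node.

    Nodes are ordered by descending weighted degree (ties by gene id).
    Every node seeds one greedy growth — scan the remaining nodes in the
    same order and keep each one adjacent to the whole clique so far — and
    the largest clique over all seeds wins (first seed on ties).  A single
    pass from the top of the ordering alone is easily trapped at size 2 in
    modular graphs, badly inflating the stability limit, so the restarts
    are part of the heuristic.  Fully deterministic; the result is a
    maximal clique, hence size ≥ 2 whenever the component has an edge.
    """
    g = component.subgraph
    order = sorted(
        g.nodes, key=lambda v: (-sum(d["weight"] for _, _, d in g.edges(v, data=True)), v)
    )
    best: list[str] = []
    for seed in order:
        clique = [seed]
        for v in order:
            if v != seed and all(g.has_edge(v, u) for u in clique):
                clique.append(v)
        if len(clique) > len(best):
            best = clique
    return set(best)


def edge_weight_threshold(
    component: NetworkComponent,
    s: float = DEFAULT_S,
    *,
    lambda2_mode: str = "weighted",
) -> float:
    """Stability limit ε of a connected component.

    Cliques use the fully connected form (m = n/2, i.e. ε = s·9.125·λ2/n);
    other components use half the greedy maximum clique size for m.
    """
    if component.n < 2:
        raise NetworkValidationError("singleton components are trivially stable")
    lam2 = algebraic_connectivity(component, mode=lambda2_mode)
    if component.is_clique():
        m = component.n / 2.0
    else:
        m = len(max_clique_greedy(component)) / 2.0
    return ring_lattice_threshold(lam2, component.n, m, s)


def find_hanging_nodes(component: NetworkComponent) -> set[str]:
    """Nodes of degree exactly 1."""
    g = component.subgraph
    return {v for v in g.nodes if g.degree(v) == 1}


@dataclass(frozen=True)
class TraceStep:
    """One stabilization action on one component."""

    iteration: int
    component_root: str  # smallest gene id of the component acted on
    action: str  # "delete-edges" | "delete-hanging-nodes"
    items: tuple  # removed edges (a, b, w) or removed node ids
    epsilon: float


@dataclass
class StabilizationTrace:
    """Ordered record of the edits the stabilization loop performed."""

    steps: list[TraceStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def removed_edge_weight(self) -> float:
        tot = 0.0
        for st in self.steps:
            if st.action == "delete-edges":
                tot += sum(w for _, _, w in st.items)
        return tot

    def replay(self, network: GeneNetwork) -> GeneNetwork:
        """Re-apply the recorded edits to *network* (audit helper)."""
        g = network.graph.copy()
        for st in self.steps:
            if st.action == "delete-edges":
                g.remove_edges_from([(a, b) for a, b, _ in st.items])
            else:
                g.remove_nodes_from(st.items)
        return GeneNetwork.from_nx(g)


def _component_stable(
    comp: NetworkComponent, s: float, lambda2_mode: str
) -> tuple[bool, float]:
    eps = edge_weight_threshold(comp, s, lambda2_mode=lambda2_mode)
    return comp.min_edge_weight() > eps, eps


def stabilize(
    network: GeneNetwork,
    s: float = DEFAULT_S,
    *,
    lambda2_mode: str = "weighted",
    drop_singletons: bool = False,
) -> tuple[GeneNetwork, StabilizationTrace]:
    """Iterate until every multi-node component satisfies w > ε.

    Per unstable component and iteration: a clique batch-deletes its edges
    with w ≤ ε; otherwise hanging nodes are deleted if any exist, else the
    sub-threshold edges are batch-deleted.  ε is recomputed for every
    component at every iteration because λ2, n and the clique size change
    as the graph shrinks.  Hanging-node deletion removes the gene from the
    network; genes isolated by edge deletion remain as singleton components
    unless ``drop_singletons`` is set.
    """
    g = network.graph.copy()
    trace = StabilizationTrace()
    iteration = 0
    while True:
        iteration += 1
        changed = False
        for comp in GeneNetwork.from_nx(g).connected_components():
            if comp.n < 2:
                continue
            stable, eps = _component_stable(comp, s, lambda2_mode)
            if stable:
                continue
            root = min(comp.nodes)
            if comp.is_clique():
                doomed = [
                    (a, b, float(d["weight"]))
                    for a, b, d in comp.subgraph.edges(data=True)
                    if d["weight"] <= eps
                ]
                g.remove_edges_from([(a, b) for a, b, _ in doomed])
                trace.steps.append(
                    TraceStep(iteration, root, "delete-edges", tuple(doomed), eps)
                )
            else:
                hanging = sorted(find_hanging_nodes(comp))
                if hanging:
                    g.remove_nodes_from(hanging)
                    trace.steps.append(
                        TraceStep(
                            iteration, root, "delete-hanging-nodes", tuple(hanging), eps
                        )
                    )
                else:
                    doomed = [
                        (a, b, float(d["weight"]))
                        for a, b, d in comp.subgraph.edges(data=True)
                        if d["weight"] <= eps
                    ]
                    g.remove_edges_from([(a, b) for a, b, _ in doomed])
                    trace.steps.append(
                        TraceStep(iteration, root, "delete-edges", tuple(doomed), eps)
                    )
            changed = True
        if not changed:
            break
    if drop_singletons:
        g.remove_nodes_from([v for v in list(g.nodes) if g.degree(v) == 0])
    result = GeneNetwork.from_nx(g)
    if trace.steps:
        log.info(
            "stabilize: %d iterations, %d edits, %d/%d nodes and %d/%d edges kept",
            iteration - 1,
            len(trace.steps),
            result.n_nodes,
            network.n_nodes,
            result.n_edges,
            network.n_edges,
        )
    return result, trace


def loss_proportion(
    network: GeneNetwork,
    s: float = DEFAULT_S,
    *,
    lambda2_mode: str = "weighted",
    measure: str = "weight",
) -> float:
    """Fraction of the network's information removed by stabilization at *s*.

    Information is measured as total edge weight by default (a
    probability-weighted network's natural mass); ``measure="count"`` uses
    the edge count instead.
    """
    if network.n_edges == 0:
        raise NetworkValidationError("loss proportion undefined for an edgeless network")
    stable, _ = stabilize(network, s, lambda2_mode=lambda2_mode)
    if measure == "weight":
        before = network.total_weight()
        after = stable.total_weight()
    elif measure == "count":
        before = float(network.n_edges)
        after = float(stable.n_edges)
    else:
        raise ValueError(f"unknown loss measure {measure!r}")
    return (before - after) / before


@dataclass(frozen=True)
class CouplingSelection:
    """Outcome of the coupling-factor sweep."""

    s: float
    gradient: float
    converged: bool  # False when no grid point met the gradient tolerance
    s_grid: tuple[float, ...]
    mean_curve: tuple[float, ...]


def _select_from_curve(
    s_grid: list[float], curve: list[float], gradient_tol: float
) -> tuple[int, float, bool]:
    """Pick the first interior grid index whose central-difference gradient
    is within tolerance; fall back to the minimum-|gradient| index."""
    if len(s_grid) < 3:
        raise NetworkValidationError("s grid needs at least 3 points for a gradient")
    grads: list[tuple[int, float]] = []
    for i in range(1, len(s_grid) - 1):
        grad = (curve[i + 1] - curve[i - 1]) / (s_grid[i + 1] - s_grid[i - 1])
        grads.append((i, grad))
        if abs(grad) <= gradient_tol:
            return i, grad, True
    i, grad = min(grads, key=lambda t: abs(t[1]))
    return i, grad, False


def select_coupling_factor(
    networks: list[GeneNetwork],
    s_grid: list[float] | tuple[float, ...] = DEFAULT_S_GRID,
    gradient_tol: float = 0.05,
    *,
    lambda2_mode: str = "weighted",
) -> CouplingSelection:
    """Depression-point selection of the coupling factor s.

    Computes the mean information-loss curve over *networks* across the
    (strictly increasing, within (0,1)) *s_grid*, then returns the smallest
    grid point where the central finite-difference gradient first comes
    within ``gradient_tol`` of zero.  If none qualifies the minimum-
    |gradient| point is returned with ``converged=False``.
    """
    s_grid = list(s_grid)
    if len(s_grid) < 3:
        raise NetworkValidationError("s grid needs at least 3 points for a gradient")
    if any(not (0.0 < s < 1.0) for s in s_grid) or any(
        b <= a for a, b in zip(s_grid, s_grid[1:])
    ):
        raise ValueError("s grid must be strictly increasing within (0, 1)")
    if not networks:
        raise ValueError("at least one network is required")
    curve = []
    for s in s_grid:
        losses = [loss_proportion(net, s, lambda2_mode=lambda2_mode) for net in networks]
        curve.append(sum(losses) / len(losses))
    idx, grad, ok = _select_from_curve(s_grid, curve, gradient_tol)
    if not ok:
        log.warning(
            "no grid point reached |gradient| <= %g; returning flattest point s=%g",
            gradient_tol,
            s_grid[idx],
        )
    return CouplingSelection(s_grid[idx], grad, ok, tuple(s_grid), tuple(curve))
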