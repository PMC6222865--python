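"""Node destructiveness scores on the stabilized network.

The importance of a gene follows the "destructiveness equals importance"
hypothesis: score a node by how much its deletion damages the synchronously
stabilized network.  Damage is read off a single scalar network metric

    M(G) = (Σ_i Σ_{j≠i} w_ij) / m_G

— the ordered-pair double sum of edge weights (each undirected edge counted
twice) divided by the number of connected components m_G — so that both
weight loss and fragmentation register.  With G_s the stabilized baseline,

    D(G, v) = M(G_s) − M((G_s − v)_s)      (delete v, re-stabilize)
    H(G, v) = D(G, v) / M(G_s)

Isolated nodes of the baseline are assigned H = 0: a node that destroys
nothing is not important, even though removing a singleton component would
make D negative through the m_G denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .network import GeneNetwork, NetworkValidationError
from .stability import DEFAULT_S, stabilize

__all__ = [
    "network_metric",
    "network_difference",
    "node_importance",
    "importance_table",
    "ImportanceTable",
]

log = logging.getLogger(__name__)


def network_metric(network: GeneNetwork) -> float:
    """M(G): total ordered-pair edge weight over the number of components."""
    if network.n_nodes == 0:
        raise NetworkValidationError("network metric undefined on an empty network")
    return 2.0 * network.total_weight() / network.n_components


def _delete_and_restabilize(
    stable_network: GeneNetwork, v: str, s: float, lambda2_mode: str
) -> GeneNetwork:
    g = stable_network.graph.copy()
    g.remove_node(v)
    if g.number_of_nodes() == 0:
        return GeneNetwork.from_nx(g)
    restabilized, _ = stabilize(
        GeneNetwork.from_nx(g), s, lambda2_mode=lambda2_mode
    )
    return restabilized


def network_difference(
    stable_network: GeneNetwork,
    v: str,
    s: float = DEFAULT_S,
    *,
    lambda2_mode: str = "weighted",
) -> float:
    """D(G, v) = M(G_s) − M((G_s − v)_s).

    *stable_network* must already be stabilized; v's deletion is followed by
    re-stabilization before the metric is compared.  D can be negative in
    degenerate cases (removing a singleton component shrinks m_G), which the
    importance layer maps to zero.
    """
    if not stable_network.has_node(v):
        raise KeyError(f"gene {v!r} is not a node of the network")
    m_before = network_metric(stable_network)
    after = _delete_and_restabilize(stable_network, v, s, lambda2_mode)
    m_after = 0.0 if after.n_nodes == 0 else network_metric(after)
    return m_before - m_after


def node_importance(
    stable_network: GeneNetwork,
    v: str,
    s: float = DEFAULT_S,
    *,
    lambda2_mode: str = "weighted",
) -> float:
    """H(G, v) = D(G, v) / M(G_s); zero for isolated baseline nodes."""
    m_base = network_metric(stable_network)
    if m_base <= 0.0:
        raise NetworkValidationError(
            "baseline M is zero: the stabilized network has no edges left"
        )
    if stable_network.graph.degree(v) == 0:
        return 0.0
    return network_difference(stable_network, v, s, lambda2_mode=lambda2_mode) / m_base


@dataclass
class ImportanceTable:
    """Per-gene destructiveness scores against one stabilized baseline."""

    h: dict[str, float]
    d: dict[str, float]
    baseline_m: float
    stabilized: GeneNetwork = field(repr=False)
    s: float = DEFAULT_S

    def score(self, gene: str) -> float:
        """H for *gene*; genes missing from the table score 0."""
        return self.h.get(gene, 0.0)

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.h)
        return pd.DataFrame(
            {
                "gene": genes,
                "H": [self.h[g] for g in genes],
                "D": [self.d[g] for g in genes],
                "baseline_M": self.baseline_m,
            }
        )


def importance_table(
    network: GeneNetwork,
    genes: list[str] | None = None,
    s: float = DEFAULT_S,
    *,
    lambda2_mode: str = "weighted",
) -> ImportanceTable:
    """Score every gene in *genes* (default: all network nodes).

    The baseline is stabilized once and shared by every evaluation; scoring
    one gene never mutates it.  Genes absent from the (possibly pruned)
    stabilized baseline — including genes never present in the input network
    — receive H = 0 with a logged warning, so downstream fusion scoring is
    total over its vocabulary.
    """
    if genes is None:
        genes = sorted(network.nodes)
    stable, _ = stabilize(network, s, lambda2_mode=lambda2_mode)
    if stable.n_nodes and network_metric(stable) <= 0.0 and genes:
        raise NetworkValidationError(
            "stabilized baseline retained no edges; importance is undefined"
        )
    baseline_m = network_metric(stable) if stable.n_nodes else 0.0
    h: dict[str, float] = {}
    d: dict[str, float] = {}
    missing = 0
    for gene in genes:
        if not stable.has_node(gene) or stable.graph.degree(gene) == 0:
            if not network.has_node(gene):
                missing += 1
            h[gene] = 0.0
            d[gene] = 0.0
            continue
        dv = network_difference(stable, gene, s, lambda2_mode=lambda2_mode)
        d[gene] = dv
        h[gene] = dv / baseline_m
    if missing:
        log.warning(
            "%d evaluated gene(s) absent from the network; scored H = 0", missing
        )
    return ImportanceTable(h=h, d=d, baseline_m=baseline_m, stabilized=stable, s=s)
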