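"""Weighted gene-network data model and I/O.

A gene network is an undirected graph whose nodes are opaque gene
identifiers and whose edge weights are probability-like interaction scores
in [0, 1].  The :class:`GeneNetwork` wrapper enforces the invariants every
downstream stage relies on (no self-loops, single storage per unordered
pair, weights in range) and provides connected-component decomposition and
algebraic connectivity, the spectral quantity that drives the
synchronous-stability threshold.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "GeneNetwork",
    "NetworkComponent",
    "NetworkValidationError",
    "load_network",
    "read_gene_list",
    "algebraic_connectivity",
]


class NetworkValidationError(ValueError):
    """An input violates a gene-network invariant."""


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class GeneNetwork:
    """Undirected weighted gene network.

    Parameters
    ----------
    edges
        Iterable of ``(gene_a, gene_b, weight)`` triples, or a mapping from
        unordered pairs to weights.
    nodes
        Extra (possibly isolated) gene identifiers to include.
    validate
        When true (default), reject self-loops, duplicate unordered pairs
        and weights outside ``[0, 1]``.  Toy constructions used for
        arithmetic checks may switch validation off.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, float]] | Mapping[tuple[str, str], float] = (),
        nodes: Iterable[str] = (),
        *,
        validate: bool = True,
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        if isinstance(edges, Mapping):
            edges = [(a, b, w) for (a, b), w in edges.items()]
        for a, b, w in edges:
            a, b = str(a), str(b)
            w = float(w)
            if validate:
                if a == b:
                    raise NetworkValidationError(f"self-loop on gene {a!r}")
                if g.has_edge(a, b):
                    raise NetworkValidationError(
                        f"duplicate unordered pair ({a!r}, {b!r})"
                    )
                if not (0.0 <= w <= 1.0) or not np.isfinite(w):
                    raise NetworkValidationError(
                        f"weight {w!r} for ({a!r}, {b!r}) outside [0, 1]"
                    )
            g.add_edge(a, b, weight=w)
        self._g = g

    # -- construction -----------------------------------------------------

    @classmethod
    def from_nx(cls, g: nx.Graph, *, validate: bool = False) -> "GeneNetwork":
        net = cls(
            ((a, b, d.get("weight", 1.0)) for a, b, d in g.edges(data=True)),
            nodes=g.nodes,
            validate=validate,
        )
        return net

    def copy(self) -> "GeneNetwork":
        return GeneNetwork.from_nx(self._g.copy())

    # -- basic queries ----------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """Underlying :class:`networkx.Graph` (treat as read-only)."""
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, v: str) -> bool:
        return self._g.has_node(v)

    def weight(self, a: str, b: str, default: float = 0.0) -> float:
        """Edge weight between *a* and *b*; *default* when no edge joins them."""
        if self._g.has_edge(a, b):
            return float(self._g[a][b]["weight"])
        return default

    def edge_items(self) -> list[tuple[str, str, float]]:
        """Edges as canonical ``(a, b, weight)`` triples, a ≤ b, sorted."""
        out = [(*_canonical(a, b), float(d["weight"])) for a, b, d in self._g.edges(data=True)]
        out.sort()
        return out

    def total_weight(self) -> float:
        """Sum of edge weights, each undirected edge counted once."""
        return float(sum(d["weight"] for _, _, d in self._g.edges(data=True)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edge_items() == other.edge_items()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneNetwork({self.n_nodes} nodes, {self.n_edges} edges)"

    # -- components -------------------------------------------------------

    def connected_components(self) -> list["NetworkComponent"]:
        """Components in deterministic order (by smallest member gene id)."""
        comps = [
            NetworkComponent(self._g.subgraph(c).copy())
            for c in nx.connected_components(self._g)
        ]
        comps.sort(key=lambda c: min(c.nodes))
        return comps

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self._g)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path | io.TextIOBase) -> None:
        """Write a sorted three-column edge-list TSV (deterministic)."""
        lines = ["gene_a\tgene_b\tweight\n"]
        lines += [f"{a}\t{b}\t{w:.10g}\n" for a, b, w in self.edge_items()]
        isolated = sorted(n for n in self._g.nodes if self._g.degree(n) == 0)
        # isolated genes are recorded as comment lines so round-trips keep them
        lines += [f"# node\t{n}\n" for n in isolated]
        if isinstance(path, io.TextIOBase):
            path.writelines(lines)
        else:
            Path(path).write_text("".join(lines))


@dataclass(frozen=True)
class NetworkComponent:
    """A connected component (induced subgraph) of a gene network."""

    subgraph: nx.Graph = field(repr=False)

    def __post_init__(self) -> None:
        if self.subgraph.number_of_nodes() == 0:
            raise NetworkValidationError("empty component")

    @property
    def nodes(self) -> set[str]:
        return set(self.subgraph.nodes)

    @property
    def n(self) -> int:
        return self.subgraph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.subgraph.number_of_edges()

    def min_edge_weight(self) -> float:
        if self.n_edges == 0:
            raise NetworkValidationError("component has no edges")
        return min(float(d["weight"]) for _, _, d in self.subgraph.edges(data=True))

    def is_clique(self) -> bool:
        """True when every pair of member nodes is adjacent ("fully connected")."""
        n = self.n
        return self.n_edges == n * (n - 1) // 2


def algebraic_connectivity(
    component: NetworkComponent, mode: str = "weighted"
) -> float:
    """Second-smallest Laplacian eigenvalue λ2 of a connected component.

    ``mode="weighted"`` builds the Laplacian from edge weights, the default
    because the stability condition couples nodes through interaction
    strengths; ``mode="unweighted"`` uses the 0/1 adjacency.
    """
    if component.n < 2:
        raise NetworkValidationError(
            "algebraic connectivity requires at least 2 nodes; "
            "singleton components are trivially stable"
        )
    if mode not in ("weighted", "unweighted"):
        raise ValueError(f"unknown lambda2 mode {mode!r}")
    order = sorted(component.nodes)
    w = "weight" if mode == "weighted" else None
    lap = nx.laplacian_matrix(component.subgraph, nodelist=order, weight=w).toarray()
    eig = np.linalg.eigvalsh(lap.astype(float))
    return float(eig[1])


def _split_row(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def load_network(source: str | Path | io.TextIOBase) -> GeneNetwork:
    """Load a gene network from an edge-list table.

    Tab-separated columns ``gene_a  gene_b  weight``; a header row is
    auto-detected by a non-numeric third column; lines starting with ``#``
    are comments, except ``# node <id>`` lines, which declare isolated genes.
    """
    if isinstance(source, io.TextIOBase):
        lines = source.readlines()
        name = "<stream>"
    else:
        p = Path(source)
        if not p.exists():
            raise FileNotFoundError(f"network file not found: {p}")
        lines = p.read_text().splitlines()
        name = str(p)

    edges: list[tuple[str, str, float]] = []
    nodes: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = _split_row(line.lstrip("# ").strip())
            if len(parts) == 2 and parts[0] == "node":
                nodes.append(parts[1])
            continue
        parts = _split_row(line)
        if len(parts) != 3:
            raise NetworkValidationError(
                f"{name}:{lineno}: expected 3 columns, got {len(parts)}"
            )
        a, b, w_str = parts
        try:
            w = float(w_str)
        except ValueError:
            if lineno == 1 or (not edges and not nodes):
                continue  # header row
            raise NetworkValidationError(
                f"{name}:{lineno}: non-numeric weight {w_str!r}"
            ) from None
        try:
            edges.append((a, b, w))
            GeneNetwork([(a, b, w)])  # per-row validation for a precise lineno
        except NetworkValidationError as err:
            raise NetworkValidationError(f"{name}:{lineno}: {err}") from None
    try:
        return GeneNetwork(edges, nodes=nodes)
    except NetworkValidationError as err:
        raise NetworkValidationError(f"{name}: {err}") from None


def read_gene_list(path: str | Path) -> list[str]:
    """One gene identifier per line; blank and ``#`` lines ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
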