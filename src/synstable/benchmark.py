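"""Synthetic benchmark: network generator, dataset sampler and evaluation.

The generator emulates the structural premise the prioritization method is
built on — susceptible (disease-associated) genes are network-important
hubs — without reproducing any real resource.  Planted susceptible genes
form a chain of small densely-wired modules (triangles bridged in
sequence) with strong interaction weights; every background gene hangs off
this core through a random attachment tree with weaker weights.  Planted
genes therefore carry both a stochastically larger weighted degree and the
connectivity burden of the core, while the tree-like periphery is exactly
the part the stability filter prunes away.

Datasets follow the fusion-set construction used for evaluation: draw 2·Ni
susceptible partners without replacement and pair them into Ni positive
fusions; draw 2·No partners from the whole-network background pool and pair
them into No ordinary fusions; if an ordinary fusion duplicates a
susceptible one, the whole ordinary draw is redone on a fresh child seed.

Evaluation sorts fusions by significance and reports the interval
distribution of positives over ten rank deciles, the cumulative recognition
rate P(i), and the ROC curve with its trapezoidal AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .baselines import rank_fusions_baseline
from .fusion import FusionGene, FusionScore, rank_fusions
from .importance import ImportanceTable, importance_table
from .network import GeneNetwork, NetworkValidationError
from .stability import DEFAULT_S

__all__ = [
    "SyntheticNetworkSpec",
    "DatasetSpec",
    "EvaluationResult",
    "GridResult",
    "generate_synthetic_network",
    "sample_fusion_dataset",
    "interval_distribution",
    "recognition_rate",
    "recognition_rates",
    "roc_and_auc",
    "evaluate_ranking",
    "run_experiment_grid",
    "DEFAULT_NF_GRID",
    "DEFAULT_NI_GRID",
    "DEFAULT_REPLICATES",
]

log = logging.getLogger(__name__)

#: Experiment grid of total and susceptible fusion counts.
DEFAULT_NF_GRID = (150, 200, 250)
DEFAULT_NI_GRID = (15, 25)
DEFAULT_REPLICATES = 20

_MODULE_SIZE = 3  # planted genes per backbone module
_N_INTERVALS = 10


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Parameters of the planted-hub synthetic gene network.

    Weight ranges are uniform-draw bounds; planted-incident edges (module,
    bridge and hub-attachment edges) are stochastically heavier than
    background-tree edges, and background genes attach to a planted hub
    with probability ``hub_attach_prob`` — far above the planted share of
    nodes, so planted genes are also better connected.
    """

    n_genes: int = 200
    susceptible_fraction: float = 0.15
    edge_density: float | None = None  # extra random background edges up to this
    hub_attach_prob: float = 0.6
    module_weight: tuple[float, float] = (0.75, 0.95)
    bridge_weight: tuple[float, float] = (0.55, 0.75)
    hub_leaf_weight: tuple[float, float] = (0.35, 0.70)
    background_weight: tuple[float, float] = (0.05, 0.45)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.susceptible_fraction < 1.0):
            raise NetworkValidationError(
                "susceptible_fraction must lie strictly between 0 and 1"
            )
        if self.n_genes < 10:
            raise NetworkValidationError("n_genes must be at least 10")
        n_planted = round(self.n_genes * self.susceptible_fraction)
        if n_planted < 2 * _MODULE_SIZE:
            raise NetworkValidationError(
                "the planted backbone needs at least two modules "
                f"({2 * _MODULE_SIZE} susceptible genes); got {n_planted}"
            )
        if self.edge_density is not None and not (0.0 < self.edge_density < 0.5):
            raise NetworkValidationError("edge_density must lie in (0, 0.5)")

    @property
    def n_planted(self) -> int:
        return round(self.n_genes * self.susceptible_fraction)


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    return float(rng.uniform(*bounds))


def generate_synthetic_network(
    spec: SyntheticNetworkSpec,
) -> tuple[GeneNetwork, list[str]]:
    """Build the planted-hub network; returns (network, susceptible genes).

    Reproducible for a fixed spec (seed included); the planted list is the
    positive-label pool for dataset sampling.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_genes
    names = [f"g{i:04d}" for i in range(n)]
    planted_idx = rng.choice(n, size=spec.n_planted, replace=False)
    planted = [names[i] for i in planted_idx]
    background = [names[i] for i in range(n) if i not in set(planted_idx)]

    edges: list[tuple[str, str, float]] = []

    # backbone: modules of three planted genes, bridged in a chain
    n_modules = spec.n_planted // _MODULE_SIZE
    modules = [
        list(planted[k * _MODULE_SIZE : (k + 1) * _MODULE_SIZE]) for k in range(n_modules)
    ]
    for i, extra in enumerate(planted[n_modules * _MODULE_SIZE :]):
        modules[i % n_modules].append(extra)
    for mod in modules:
        for a_i in range(len(mod)):
            for b_i in range(a_i + 1, len(mod)):
                edges.append((mod[a_i], mod[b_i], _uniform(rng, spec.module_weight)))
    for prev, nxt in zip(modules, modules[1:]):
        a = prev[rng.integers(len(prev))]
        b = nxt[rng.integers(len(nxt))]
        edges.append((a, b, _uniform(rng, spec.bridge_weight)))

    # periphery: every background gene attaches once, preferentially to hubs
    attached: list[str] = []
    for gene in background:
        if attached and rng.random() >= spec.hub_attach_prob:
            parent = attached[rng.integers(len(attached))]
            w = _uniform(rng, spec.background_weight)
        else:
            parent = planted[rng.integers(len(planted))]
            w = _uniform(rng, spec.hub_leaf_weight)
        edges.append((gene, parent, w))
        attached.append(gene)

    if spec.edge_density is not None:
        target = int(round(spec.edge_density * n * (n - 1) / 2))
        if target < len(edges):
            raise NetworkValidationError(
                f"edge_density {spec.edge_density} is below the structural "
                f"minimum ({len(edges)} edges, density "
                f"{2 * len(edges) / (n * (n - 1)):.4f})"
            )
        have = {(min(a, b), max(a, b)) for a, b, _ in edges}
        guard = 0
        while len(edges) < target:
            a, b = (background[k] for k in rng.integers(len(background), size=2))
            key = (min(a, b), max(a, b))
            if a == b or key in have:
                guard += 1
                if guard > 50 * target:
                    raise NetworkValidationError("edge_density target unreachable")
                continue
            have.add(key)
            edges.append((a, b, _uniform(rng, spec.background_weight)))

    return GeneNetwork(edges, nodes=names), sorted(planted)


# ---------------------------------------------------------------------------
# dataset sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetSpec:
    """Fusion-set sizes: Nf total fusions of which Ni are susceptible."""

    n_fusions: int
    n_susceptible: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_susceptible < self.n_fusions):
            raise NetworkValidationError(
                "need 0 < n_susceptible < n_fusions, got "
                f"Ni={self.n_susceptible}, Nf={self.n_fusions}"
            )

    @property
    def n_ordinary(self) -> int:
        return self.n_fusions - self.n_susceptible


def _draw_pairs(
    rng: np.random.Generator, pool: list[str], n_pairs: int, label: int
) -> list[FusionGene]:
    chosen = rng.choice(len(pool), size=2 * n_pairs, replace=False)
    return [
        FusionGene(pool[chosen[2 * k]], pool[chosen[2 * k + 1]], label)
        for k in range(n_pairs)
    ]


def sample_fusion_dataset(
    susceptible_pool: list[str],
    background_pool: list[str],
    spec: DatasetSpec,
    *,
    max_redraws: int = 1000,
) -> list[FusionGene]:
    """Sample a labeled fusion dataset.

    Partners are drawn without replacement inside each pool, so no gene
    fills two slots of the same draw and no fusion repeats within the
    dataset.  The background pool normally contains every network gene
    (susceptible ones included), so an ordinary fusion can collide with a
    susceptible one; the entire ordinary draw is then redone on a fresh
    child seed until the two sets are disjoint.  Each random process runs
    on its own child stream of the dataset seed.
    """
    if 2 * spec.n_susceptible > len(susceptible_pool):
        raise NetworkValidationError(
            f"susceptible pool of {len(susceptible_pool)} cannot supply "
            f"{2 * spec.n_susceptible} distinct partners"
        )
    if 2 * spec.n_ordinary > len(background_pool):
        raise NetworkValidationError(
            f"background pool of {len(background_pool)} cannot supply "
            f"{2 * spec.n_ordinary} distinct partners"
        )
    rng_sus = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    susceptible = _draw_pairs(rng_sus, list(susceptible_pool), spec.n_susceptible, 1)
    taken = {f.pair for f in susceptible}
    for attempt in range(max_redraws):
        rng_ord = np.random.default_rng(
            np.random.SeedSequence(spec.seed, spawn_key=(1, attempt))
        )
        ordinary = _draw_pairs(rng_ord, list(background_pool), spec.n_ordinary, 0)
        if not any(f.pair in taken for f in ordinary):
            break
    else:
        raise NetworkValidationError(
            f"could not draw a collision-free ordinary set in {max_redraws} attempts"
        )
    return susceptible + ordinary


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------


def _labels_of(scores: list[FusionScore]) -> list[int]:
    labels = [fs.fusion.label for fs in scores]
    if any(lab is None for lab in labels):
        raise NetworkValidationError("evaluation requires labeled fusions")
    return labels  # type: ignore[return-value]


def interval_distribution(scores: list[FusionScore]) -> np.ndarray:
    """Counts of positive fusions per rank decile I_i = ((i−1)Nf/10, iNf/10].

    Interval edges are real-valued when Nf is not a multiple of ten; integer
    ranks are compared against them directly, and a rank sitting exactly on
    an edge belongs to the lower-indexed interval (half-open bracket).
    """
    n_f = len(scores)
    ranks = sorted(fs.rank for fs in scores)
    if ranks != list(range(1, n_f + 1)):
        raise NetworkValidationError("ranks must be a permutation of 1..Nf")
    counts = np.zeros(_N_INTERVALS, dtype=int)
    for fs in scores:
        if fs.fusion.label == 1:
            i = int(np.ceil(_N_INTERVALS * fs.rank / n_f))
            counts[i - 1] += 1
    return counts


def recognition_rate(counts: np.ndarray, n_i: int, i: int) -> float:
    """P(i): cumulative fraction of positives found within the top i/10."""
    if n_i <= 0:
        raise NetworkValidationError("recognition rate undefined for Ni = 0")
    if not (1 <= i <= _N_INTERVALS):
        raise ValueError(f"interval index must be 1..{_N_INTERVALS}, got {i}")
    return float(np.sum(counts[:i])) / n_i


def recognition_rates(counts: np.ndarray, n_i: int) -> np.ndarray:
    return np.array([recognition_rate(counts, n_i, i) for i in range(1, 11)])


def roc_and_auc(
    scores: list[FusionScore],
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points (FP rate, TP rate) and trapezoidal AUC from fusion scores.

    Thresholds sweep the distinct score values descending; tied scores move
    as one step, so the AUC equals the Mann-Whitney pair statistic with
    ties counted one half.
    """
    labels = _labels_of(scores)
    if len(set(labels)) < 2:
        raise NetworkValidationError("ROC needs both positive and negative fusions")
    y = np.asarray(labels)
    sc = np.asarray([fs.score for fs in scores], dtype=float)
    fpr, tpr, _ = _roc_curve(y, sc, drop_intermediate=False)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


@dataclass(frozen=True)
class EvaluationResult:
    """All metrics of one algorithm on one dataset."""

    algorithm: str
    n_fusions: int
    n_susceptible: int
    replicate: int
    dataset_seed: int
    interval_counts: tuple[int, ...]
    recognition: tuple[float, ...]
    fpr: tuple[float, ...] = field(repr=False)
    tpr: tuple[float, ...] = field(repr=False)
    auc: float = float("nan")


def evaluate_ranking(
    scores: list[FusionScore],
    *,
    replicate: int = 0,
    dataset_seed: int = 0,
) -> EvaluationResult:
    counts = interval_distribution(scores)
    n_i = sum(1 for fs in scores if fs.fusion.label == 1)
    rates = recognition_rates(counts, n_i)
    fpr, tpr, auc_value = roc_and_auc(scores)
    return EvaluationResult(
        algorithm=scores[0].algorithm,
        n_fusions=len(scores),
        n_susceptible=n_i,
        replicate=replicate,
        dataset_seed=dataset_seed,
        interval_counts=tuple(int(c) for c in counts),
        recognition=tuple(float(r) for r in rates),
        fpr=tuple(float(x) for x in fpr),
        tpr=tuple(float(x) for x in tpr),
        auc=auc_value,
    )


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------


@dataclass
class GridResult:
    """Results of a full experiment grid on one network."""

    results: list[EvaluationResult]
    failures: list[tuple[str, str]]
    n_datasets: int
    network: GeneNetwork = field(repr=False)
    susceptible: list[str] = field(repr=False, default_factory=list)
    importance: ImportanceTable | None = field(repr=False, default=None)

    def mean_auc(self, algorithm: str) -> float:
        vals = [r.auc for r in self.results if r.algorithm == algorithm]
        if not vals:
            raise KeyError(f"no results for algorithm {algorithm!r}")
        return float(np.mean(vals))

    def summary(self) -> pd.DataFrame:
        """Per-configuration means over replicates (figure-style aggregation)."""
        frame = self.to_frame()
        keep = frame[frame.metric.isin(["auc"] + [f"P{i}" for i in range(1, 11)])]
        return (
            keep.groupby(["n_fusions", "n_susceptible", "algorithm", "metric"])["value"]
            .mean()
            .reset_index()
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            config_id = f"Nf{r.n_fusions}_Ni{r.n_susceptible}"
            base = {
                "config_id": config_id,
                "n_fusions": r.n_fusions,
                "n_susceptible": r.n_susceptible,
                "replicate": r.replicate,
                "algorithm": r.algorithm,
            }
            rows.append({**base, "metric": "auc", "value": r.auc})
            for i, c in enumerate(r.interval_counts, start=1):
                rows.append({**base, "metric": f"I{i}", "value": float(c)})
            for i, p in enumerate(r.recognition, start=1):
                rows.append({**base, "metric": f"P{i}", "value": p})
        return pd.DataFrame(rows)


def _child_seed(master: int, *key: int) -> int:
    state = np.random.SeedSequence(master, spawn_key=tuple(key)).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def run_experiment_grid(
    network: GeneNetwork | None = None,
    susceptible: list[str] | None = None,
    *,
    network_spec: SyntheticNetworkSpec | None = None,
    nf_grid: tuple[int, ...] = DEFAULT_NF_GRID,
    ni_grid: tuple[int, ...] = DEFAULT_NI_GRID,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    s: float = DEFAULT_S,
    lambda2_mode: str = "weighted",
    algorithms: tuple[str, ...] = ("SYN", "DEG", "BET"),
    merge_policy: str = "max",
    path_mode: str = "hop",
    weight_source: str = "original",
) -> GridResult:
    """Run every (Nf, Ni) configuration for every replicate seed.

    One network (supplied, or generated from *network_spec* on a child seed
    of *seed*) serves the whole grid; node importances are computed once and
    shared.  Each dataset is sampled on its own child seed, scored by every
    requested algorithm, and evaluated; a failure in one dataset is recorded
    and does not abort the rest.
    """
    if network is None:
        if susceptible is not None:
            raise ValueError("susceptible genes supplied without a network")
        spec = network_spec or SyntheticNetworkSpec()
        spec = replace(spec, seed=_child_seed(seed, 0))
        network, susceptible = generate_synthetic_network(spec)
    if not susceptible:
        raise NetworkValidationError("a non-empty susceptible gene list is required")

    imp = None
    if "SYN" in algorithms:
        imp = importance_table(network, s=s, lambda2_mode=lambda2_mode)
    background_pool = sorted(network.nodes)  # ordinary partners: any network gene
    caches: dict[str, dict] = {"DEG": {}, "BET": {}}

    results: list[EvaluationResult] = []
    failures: list[tuple[str, str]] = []
    n_datasets = 0
    for cfg_idx, (n_f, n_i) in enumerate(product(nf_grid, ni_grid)):
        for rep in range(replicates):
            ds_seed = _child_seed(seed, 1, cfg_idx, rep)
            tag = f"Nf{n_f}_Ni{n_i}_rep{rep}"
            try:
                dataset = sample_fusion_dataset(
                    susceptible, background_pool, DatasetSpec(n_f, n_i, ds_seed)
                )
                n_datasets += 1
                for algo in algorithms:
                    if algo == "SYN":
                        ranked = rank_fusions(
                            dataset, imp, network, weight_source=weight_source
                        )
                    else:
                        ranked = rank_fusions_baseline(
                            dataset,
                            network,
                            algo,
                            merge_policy=merge_policy,
                            path_mode=path_mode,
                            _cache=caches.get(algo),
                        )
                    results.append(
                        evaluate_ranking(ranked, replicate=rep, dataset_seed=ds_seed)
                    )
            except Exception as err:  # per-dataset isolation
                log.error("dataset %s failed: %s", tag, err)
                failures.append((tag, str(err)))
    return GridResult(
        results=results,
        failures=failures,
        n_datasets=n_datasets,
        network=network,
        susceptible=list(susceptible),
        importance=imp,
    )
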