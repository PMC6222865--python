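"""Fusion-gene significance and ranking.

A fusion gene is an unordered pair of partner genes.  Its significance adds
the partners' importances and rewards a direct interaction between them:

    S(f) = (1 + w_ij) · (H(i) + H(j))

where w_ij is the edge weight between the partners in the original input
network (0 when no edge joins them).  Fusions are ranked by descending S;
ties break on the canonical fusion name so ranks are deterministic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .importance import ImportanceTable
from .network import GeneNetwork, NetworkValidationError

__all__ = [
    "FusionGene",
    "FusionScore",
    "fusion_significance",
    "rank_fusions",
    "load_fusions",
    "write_scores",
]


@dataclass(frozen=True)
class FusionGene:
    """An unordered partner pair with an optional susceptibility label."""

    partner_a: str
    partner_b: str
    label: int | None = None  # 1 = susceptible, 0 = ordinary, None = unknown

    def __post_init__(self) -> None:
        if self.partner_a == self.partner_b:
            raise NetworkValidationError(
                f"fusion partners must differ, got {self.partner_a!r} twice"
            )
        if self.partner_a > self.partner_b:  # canonical order
            a, b = self.partner_b, self.partner_a
            object.__setattr__(self, "partner_a", a)
            object.__setattr__(self, "partner_b", b)
        if self.label is not None and self.label not in (0, 1):
            raise NetworkValidationError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.partner_a, self.partner_b)

    @property
    def name(self) -> str:
        return f"{self.partner_a}-{self.partner_b}"


@dataclass(frozen=True)
class FusionScore:
    fusion: FusionGene
    score: float
    rank: int  # 1-based position in descending score order
    algorithm: str  # "SYN" | "DEG" | "BET"


def fusion_significance(h_i: float, h_j: float, w_ij: float) -> float:
    """S = (1 + w_ij)(H_i + H_j)."""
    if not (0.0 <= w_ij <= 1.0):
        raise NetworkValidationError(f"partner edge weight {w_ij} outside [0, 1]")
    return (1.0 + w_ij) * (h_i + h_j)


def _assign_ranks(
    fusions: list[FusionGene], scores: list[float], algorithm: str
) -> list[FusionScore]:
    if len({f.pair for f in fusions}) != len(fusions):
        raise NetworkValidationError("duplicate fusion in input")
    order = sorted(range(len(fusions)), key=lambda i: (-scores[i], fusions[i].name))
    out = [None] * len(fusions)
    for rank, i in enumerate(order, start=1):
        out[i] = FusionScore(fusions[i], scores[i], rank, algorithm)
    return sorted(out, key=lambda fs: fs.rank)


def rank_fusions(
    fusions: list[FusionGene],
    importances: ImportanceTable,
    network: GeneNetwork,
    *,
    weight_source: str = "original",
) -> list[FusionScore]:
    """Score and rank fusions by S(f), descending.

    The partner edge weight is looked up in the original input network by
    default — the interaction tendency of the partners is a property of the
    data, not of the stability filtering — or in the stabilized baseline
    with ``weight_source="stabilized"``.  Partners without an importance
    entry contribute H = 0.
    """
    if weight_source == "original":
        wnet = network
    elif weight_source == "stabilized":
        wnet = importances.stabilized
    else:
        raise ValueError(f"unknown weight source {weight_source!r}")
    scores = [
        fusion_significance(
            importances.score(f.partner_a),
            importances.score(f.partner_b),
            wnet.weight(f.partner_a, f.partner_b),
        )
        for f in fusions
    ]
    return _assign_ranks(fusions, scores, "SYN")


def load_fusions(source: str | Path | io.TextIOBase) -> list[FusionGene]:
    """Read a fusion-pair TSV: partner_a, partner_b[, label]."""
    if isinstance(source, io.TextIOBase):
        lines = source.readlines()
        name = "<stream>"
    else:
        p = Path(source)
        if not p.exists():
            raise FileNotFoundError(f"fusion file not found: {p}")
        lines = p.read_text().splitlines()
        name = str(p)
    out: list[FusionGene] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) not in (2, 3):
            raise NetworkValidationError(
                f"{name}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
            )
        label: int | None = None
        if len(parts) == 3:
            try:
                label = int(parts[2])
            except ValueError:
                if lineno == 1 and not out:
                    continue  # header row
                raise NetworkValidationError(
                    f"{name}:{lineno}: non-integer label {parts[2]!r}"
                ) from None
        try:
            out.append(FusionGene(parts[0], parts[1], label))
        except NetworkValidationError as err:
            raise NetworkValidationError(f"{name}:{lineno}: {err}") from None
    return out


def write_scores(scores: list[FusionScore], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "partner_a": [fs.fusion.partner_a for fs in scores],
            "partner_b": [fs.fusion.partner_b for fs in scores],
            "S": [fs.score for fs in scores],
            "rank": [fs.rank for fs in scores],
            "algorithm": [fs.algorithm for fs in scores],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
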