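"""Run configuration: documented defaults plus YAML round-trip.

Every tunable of the pipeline lives here so a run can be serialized next to
its outputs and replayed exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .benchmark import DEFAULT_NF_GRID, DEFAULT_NI_GRID, DEFAULT_REPLICATES
from .stability import DEFAULT_S

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline settings with their defaults.

    stability.* control the synchronous-stability filter, baselines.* the
    burden-node centralities, fusion.* the significance formula, and
    benchmark.* the synthetic experiment grid.
    """

    # stability
    s: float = DEFAULT_S  # coupling-factor multiplier a = s·λ2
    lambda2_mode: str = "weighted"  # "weighted" | "unweighted" Laplacian
    drop_singletons: bool = False  # drop genes isolated by edge deletion
    gradient_tol: float = 0.05  # depression-point gradient tolerance
    # baselines
    merge_policy: str = "max"  # overlapped-edge rule: "max" | "sum"
    path_mode: str = "hop"  # betweenness distances: "hop" | "inverse-weight"
    # fusion scoring
    weight_source: str = "original"  # partner w_ij lookup: "original" | "stabilized"
    # benchmark
    nf_grid: tuple[int, ...] = DEFAULT_NF_GRID
    ni_grid: tuple[int, ...] = DEFAULT_NI_GRID
    replicates: int = DEFAULT_REPLICATES
    n_genes: int = 560  # grid-scale synthetic network size
    susceptible_fraction: float = 0.1
    # randomness
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["nf_grid"] = list(self.nf_grid)
        data["ni_grid"] = list(self.ni_grid)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("nf_grid", "ni_grid"):
            if key in data:
                data[key] = tuple(int(x) for x in data[key])
        return cls(**data)
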