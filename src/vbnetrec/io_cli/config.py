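"""Run configuration with lossless YAML/JSON round-tripping."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]

MODES = (
    "simulate",
    "fixture",
    "fit-phenotypes",
    "fit-network",
    "build-graph",
    "baseline",
    "benchmark",
    "refit-ols",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one CLI run bit-for-bit.

    Defaults follow the reference protocol: threshold 0.99, 1000 restarts for
    phenotype neighborhoods, 50 for expression neighborhoods, 20 expression
    principal components.
    """

    mode: str
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)
    threshold: float = 0.99
    phenotype_restarts: int = 1000
    expression_restarts: int = 50
    n_pcs: int = 20
    rel_tol: float = 1e-6
    max_sweeps: int = 500
    fp_bound: float = 1.0
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {MODES}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        try:  # JSON first: YAML 1.1 misreads "1e-06" (no dot) as a string
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = yaml.safe_load(text)
        return cls(**raw)
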