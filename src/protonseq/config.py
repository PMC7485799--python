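"""Run configuration: one flat record tying all simulation parameters
together, loadable from YAML and overridable from the command line."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .kinetics import SolutionConditions
from .trace_sim import NoiseSpec, ShieldingModel

__all__ = ["RunConfig"]

_DISTANCE_MAPS = {
    "sqrt": np.sqrt,
    "identity": lambda d: np.asarray(d, dtype=float),
}


@dataclass
class RunConfig:
    """Baseline peptide-sequencing conditions: pH 2.5, initial SNR 10,
    shielding exp(-0.2 sqrt(d)), 100 ms per residue at 10 MHz, 1 ms chunks
    with a size-3 median filter, blocked side chains, tryptic N-terminal
    peptides up to length 50.  Isolated-residue runs conventionally use
    pH 3.0 and free side chains instead."""

    ph: float = 2.5
    snr: float = 10.0
    chi: float = 0.2
    distance_map: str = "sqrt"
    duration_per_aa: float = 0.1
    sample_rate: float = 1e7
    chunk_duration: float = 1e-3
    filter_size: int = 3
    side_chains: str = "blocked"
    enzyme: str = "trypsin"
    max_peptide_length: int | None = 50
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snr", "chi", "duration_per_aa", "sample_rate", "chunk_duration"):
            if not (getattr(self, name) >= 0):
                raise ValueError(f"{name} must be positive")
        if self.side_chains not in ("free", "blocked"):
            raise ValueError(f"invalid side_chains: {self.side_chains!r}")
        if self.distance_map not in _DISTANCE_MAPS:
            raise ValueError(f"unknown distance_map: {self.distance_map!r}")

    @property
    def conditions(self) -> SolutionConditions:
        return SolutionConditions(ph=self.ph)

    @property
    def shielding(self) -> ShieldingModel:
        return ShieldingModel(chi=self.chi, distance_map=_DISTANCE_MAPS[self.distance_map])

    @property
    def noise(self) -> NoiseSpec:
        return NoiseSpec(snr=self.snr)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
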