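"""Run configuration: nutrient conditions, model variant, all parameter
blocks, lattice geometry and numerical settings, with YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .cells import CellCycleParams
from .fields import DiffusionParams
from .metabolism import MetabolicParams
from .variants import ModelSpec

#: nutrient media: name -> (glucose mM, oxygen mM)
CONDITIONS = {
    "I": (1.0, 0.28),     # hyponourished
    "II": (5.0, 0.28),    # physiological
    "III": (25.0, 0.28),  # hypernourished
    "IV": (25.0, 0.07),   # hypoxic
}


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one spheroid growth run.

    Times are hours internally; the default initial population is
    desk-scale (hundreds to a couple thousand cells) rather than the
    experiment-scale ~10^4; the reference scale remains available by
    raising ``initial_cells`` and ``n_per_dim``.
    """

    medium_G: float = 25.0
    medium_O: float = 0.28
    model: ModelSpec = field(default_factory=ModelSpec)
    cycle: CellCycleParams = field(default_factory=CellCycleParams)
    metabolic: MetabolicParams = field(default_factory=MetabolicParams)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    n_per_dim: int = 30
    spacing: float = 16.8
    jitter: float = 0.25
    initial_cells: int = 1000
    t_end: float = 240.0          # h
    field_interval: float = 0.1   # h
    output_interval: float = 12.0  # h
    record_profiles: bool = True
    profile_bin_width: float = 16.8  # one cell layer
    #: age (h) assigned to the initial tissue for ECM seeding: spheroids
    #: are pre-formed for ~2 days before tracking starts
    initial_tissue_age: float = 48.0
    solver_tol: float = 1e-8
    linear_solver: str = "bicgstab"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.field_interval <= 0 or self.output_interval <= 0:
            raise ValueError("intervals must be > 0")
        if self.medium_G < 0 or self.medium_O < 0:
            raise ValueError("medium concentrations must be >= 0")

    # -- constructors ------------------------------------------------------

    @classmethod
    def for_condition(cls, name: str, **overrides) -> "SimulationConfig":
        """Config preset for one of the nutrient conditions I-IV."""
        g, o = CONDITIONS[name]
        return cls(medium_G=g, medium_O=o, **overrides)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key, sub in (("model", ModelSpec), ("cycle", CellCycleParams),
                         ("metabolic", MetabolicParams),
                         ("diffusion", DiffusionParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def digest(self) -> str:
        """Provenance hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
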