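"""Pipeline configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .network import DEFAULT_SPARSITY_GRID
from .signal import DEFAULT_BANDS, BandDefinition

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the end-to-end analysis chain.

    Defaults mirror the study protocol: theta+alpha (4-13 Hz) and beta
    (14-30 Hz) bands, 8 s PLI epochs, a 5-40% sparsity grid in 5% steps,
    and 20 degree-preserving random references per graph.
    """

    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    epoch_length: float = 8.0
    sparsity_grid: tuple[float, ...] = DEFAULT_SPARSITY_GRID
    n_random_realizations: int = 20
    seed: int = 0
    path_method: str = "harmonic"
    # simulate-spec (used when no recordings are supplied)
    profile_a: str = "resting"
    profile_b: str = "fatigue"
    n_per_group: int = 13
    duration: float = 60.0
    fs: float = 250.0
    output_dir: str = "neurostates_out"

    def __post_init__(self) -> None:
        self.bands = tuple(
            b if isinstance(b, BandDefinition) else BandDefinition(**b)
            for b in self.bands
        )
        self.sparsity_grid = tuple(float(s) for s in self.sparsity_grid)
        for s in self.sparsity_grid:
            if not 0.0 < s <= 1.0:
                raise ValueError(f"sparsity grid value {s} outside (0, 1]")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if self.n_random_realizations < 1:
            raise ValueError("n_random_realizations must be >= 1")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.duration < 4.0:
            raise ValueError("duration must be >= 4 s")
        if self.path_method not in ("harmonic", "arithmetic"):
            raise ValueError(f"unknown path_method {self.path_method!r}")
        for band in self.bands:
            band.validate_for_fs(self.fs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [asdict(b) for b in self.bands]
        d["sparsity_grid"] = list(self.sparsity_grid)
        return d

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)
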