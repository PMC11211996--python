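"""Run configuration: validated settings serialized alongside every result."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

DEFAULT_SEEDS = [
    "entorhinal", "fusiform", "inferiortemporal", "middletemporal",
    "supramarginal",
]
DEFAULT_THRESHOLDS = [0.5, 0.4, 0.3, 0.2, 0.1, 0.05]


@dataclass
class RunConfig:
    connectomes: dict[str, str] = field(default_factory=dict)  # modality -> path
    pathology: str | None = None
    seeds: list[str] = field(default_factory=lambda: list(DEFAULT_SEEDS))
    thresholds: list[float] = field(default_factory=lambda: list(DEFAULT_THRESHOLDS))
    beta: float = 1.0
    t_min: float = 1e-3
    t_max: float = 1e3
    n_times: int = 501
    refine: bool = False
    n_random: int = 300
    n_iter: int = 500
    n_nulls: int = 100
    n_repeats: int = 100
    n_subsample: int = 30
    cv_folds: int = 5
    rng_seed: int = 0
    output_dir: str = "netspread_out"

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 < self.t_min < self.t_max:
            raise ValueError("need 0 < t_min < t_max")
        if self.n_times < 3:
            raise ValueError("need at least 3 timepoints")
        for f in self.thresholds:
            if not 0 < f <= 1:
                raise ValueError(f"threshold {f} outside (0, 1]")

    def time_grid(self):
        from .diffusion import default_time_grid

        return default_time_grid(self.t_min, self.t_max, self.n_times)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def save(self, path) -> None:
        path = Path(path)
        data = asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
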