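"""Run configuration: validated stage parameters with named presets.

The ``full`` preset carries the production defaults (nu = 10, L = 232,
T = 5, 7500 training epochs); ``desk`` scales the score model down for
laptop-sized runs and tests (L = 50, 2000 epochs, <= 64 genes expected).
Unknown keys are rejected so typos cannot silently change a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

__all__ = ["RunConfig", "PRESETS"]


@dataclass
class RunConfig:
    # cell typing
    nu: float = 10.0
    n_restarts: int = 5
    radius: float = 1.5
    # score model
    L: int = 232
    T: int = 5
    eta0: float = 1e-5
    epochs: int = 7500
    sigma_min: float = 0.01
    sigma_max: float | None = None      # None: max pairwise distance rule
    # decomposition
    R: int = 10
    link: str = "exp"
    # gene selection
    n_hvg: int = 1000
    n_markers_per_type: int = 50
    # bookkeeping
    seed: int = 0
    preset: str = "full"
    # paths
    reference_path: str | None = None
    labels_path: str | None = None
    spots_prefix: str | None = None
    out_dir: str = "spotcell_out"

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise ValueError("nu must be >= 0")
        if self.L < 2 or self.T < 1:
            raise ValueError("L >= 2 and T >= 1 required")
        if self.eta0 <= 0:
            raise ValueError("eta0 must be positive")
        if self.epochs < 1 or self.R < 1 or self.n_restarts < 1:
            raise ValueError("epochs, R, n_restarts must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.sigma_min <= 0:
            raise ValueError("sigma_min must be positive")
        if self.sigma_max is not None and self.sigma_max <= self.sigma_min:
            raise ValueError("sigma_max must exceed sigma_min")
        if self.link not in ("exp", "linear"):
            raise ValueError("link must be 'exp' or 'linear'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        preset = data.get("preset", "full")
        base = PRESETS.get(preset)
        if base is None:
            raise ValueError(f"unknown preset {preset!r}")
        return replace(base, **data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


PRESETS = {
    "full": RunConfig(),
    "desk": RunConfig(L=50, epochs=2000, n_hvg=64, n_markers_per_type=4,
                      preset="desk"),
}
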