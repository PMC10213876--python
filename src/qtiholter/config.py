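"""Pipeline configuration with paper-faithful defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .diagnostics import DEFAULT_CUTOFFS
from .regression import RR_GRID

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters in one flat, serializable object.

    Defaults encode the published measurement protocol: 30-s template
    windows, the QT > 700 ms template filter, the 4-h minimum of useful
    registration, the 600-1400 ms RR evaluation grid and the
    sex-specific QTi cut-offs (430 ms male / 445 ms female).
    """

    fs_hz: float = 200.0
    n_channels: int = 2
    duration_h: float = 24.0
    window_s: float = 30.0
    qt_max_ms: float = 700.0
    min_useful_h: float = 4.0
    min_beats: int = 15
    qti_rr_grid: tuple = RR_GRID
    cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    seed: int = 0

    def __post_init__(self):
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.qt_max_ms <= 0:
            raise ValueError("qt_max_ms must be positive")
        if any(v <= 0 for v in self.qti_rr_grid):
            raise ValueError("RR grid values must be positive")

    @property
    def min_points(self) -> int:
        """Regression minimum-point rule tied to the useful-hours rule."""
        return int(self.min_useful_h * 3600 / self.window_s)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["qti_rr_grid"] = list(self.qti_rr_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "qti_rr_grid" in d:
            d["qti_rr_grid"] = tuple(d["qti_rr_grid"])
        return cls(**d)
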