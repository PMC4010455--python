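"""Run configuration: one validated, YAML-round-trippable record per run."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .costgraph import CostParams
from .grid import GridSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialisable to YAML.

    The grid may be omitted (None), in which case commands infer it from
    the station extent and ``cell_size``.
    """

    grid: GridSpec | None = None
    cell_size: float = 500.0
    shape_c: float | None = None
    gamma: float = 4.0
    beta: float = 2.0
    speed_weighting: bool = False
    calm_threshold: float = 0.1
    power: float = 2.0
    metric: str = "swpd"
    direction: str = "station_to_point"
    convention: str = "from"
    wind_csv: str | None = None
    conc_csv: str | None = None
    out_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.metric not in ("euclidean", "swpd"):
            raise ValueError(f"metric must be 'euclidean' or 'swpd', got {self.metric!r}")
        if self.direction not in ("station_to_point", "point_to_station"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.convention not in ("from", "toward"):
            raise ValueError(f"invalid convention {self.convention!r}")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if not self.power > 0:
            raise ValueError("power must be > 0")
        # validates gamma/beta bounds
        self.cost_params()

    def cost_params(self) -> CostParams:
        return CostParams(
            gamma=self.gamma,
            beta=self.beta,
            speed_weighting=self.speed_weighting,
            calm_threshold=self.calm_threshold,
        )

    def to_yaml(self, path) -> None:
        data = asdict(self)
        if self.grid is not None:
            data["grid"] = asdict(self.grid)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if data.get("grid") is not None:
            data["grid"] = GridSpec(**data["grid"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)
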