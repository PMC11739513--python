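"""Run configuration: schema-validated, unknown keys rejected.

The YAML layout mirrors the pipeline stages::

    seed: 7
    geometry:
      mesh_path: null          # STL path, or null for the synthetic ellipsoid
      target_volume_ml: 1600.0
      n_super_lobules: 100
      points_per_sl: 200
      min_cloud: 5000
      blood_volume_fraction: 0.25
    growth: {D: 5.0, d_k: 10.0, d_i: 15.0, max_iterations: 2000}
    primary: {}                # roots/targets; defaults derived from geometry
    flow:
      P_in_mmHg: 5.8
      P_out_mmHg: 0.0
      Q_target_ml_min: 767.0
      mu_cP: 3.5
      gamma: 3.0
      root_diameter_mm: 15.0
      bisect_tol: 1.0e-8
      bisect_upper: 1.0
    perfusion:
      dt_s: 0.01
      thresholds: [0.5, 0.9, 0.98]
      t_max_s: 3600.0
      inlet_concentration: 1.0
      scheme: previous
    sweep:
      pressures_mmHg: [3, 4, 5, 6, 7, 8, 9, 10, 11, 12]
      flows_ml_min: [100, 200, 300, 400, 500, 600, 700, 800, 900, 1000]
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError

__all__ = [
    "GeometryConfig",
    "GrowthConfig",
    "PrimaryConfig",
    "FlowConfig",
    "PerfusionConfig",
    "SweepConfig",
    "RunConfig",
]


def _from_dict(cls, d: dict, path: str):
    if not isinstance(d, dict):
        raise ConfigError(f"section '{path}' must be a mapping, got {type(d).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(d) - names)
    if unknown:
        raise ConfigError(f"unknown key(s) in '{path}': {unknown}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
                v = _from_dict(f.type, v, f"{path}.{f.name}")
            kwargs[f.name] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid value in '{path}': {err}") from err


@dataclass
class GeometryConfig:
    mesh_path: str | None = None
    target_volume_ml: float = 1600.0
    ellipsoid_ratios: tuple[float, float, float] = (2.0, 1.2, 0.8)
    n_super_lobules: int = 100
    points_per_sl: int = 200
    min_cloud: int = 5000
    blood_volume_fraction: float = 0.25

    def __post_init__(self):
        if self.target_volume_ml <= 0:
            raise ConfigError("target_volume_ml must be positive")
        if self.n_super_lobules < 1:
            raise ConfigError("n_super_lobules must be >= 1")
        if not (0 < self.blood_volume_fraction < 1):
            raise ConfigError("blood_volume_fraction must be in (0, 1)")

    @property
    def cloud_size(self) -> int:
        return max(self.points_per_sl * self.n_super_lobules, self.min_cloud)


@dataclass
class GrowthConfig:
    D: float = 5.0
    d_k: float = 10.0
    d_i: float = 15.0
    max_iterations: int = 2000


@dataclass
class PrimaryConfig:
    """Primary-branch stage: roots and anatomical targets.

    All positions are fractions of the domain half-extents about the
    centroid when `relative` is true (the default, so the same config works
    for any organ size), or absolute mm otherwise. Defaults place the two
    portal-vein targets in the left/right lobes and the three hepatic-vein
    targets left/middle/right. The first-stage sphere of influence defaults
    to the bounding-box diagonal so the root always sees its targets.
    """

    relative: bool = True
    inlet_root: tuple[float, float, float] = (0.0, -0.95, 0.0)
    # right lobe (+x) is larger, so the right-branch targets sit deeper
    inlet_targets: tuple = ((-0.45, -0.1, 0.0), (0.55, -0.05, -0.05))
    outlet_root: tuple[float, float, float] = (0.0, 0.95, 0.0)
    outlet_targets: tuple = (
        (-0.5, 0.15, 0.05),
        (0.0, 0.3, 0.12),
        (0.55, 0.1, 0.0),
    )
    D: float | None = None
    d_k: float | None = None
    d_i: float | None = None


@dataclass
class FlowConfig:
    P_in_mmHg: float = 5.8
    P_out_mmHg: float = 0.0
    Q_target_ml_min: float = 767.0
    mu_cP: float = 3.5
    gamma: float = 3.0
    root_diameter_mm: float = 15.0
    bisect_tol: float = 1e-8
    bisect_upper: float = 1.0


@dataclass
class PerfusionConfig:
    dt_s: float = 0.01
    thresholds: tuple[float, ...] = (0.5, 0.9, 0.98)
    t_max_s: float = 3600.0
    inlet_concentration: float = 1.0
    scheme: str = "previous"

    def __post_init__(self):
        if self.scheme not in ("previous", "updated"):
            raise ConfigError(f"unknown perfusion scheme {self.scheme!r}")
        if self.dt_s <= 0:
            raise ConfigError("dt_s must be positive")


@dataclass
class SweepConfig:
    pressures_mmHg: tuple[float, ...] = tuple(range(3, 13))
    flows_ml_min: tuple[float, ...] = tuple(range(100, 1001, 100))

    def __post_init__(self):
        if len(self.pressures_mmHg) == 0 or len(self.flows_ml_min) == 0:
            raise ConfigError("sweep grids must be non-empty")
        if min(self.pressures_mmHg) <= 0 or min(self.flows_ml_min) <= 0:
            raise ConfigError("sweep grids must be positive")


@dataclass
class RunConfig:
    seed: int = 0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    primary: PrimaryConfig = field(default_factory=PrimaryConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    perfusion: PerfusionConfig = field(default_factory=PerfusionConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)

    _SECTIONS = {
        "geometry": GeometryConfig,
        "growth": GrowthConfig,
        "primary": PrimaryConfig,
        "flow": FlowConfig,
        "perfusion": PerfusionConfig,
        "sweep": SweepConfig,
    }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if not isinstance(d, dict):
            raise ConfigError("config root must be a mapping")
        unknown = sorted(set(d) - set(cls._SECTIONS) - {"seed"})
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {unknown}")
        kwargs = {}
        if "seed" in d:
            if not isinstance(d["seed"], int):
                raise ConfigError("seed must be an integer")
            kwargs["seed"] = d["seed"]
        for name, section_cls in cls._SECTIONS.items():
            if name in d:
                kwargs[name] = _from_dict(section_cls, d[name], name)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
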