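"""Run configuration: one YAML-serialisable object holding every
parameter of a pipeline run (dosing, pharmacodynamics, rendering,
imaging protocol, analysis radii/bands/windows, QC thresholds, seed).

The seed is mandatory — a run without one is refused rather than being
silently nondeterministic.  Configs round-trip losslessly through YAML
and the effective config is archived next to every run's outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .render import ImagingProtocol, RenderParams
from .simulate import PDParams

__all__ = ["PKConfig", "AnalysisConfig", "QCThresholds", "RunConfig"]


@dataclass(frozen=True)
class PKConfig:
    """Dosing-profile parameters; mode selects the regimen."""

    mode: str = "pk"  # "pk" | "constant" | "vehicle"
    peak_uM: float = 50.0
    t_peak_h: float = 1.5
    n_decay_steps: int = 12
    target_constant_uM: float = 9.3
    cycle_length_h: float = 24.0
    n_cycles: int = 3
    q_total_ul_min: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("pk", "constant", "vehicle"):
            raise ValueError("mode must be pk, constant or vehicle")


@dataclass(frozen=True)
class AnalysisConfig:
    nucleus_diameter_um: float = 7.0
    neighbor_radius_um: float = 20.0
    region_band_um: float = 35.0
    section_thickness_um: float = 30.0
    rolling_ball_um: float = 50.0
    spacing_min: float = 84.0
    lowess_window: int = 10
    analyze3d_stride: int = 1  # analyse every k-th frame in 3D


@dataclass(frozen=True)
class QCThresholds:
    min_area_um2: float = 1000.0  # below: frame counts as "empty"
    max_empty_fraction: float = 0.10
    max_first_frame: int = 4  # first usable frame must be <= this index


@dataclass(frozen=True)
class RunConfig:
    seed: int | None = None
    out_dir: str = "run"
    target_diameter_um: float = 225.0
    nucleus_radius_um: float = 3.5
    pk: PKConfig = field(default_factory=PKConfig)
    pd: PDParams = field(default_factory=PDParams)
    protocol: ImagingProtocol = field(default_factory=ImagingProtocol)
    render: RenderParams = field(default_factory=RenderParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("config has no seed: refusing a nondeterministic run")
        return int(self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["render"]["voxel_size"] = list(self.render.voxel_size)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        render = dict(d.pop("render", {}))
        if "voxel_size" in render:
            render["voxel_size"] = tuple(render["voxel_size"])
        if "depth_attenuation" in render and render["depth_attenuation"] is not None:
            render["depth_attenuation"] = float(render["depth_attenuation"])
        return cls(
            seed=d.get("seed"),
            out_dir=d.get("out_dir", "run"),
            target_diameter_um=d.get("target_diameter_um", 225.0),
            nucleus_radius_um=d.get("nucleus_radius_um", 3.5),
            pk=PKConfig(**d.get("pk", {})),
            pd=PDParams(**d.get("pd", {})),
            protocol=ImagingProtocol(**d.get("protocol", {})),
            render=RenderParams(**render),
            analysis=AnalysisConfig(**d.get("analysis", {})),
            qc=QCThresholds(**d.get("qc", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
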