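"""Experiment configuration: one serializable object drives the whole run.

The defaults reproduce the reference setup: 8 antennas 23 mm apart, five
frequencies 600–1400 MHz, a 120 × 102 × 102 mm ROI at 3 mm (50,225 nodes),
the two-ellipsoid phantom 35 mm in front of the array, and 45 dB measurement
SNR.  YAML and JSON files are interchangeable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .dielectrics import DispersiveMaterial, default_materials
from .errors import ConfigError
from .scenario import SCENARIOS, ArrayGeometry, PhantomSpec, RoiGrid, build_grid

__all__ = ["ExperimentConfig", "default_config", "tiny_config"]


@dataclass
class ExperimentConfig:
    # acquisition
    frequencies: tuple[float, ...] = (600e6, 800e6, 1000e6, 1200e6, 1400e6)
    n_antennas: int = 8
    antenna_spacing_mm: float = 23.0
    antenna_polarization: str = "y"  # "x" or "y", in the array plane
    phase_center_standoff_mm: float = 15.0
    snr_db: float | None = 45.0
    seed: int = 0
    # ROI grid
    grid_extent_mm: tuple[float, float, float] = (120.0, 102.0, 102.0)
    grid_spacing_mm: float = 3.0
    grid_origin_mm: tuple[float, float, float] = (-60.0, -51.0, 2.0)
    # phantom
    phantom_center_mm: tuple[float, float, float] = (0.0, 0.0, 55.0)
    outer_semi_axes_mm: tuple[float, float, float] = (30.0, 20.0, 20.0)
    inner_semi_axes_mm: tuple[float, float, float] = (17.0, 6.5, 6.5)
    shell_thickness_mm: float = 1.5
    scenarios: tuple[str, ...] = SCENARIOS
    # contrast evaluation frequency (the linear model uses one Δx for the band)
    reference_frequency: float = 1000e6
    # forward-data generation
    refinement: int = 2
    consistent_grid: bool = False  # True: inverse-crime mode, data on imaging grid
    # inversion: nu forces the index; differential_noise_db forces the noise
    # level of the selection rule; with both None the pipeline derives the
    # level from the simulated data (s0 scan power vs differential power)
    nu: int | None = None
    differential_noise_db: float | None = None
    noise_db: float = -15.0  # selection level used outside the pipeline
    slope_window: int = 5
    slope_prominence_db: float = 0.5
    detection_threshold: float = 0.5
    # materials: mapping name -> DispersiveMaterial constructor kwargs
    materials: dict[str, Any] | None = None
    # outputs
    output_dir: str | None = None
    cache_dir: str | None = None

    # -- derived builders ------------------------------------------------

    def grid(self) -> RoiGrid:
        return build_grid(self.grid_extent_mm, self.grid_spacing_mm, self.grid_origin_mm)

    def array(self) -> ArrayGeometry:
        if self.antenna_polarization not in ("x", "y"):
            raise ConfigError("antenna_polarization must be 'x' or 'y'")
        pol = (1.0, 0.0, 0.0) if self.antenna_polarization == "x" else (0.0, 1.0, 0.0)
        return ArrayGeometry(self.n_antennas, self.antenna_spacing_mm, polarization=pol)

    def phantom(self) -> PhantomSpec:
        return PhantomSpec(
            tuple(self.outer_semi_axes_mm),
            tuple(self.inner_semi_axes_mm),
            tuple(self.phantom_center_mm),
            self.shell_thickness_mm,
        )

    def materials_lib(self) -> dict[str, DispersiveMaterial]:
        lib = default_materials()
        for name, spec in (self.materials or {}).items():
            if isinstance(spec, DispersiveMaterial):
                lib[name] = spec
            elif isinstance(spec, Mapping):
                lib[name] = DispersiveMaterial(name=name, **dict(spec))
            else:
                raise ConfigError(f"material {name!r}: expected a mapping of parameters")
        return lib

    def background(self) -> DispersiveMaterial:
        return self.materials_lib()["coupling_medium"]

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if self.materials:
            d["materials"] = {
                name: (
                    {k: v for k, v in asdict(m).items() if v is not None and k != "name"}
                    if isinstance(m, DispersiveMaterial)
                    else dict(m)
                )
                for name, m in self.materials.items()
            }
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in (
            "frequencies",
            "scenarios",
            "grid_extent_mm",
            "grid_origin_mm",
            "phantom_center_mm",
            "outer_semi_axes_mm",
            "inner_semi_axes_mm",
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def kernel_hash(self) -> str:
        """Hash of the kernel-relevant configuration (geometry + background).

        Scenario, noise and inversion settings deliberately do not enter, so
        the SVD cache survives scenario changes.
        """
        lib = self.materials_lib()
        bg = lib["coupling_medium"]
        payload = {
            "frequencies": list(self.frequencies),
            "n_antennas": self.n_antennas,
            "antenna_spacing_mm": self.antenna_spacing_mm,
            "antenna_polarization": self.antenna_polarization,
            "phase_center_standoff_mm": self.phase_center_standoff_mm,
            "grid_extent_mm": list(self.grid_extent_mm),
            "grid_spacing_mm": self.grid_spacing_mm,
            "grid_origin_mm": list(self.grid_origin_mm),
            "background": [bg.model, bg.eps_r, bg.sigma, _plain(bg.table)],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def with_overrides(self, **kwargs) -> "ExperimentConfig":
        return replace(self, **kwargs)


def _plain(obj):
    """Recursively convert numpy/tuples into plain YAML-safe types."""
    import numpy as np

    if isinstance(obj, Mapping):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def default_config() -> ExperimentConfig:
    """The full reference setup (paper scale)."""
    return ExperimentConfig()


def tiny_config() -> ExperimentConfig:
    """A seconds-fast configuration for tests and smoke runs.

    4 antennas, 2 frequencies, an 11 × 9 × 9 node grid and a two-region
    spherical phantom; kernel shape (32, 891).
    """
    return ExperimentConfig(
        frequencies=(800e6, 1200e6),
        n_antennas=4,
        grid_extent_mm=(30.0, 24.0, 24.0),
        grid_origin_mm=(-15.0, -12.0, 2.0),
        phantom_center_mm=(0.0, 0.0, 14.0),
        outer_semi_axes_mm=(8.0, 8.0, 8.0),
        inner_semi_axes_mm=(4.0, 4.0, 4.0),
        refinement=1,
        consistent_grid=True,
    )
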