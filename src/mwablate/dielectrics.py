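"""Frequency-dependent dielectric models for every material in the setup.

The imaging tank contains a lossy coupling medium (εr = 23, σ = 0.07 S/m),
tissue-mimicking materials for liver, coagulation necrosis and carbonized
tissue, and the ABS plastic of 3D-printed phantom shells.  Each material is a
:class:`DispersiveMaterial` evaluated at a frequency to a complex equivalent
permittivity

    ε_eq(ω) = ε_r(ω)·ε0 − j·σ(ω)/ω        [F/m]

under the engineering e^{+jωt} time convention, so passive media always have
Im(ε_eq) ≤ 0.

Supported dispersion models:

``constant``
    frequency-independent (ε_r, σ).
``debye``
    single-pole Debye relaxation, parameters ``eps_inf``, ``delta_eps``,
    ``tau_s`` and optional static conductivity ``sigma_s``.
``cole_cole``
    single-pole Cole-Cole, same parameters plus the broadening exponent
    ``alpha`` in [0, 1).
``table``
    measured (frequency, ε_r, σ) rows, linearly interpolated; evaluation
    outside the tabulated range is an error, never an extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.constants import c as C0, epsilon_0 as EPS0

from .errors import ConfigError, FrequencyRangeError

__all__ = [
    "DispersiveMaterial",
    "ComplexPermittivity",
    "evaluate_permittivity",
    "wavelength_in_medium",
    "default_materials",
]

_MODELS = ("constant", "debye", "cole_cole", "table")


@dataclass(frozen=True)
class ComplexPermittivity:
    """Complex equivalent permittivity at a single frequency.

    ``value`` is ε_eq = ε_r·ε0 − j·σ/ω in F/m under the fixed e^{+jωt}
    convention, so ``value.real > 0`` and ``value.imag <= 0`` for any passive
    medium.
    """

    value: complex
    frequency: float
    convention: str = "+jwt"

    @property
    def eps_r(self) -> float:
        """Real relative permittivity."""
        return self.value.real / EPS0

    @property
    def sigma(self) -> float:
        """Equivalent conductivity in S/m."""
        return -self.value.imag * (2.0 * math.pi * self.frequency)


@dataclass(eq=False)
class DispersiveMaterial:
    """A named material with one of the supported dispersion models."""

    name: str
    model: str = "constant"
    eps_r: float | None = None
    sigma: float | None = None
    model_params: Mapping[str, float] = field(default_factory=dict)
    table: Sequence[Sequence[float]] | None = None

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ConfigError(
                f"unknown dispersion model {self.model!r} for material {self.name!r};"
                f" expected one of {_MODELS}"
            )
        if self.model == "constant":
            if self.eps_r is None or self.sigma is None:
                raise ConfigError(f"constant material {self.name!r} needs eps_r and sigma")
        if self.model in ("debye", "cole_cole"):
            for key in ("eps_inf", "delta_eps", "tau_s"):
                if key not in self.model_params:
                    raise ConfigError(f"{self.model} material {self.name!r} missing {key!r}")
        if self.model == "table":
            tab = np.asarray(self.table, dtype=float)
            if tab.ndim != 2 or tab.shape[1] != 3 or tab.shape[0] < 2:
                raise ConfigError(
                    f"table material {self.name!r} needs >= 2 rows of (f_hz, eps_r, sigma)"
                )
            if not np.all(np.diff(tab[:, 0]) > 0):
                raise ConfigError(f"table frequencies for {self.name!r} must strictly increase")
            self.table = tab

    # -- evaluation ------------------------------------------------------

    def properties_at(self, frequency: float) -> tuple[float, float]:
        """(ε_r, σ) at ``frequency`` in Hz."""
        if frequency <= 0:
            raise ConfigError("frequency must be positive")
        omega = 2.0 * math.pi * frequency
        if self.model == "constant":
            eps_r, sigma = float(self.eps_r), float(self.sigma)
        elif self.model == "table":
            tab = self.table
            if frequency < tab[0, 0] or frequency > tab[-1, 0]:
                raise FrequencyRangeError(
                    f"{self.name!r}: {frequency:.6g} Hz outside tabulated range "
                    f"[{tab[0, 0]:.6g}, {tab[-1, 0]:.6g}] Hz"
                )
            eps_r = float(np.interp(frequency, tab[:, 0], tab[:, 1]))
            sigma = float(np.interp(frequency, tab[:, 0], tab[:, 2]))
        else:
            p = self.model_params
            jwt = 1j * omega * p["tau_s"]
            if self.model == "cole_cole":
                jwt = jwt ** (1.0 - p.get("alpha", 0.0))
            eps_c = p["eps_inf"] + p["delta_eps"] / (1.0 + jwt)
            eps_r = float(eps_c.real)
            sigma = float(p.get("sigma_s", 0.0) - eps_c.imag * omega * EPS0)
        if eps_r < 1.0 - 1e-9 or sigma < 0.0:
            raise ConfigError(
                f"{self.name!r} evaluates to non-physical (eps_r={eps_r:.4g}, "
                f"sigma={sigma:.4g}) at {frequency:.4g} Hz"
            )
        return eps_r, sigma

    def complex_permittivity(self, frequency: float) -> ComplexPermittivity:
        eps_r, sigma = self.properties_at(frequency)
        omega = 2.0 * math.pi * frequency
        return ComplexPermittivity(eps_r * EPS0 - 1j * sigma / omega, frequency)

    def relative_complex_permittivity(self, frequency: float) -> complex:
        """Dimensionless ε_r − j·σ/(ω ε0)."""
        return self.complex_permittivity(frequency).value / EPS0


def evaluate_permittivity(material: DispersiveMaterial, frequency: float) -> ComplexPermittivity:
    """Complex equivalent permittivity ε_eq = ε_r ε0 − jσ/ω of ``material``."""
    return material.complex_permittivity(frequency)


def wavelength_in_medium(material: DispersiveMaterial, frequency: float) -> float:
    """Wavelength λ = c0 / (f · Re√(ε_r − jσ/(ωε0))) in metres.

    For a low-loss medium this reduces to the familiar c0/(f√εr); the small
    conductivity of the coupling medium shifts the value only in the fourth
    significant digit.
    """
    n = np.sqrt(material.relative_complex_permittivity(frequency))
    return C0 / (frequency * float(n.real))


def default_materials() -> dict[str, DispersiveMaterial]:
    """The material library of the default setup.

    Coupling medium, carbonized tissue and ABS come straight from the setup
    description.  Liver and coagulation-necrosis dispersion are editable
    placeholder tables (measured values are only cited, not printed, in the
    study this emulates): both fall with frequency across 600-1400 MHz, with
    necrosis a few units below liver, which is the qualitative behaviour that
    matters for differential imaging.  Nothing quantitative downstream depends
    on these exact numbers.
    """
    return {
        "coupling_medium": DispersiveMaterial("coupling_medium", "constant", eps_r=23.0, sigma=0.07),
        "liver": DispersiveMaterial(
            "liver",
            "table",
            table=[(600e6, 50.0, 0.65), (1400e6, 46.0, 1.0)],
        ),
        "necrosis": DispersiveMaterial(
            "necrosis",
            "table",
            table=[(600e6, 42.0, 0.55), (1400e6, 38.0, 0.85)],
        ),
        "carbonized": DispersiveMaterial("carbonized", "constant", eps_r=8.33, sigma=0.39),
        "abs": DispersiveMaterial("abs", "constant", eps_r=3.0, sigma=4e-3),
    }
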