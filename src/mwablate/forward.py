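"""Synthetic multistatic scattering data.

This module stands in for a full-wave solver: each antenna is modelled as an
elementary electric dipole radiating in the homogeneous lossy coupling
medium, polarized in the antenna-board plane (y by default) and placed at the
element's phase centre — a configurable standoff behind the physical tip
(default 15 mm), because the phase centre of an end-fire traveling-wave
radiator lies inside the taper, and a point source directly at the tip would
make the reactive 1/r³ terms dominate the nearest ROI voxels in a way the
extended aperture it stands in for does not.  The incident field uses the
full near+far dyadic Green's function terms (1/r, 1/r², 1/r³) with complex
wavenumber k = ω√(μ0 ε_eq), branch Im(k) < 0 so fields decay with distance
under e^{+jωt}.

Differential scattered data follow the linearized (Born/distorted-Born)
scattering integral — `born_forward` is the kernel-times-contrast product on
the imaging grid, while `fine_grid_forward` evaluates the same integral on a
refined discretization to avoid the inverse crime when generating "measured"
data.  Antenna crosstalk is not modelled, so the empty-tank reference s0 has
identically zero scattering matrices; all imaging operates on differential
data, where the informative signal lives.

Data-vector ordering is fixed package-wide: frequency-major, then transmitter
p, then receiver q (row-major on each 8×8 matrix), giving the
5 · 8 · 8 = 320-element vector of the default configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import h5py
import numpy as np
from scipy.constants import mu_0 as MU0

from .dielectrics import DispersiveMaterial
from .errors import CalibrationError, ConfigError, ContractError, GeometryError
from .scenario import ArrayGeometry, ContrastImage, PhantomSpec, RoiGrid, ground_truth_contrast

__all__ = [
    "DEFAULT_STANDOFF_MM",
    "NoiseSpec",
    "ScatteringDataset",
    "IncidentFieldSet",
    "complex_wavenumber",
    "incident_field",
    "compute_incident_fields",
    "born_forward",
    "fine_grid_forward",
    "add_noise",
    "empirical_snr_db",
    "differential_data",
    "vector_to_matrices",
    "matrices_to_vector",
    "write_touchstone",
    "read_touchstone",
    "save_fields",
    "load_fields",
]

DEFAULT_FREQUENCIES = (600e6, 800e6, 1000e6, 1200e6, 1400e6)

#: default distance (mm) of the equivalent dipole behind the antenna tip
DEFAULT_STANDOFF_MM = 15.0


def _source_positions_m(array: ArrayGeometry, standoff_mm: float) -> np.ndarray:
    """Dipole positions: antenna tips shifted ``standoff_mm`` against boresight."""
    tips = array.tip_positions_mm - standoff_mm * np.asarray(array.boresight, float)
    return tips * 1e-3


@dataclass(frozen=True)
class NoiseSpec:
    """Additive circular complex Gaussian noise calibrated to an SNR.

    ``snr_db=None`` disables noise.  With ``per_frequency=True`` (default) the
    noise power is calibrated against the signal power of each frequency's
    S-matrix separately, emulating a VNA whose noise floor tracks the band.
    """

    snr_db: float | None = 45.0
    seed: int | None = None
    per_frequency: bool = True


@dataclass
class ScatteringDataset:
    """Per-frequency multistatic S-matrices for one scenario."""

    frequencies: np.ndarray
    s_matrices: np.ndarray  # (n_freq, n_ant, n_ant) complex
    scenario: str = ""
    noise_meta: NoiseSpec | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.s_matrices = np.asarray(self.s_matrices, dtype=complex)
        nf = self.frequencies.size
        if self.s_matrices.ndim != 3 or self.s_matrices.shape[0] != nf:
            raise ContractError("s_matrices must be (n_freq, n_ant, n_ant)")
        if self.s_matrices.shape[1] != self.s_matrices.shape[2]:
            raise ContractError("S-matrices must be square")

    @property
    def n_antennas(self) -> int:
        return self.s_matrices.shape[1]

    def as_vector(self) -> np.ndarray:
        return matrices_to_vector(self.s_matrices)


@dataclass
class IncidentFieldSet:
    """Incident fields E_i(r_n, p, f) on a grid: array (n_ant, n_freq, n_nodes, 3)."""

    fields: np.ndarray
    frequencies: np.ndarray
    grid: RoiGrid
    array: ArrayGeometry
    background: DispersiveMaterial

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=complex)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        expected = (
            self.array.n_antennas,
            self.frequencies.size,
            self.grid.n_nodes,
            3,
        )
        if self.fields.shape != expected:
            raise ContractError(f"fields shape {self.fields.shape} != {expected}")
        if not np.all(np.isfinite(self.fields)):
            raise GeometryError("incident fields contain non-finite values")


def complex_wavenumber(background: DispersiveMaterial, frequency: float) -> complex:
    """k = ω√(μ0 ε_eq) with the decaying branch Im(k) <= 0."""
    omega = 2.0 * math.pi * frequency
    k = omega * np.sqrt(MU0 * background.complex_permittivity(frequency).value)
    return complex(k) if k.imag <= 0 else complex(-k)


def _dipole_field(
    points_m: np.ndarray,
    source_m: np.ndarray,
    polarization: np.ndarray,
    k: complex,
    eps_eq: complex,
    min_distance_m: float,
) -> np.ndarray:
    """Field of a unit elementary electric dipole at ``source_m``.

    E = e^{−jkr}/(4π ε_eq) · [ k² (p̂ − n̂(n̂·p̂))/r + (3n̂(n̂·p̂) − p̂)(1/r³ + jk/r²) ]
    """
    rel = points_m - source_m
    r = np.linalg.norm(rel, axis=1)
    if np.any(r < min_distance_m):
        raise GeometryError(
            f"{np.count_nonzero(r < min_distance_m)} grid node(s) within "
            f"{min_distance_m * 1e3:.2f} mm of a source point"
        )
    n = rel / r[:, None]
    ndotp = n @ polarization
    transverse = polarization[None, :] - n * ndotp[:, None]
    longitudinal = 3.0 * n * ndotp[:, None] - polarization[None, :]
    radial = (1.0 / r**3 + 1j * k / r**2)[:, None]
    phase = np.exp(-1j * k * r)[:, None] / (4.0 * math.pi * eps_eq)
    return phase * (k**2 * transverse / r[:, None] + longitudinal * radial)


def incident_field(
    array: ArrayGeometry,
    antenna: int,
    grid: RoiGrid,
    background: DispersiveMaterial,
    frequency: float,
    min_source_distance_mm: float = 1.5,
    standoff_mm: float = DEFAULT_STANDOFF_MM,
) -> np.ndarray:
    """(n_nodes, 3) complex incident field of one antenna at one frequency."""
    eps_eq = background.complex_permittivity(frequency).value
    k = complex_wavenumber(background, frequency)
    return _dipole_field(
        grid.coords() * 1e-3,
        _source_positions_m(array, standoff_mm)[antenna],
        np.asarray(array.polarization, float),
        k,
        eps_eq,
        min_source_distance_mm * 1e-3,
    )


def compute_incident_fields(
    array: ArrayGeometry,
    grid: RoiGrid,
    background: DispersiveMaterial,
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES,
    min_source_distance_mm: float = 1.5,
    standoff_mm: float = DEFAULT_STANDOFF_MM,
) -> IncidentFieldSet:
    """Incident fields of every antenna at every frequency on the grid."""
    pts = grid.coords() * 1e-3
    pol = np.asarray(array.polarization, float)
    tips = _source_positions_m(array, standoff_mm)
    out = np.empty((array.n_antennas, len(frequencies), grid.n_nodes, 3), dtype=complex)
    for fi, f in enumerate(frequencies):
        eps_eq = background.complex_permittivity(f).value
        k = complex_wavenumber(background, f)
        for p in range(array.n_antennas):
            out[p, fi] = _dipole_field(pts, tips[p], pol, k, eps_eq, min_source_distance_mm * 1e-3)
    return IncidentFieldSet(out, np.asarray(frequencies, float), grid, array, background)


# -- data-vector ordering ------------------------------------------------


def matrices_to_vector(s_matrices: np.ndarray) -> np.ndarray:
    """(n_freq, A, A) -> (n_freq·A², ) frequency-major, p-major then q."""
    s = np.asarray(s_matrices)
    return s.reshape(-1)


def vector_to_matrices(vector: np.ndarray, n_freq: int, n_antennas: int) -> np.ndarray:
    v = np.asarray(vector)
    if v.size != n_freq * n_antennas**2:
        raise ContractError(
            f"vector length {v.size} != n_freq·n_ant² = {n_freq * n_antennas**2}"
        )
    return v.reshape(n_freq, n_antennas, n_antennas)


# -- linearized forward --------------------------------------------------


def born_forward(kernel, contrast: ContrastImage) -> np.ndarray:
    """ΔS = K Δx — the linearized scattering data of a contrast."""
    if contrast.values.size != kernel.matrix.shape[1]:
        raise ContractError(
            f"contrast length {contrast.values.size} != kernel columns "
            f"{kernel.matrix.shape[1]}"
        )
    if contrast.grid is not None and contrast.grid != kernel.grid:
        raise ContractError("contrast and kernel are on different grids")
    return kernel.matrix @ contrast.values


def fine_grid_forward(
    scenario_pair: tuple[str, str],
    array: ArrayGeometry,
    background: DispersiveMaterial,
    frequencies: Sequence[float],
    grid: RoiGrid,
    refinement: int = 2,
    reference_frequency: float | None = None,
    materials=None,
    phantom: PhantomSpec | None = None,
    max_nodes: int = 5_000_000,
    min_source_distance_mm: float = 1.5,
    standoff_mm: float = DEFAULT_STANDOFF_MM,
) -> np.ndarray:
    """Born data of a scenario pair on a ``refinement``-times finer grid.

    Generating "measured" data on an independent, finer discretization than
    the imaging kernel mitigates the inverse crime.  ``refinement=1``
    reproduces the coarse-grid product of :func:`born_forward` (up to
    floating-point summation order).  The field evaluation is restricted to
    the contrast support, so the cost scales with the phantom, not the ROI.
    """
    fine = grid.refined(refinement)
    if fine.n_nodes > max_nodes:
        raise ConfigError(
            f"refined grid has {fine.n_nodes} nodes, above the cap {max_nodes}"
        )
    if reference_frequency is None:
        reference_frequency = float(np.median(np.asarray(frequencies, float)))
    gt = ground_truth_contrast(scenario_pair, fine, reference_frequency, materials, phantom)
    support = gt.support
    n_ant = array.n_antennas
    data = np.zeros(len(frequencies) * n_ant**2, dtype=complex)
    if support.size == 0:
        return data
    pts = fine.coords()[support] * 1e-3
    dx = gt.values[support]
    pol = np.asarray(array.polarization, float)
    tips = _source_positions_m(array, standoff_mm)
    dv = (fine.spacing * 1e-3) ** 3
    for fi, f in enumerate(frequencies):
        eps_eq = background.complex_permittivity(f).value
        k = complex_wavenumber(background, f)
        omega = 2.0 * math.pi * f
        E = np.stack(
            [_dipole_field(pts, tips[p], pol, k, eps_eq, min_source_distance_mm * 1e-3)
             for p in range(n_ant)]
        )
        coeff = -1j * dv / (4.0 * omega * eps_eq)
        s = coeff * np.einsum("ank,bnk->ab", E, E * dx[None, :, None])
        data[fi * n_ant**2 : (fi + 1) * n_ant**2] = s.reshape(-1)
    return data


# -- noise ---------------------------------------------------------------


def add_noise(
    data: "ScatteringDataset | np.ndarray",
    spec: NoiseSpec,
    reference_power: np.ndarray | float | None = None,
) -> "ScatteringDataset | np.ndarray":
    """Additive i.i.d. circular complex Gaussian noise at the specified SNR.

    Per calibration scope (each frequency's S-matrix by default), the noise
    power per complex entry is ``P_sig · 10^(−snr_db/10)`` where ``P_sig`` is
    the mean |S|² per entry.  ``reference_power`` (per-entry power, scalar or
    per-frequency array) overrides the signal's own power — needed to noise
    the all-zero reference scenario at the floor set by the phantom scans.
    Identical spec + seed reproduces the realization bit for bit.
    """
    if spec.snr_db is None or np.isinf(spec.snr_db):
        if isinstance(data, ScatteringDataset):
            return replace(data, noise_meta=spec)
        return np.array(data, copy=True)
    rng = np.random.default_rng(spec.seed)
    factor = 10.0 ** (-spec.snr_db / 10.0)

    def _noise(shape, power_per_entry):
        if power_per_entry <= 0:
            raise CalibrationError("cannot calibrate noise to a zero-power signal")
        std = math.sqrt(power_per_entry * factor / 2.0)
        return std * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))

    if isinstance(data, ScatteringDataset):
        s = data.s_matrices.copy()
        nf = data.frequencies.size
        if spec.per_frequency:
            ref = np.broadcast_to(
                np.mean(np.abs(s) ** 2, axis=(1, 2)) if reference_power is None
                else np.asarray(reference_power, float),
                (nf,),
            )
            for fi in range(nf):
                s[fi] += _noise(s[fi].shape, float(ref[fi]))
        else:
            power = float(np.mean(np.abs(s) ** 2)) if reference_power is None else float(
                np.mean(reference_power)
            )
            s += _noise(s.shape, power)
        return ScatteringDataset(data.frequencies, s, data.scenario, noise_meta=spec)

    vec = np.asarray(data, dtype=complex)
    power = float(np.mean(np.abs(vec) ** 2)) if reference_power is None else float(
        np.mean(reference_power)
    )
    return vec + _noise(vec.shape, power)


def empirical_snr_db(clean: ScatteringDataset, noisy: ScatteringDataset) -> float:
    """10·log10 of total signal power over total realized noise power."""
    sig = np.sum(np.abs(clean.s_matrices) ** 2)
    noise = np.sum(np.abs(noisy.s_matrices - clean.s_matrices) ** 2)
    if noise == 0:
        return math.inf
    return float(10.0 * np.log10(sig / noise))


def differential_data(meas: ScatteringDataset, ref: ScatteringDataset) -> np.ndarray:
    """Entrywise S(meas) − S(ref), reshaped to the package data-vector order."""
    if meas.frequencies.size != ref.frequencies.size or not np.allclose(
        meas.frequencies, ref.frequencies
    ):
        raise ContractError("datasets have different frequency lists")
    if meas.n_antennas != ref.n_antennas:
        raise ContractError("datasets have different array sizes")
    return matrices_to_vector(meas.s_matrices - ref.s_matrices)


# -- I/O -----------------------------------------------------------------


def write_touchstone(path, dataset: ScatteringDataset, z0: float = 50.0) -> None:
    """Write an n-port Touchstone file (.s8p for 8 ports; RI format, Hz).

    Each frequency block lists the S-matrix row-major as real/imag pairs, four
    pairs per line.
    """
    s = dataset.s_matrices
    n = dataset.n_antennas
    with open(path, "w") as fh:
        fh.write(f"! mwablate synthetic scattering data, scenario {dataset.scenario or '?'}\n")
        fh.write(f"! {n} ports, {dataset.frequencies.size} frequencies\n")
        fh.write(f"# Hz S RI R {z0:g}\n")
        for fi, f in enumerate(dataset.frequencies):
            pairs = [f"{f:.10g}"]
            flat = s[fi].reshape(-1)
            for v in flat:
                pairs.append(f"{v.real:.12e} {v.imag:.12e}")
            # first line carries the frequency + 4 pairs, then 4 pairs per line
            line, chunks = [pairs[0]], pairs[1:]
            for i, c in enumerate(chunks):
                line.append(c)
                if (i + 1) % 4 == 0:
                    fh.write(" ".join(line) + "\n")
                    line = []
            if line:
                fh.write(" ".join(line) + "\n")


def read_touchstone(path, n_ports: int | None = None, scenario: str = "") -> ScatteringDataset:
    """Read a Touchstone file written by :func:`write_touchstone`.

    ``n_ports`` defaults to the number in the ``.sNp`` extension.
    """
    path = str(path)
    if n_ports is None:
        import re

        m = re.search(r"\.s(\d+)p$", path.lower())
        if not m:
            raise ConfigError(f"cannot infer port count from {path!r}")
        n_ports = int(m.group(1))
    unit_scale = 1.0
    values: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#"):
                tokens = line[1:].split()
                unit = tokens[0].lower() if tokens else "ghz"
                unit_scale = {"hz": 1.0, "khz": 1e3, "mhz": 1e6, "ghz": 1e9}[unit]
                if "ri" not in [t.lower() for t in tokens]:
                    raise ConfigError("only RI-format Touchstone files are supported")
                continue
            values.extend(float(t) for t in line.split())
    block = 1 + 2 * n_ports**2
    if len(values) % block:
        raise ConfigError(f"corrupt Touchstone file {path!r}")
    arr = np.asarray(values).reshape(-1, block)
    freqs = arr[:, 0] * unit_scale
    s = (arr[:, 1::2] + 1j * arr[:, 2::2]).reshape(-1, n_ports, n_ports)
    return ScatteringDataset(freqs, s, scenario=scenario)


def save_fields(path, field_set: IncidentFieldSet) -> None:
    """HDF5 field container: /fields (n_ant, n_freq, nx, ny, nz, 3) + grid attrs."""
    g = field_set.grid
    # node axis is x-fastest; C-order reshape therefore yields (z, y, x)
    shaped = field_set.fields.reshape(
        field_set.array.n_antennas, field_set.frequencies.size, g.shape[2], g.shape[1], g.shape[0], 3
    ).transpose(0, 1, 4, 3, 2, 5)
    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("fields", data=shaped)
        d.attrs["axis_order"] = "antenna, frequency, x, y, z, component"
        fh.attrs["frequencies_hz"] = field_set.frequencies
        fh.attrs["grid_origin_mm"] = np.asarray(g.origin)
        fh.attrs["grid_spacing_mm"] = g.spacing
        fh.attrs["grid_shape"] = np.asarray(g.shape)
        fh.attrs["n_antennas"] = field_set.array.n_antennas
        fh.attrs["antenna_spacing_mm"] = field_set.array.spacing_mm


def load_fields(path, array: ArrayGeometry, background: DispersiveMaterial) -> IncidentFieldSet:
    """Read a field container produced by :func:`save_fields` (or externally)."""
    with h5py.File(path, "r") as fh:
        shaped = fh["fields"][()]
        freqs = np.asarray(fh.attrs["frequencies_hz"], float)
        grid = RoiGrid(
            tuple(float(v) for v in fh.attrs["grid_origin_mm"]),
            float(fh.attrs["grid_spacing_mm"]),
            tuple(int(v) for v in fh.attrs["grid_shape"]),
        )
    n_ant, n_freq = shaped.shape[0], shaped.shape[1]
    flat = shaped.transpose(0, 1, 4, 3, 2, 5).reshape(n_ant, n_freq, grid.n_nodes, 3)
    return IncidentFieldSet(flat, freqs, grid, array, background)
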