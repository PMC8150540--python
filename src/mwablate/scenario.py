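"""Setup geometry and ground-truth contrast maps.

Coordinate convention: right-handed, x along the antenna array, z along the
array boresight (from the antennas into the tank), origin at the central point
of the antenna tips.  All geometry is in millimetres, frequencies in Hz.

The region of interest (ROI) is a lattice of nodes spanning its extent
inclusively; the default 120 x 102 x 102 mm box at 3 mm spacing gives
41 x 35 x 35 = 50,225 nodes.  Linear node index is x-fastest:
``idx = i + nx*(j + ny*k)``.

The ablation phantom is two nested ellipsoids.  Filling them with different
tissue-mimicking materials yields the treatment stages:

==== =============== ================
stage outer ellipsoid inner ellipsoid
==== =============== ================
 a    liver           liver            (pre-treatment)
 b    liver           necrosis         (ongoing ablation)
 c    necrosis        carbonized       (completed treatment)
==== =============== ================

Scenario labels: ``s0`` (empty tank), ``a1/b1/c1`` (shell-free phantoms) and
``a2/b2/c2`` (with 1.5 mm ABS shells just outside each ellipsoid surface, as
in the 3D-printed realization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dielectrics import DispersiveMaterial, default_materials, wavelength_in_medium
from .errors import ConfigError, ContractError

__all__ = [
    "RoiGrid",
    "ArrayGeometry",
    "PhantomSpec",
    "ContrastImage",
    "SCENARIOS",
    "LABEL_CODES",
    "LABEL_NAMES",
    "build_grid",
    "material_map",
    "ground_truth_contrast",
    "enumerate_pairs",
]

SCENARIOS = ("s0", "a1", "a2", "b1", "b2", "c1", "c2")

#: integer label codes used by :func:`material_map`
LABEL_CODES = {"background": 0, "liver": 1, "necrosis": 2, "carbonized": 3, "abs": 4}
LABEL_NAMES = {v: k for k, v in LABEL_CODES.items()}

#: material filling (outer, inner) ellipsoid per treatment stage
STAGE_FILL = {
    "a": ("liver", "liver"),
    "b": ("liver", "necrosis"),
    "c": ("necrosis", "carbonized"),
}

#: which material-library entry realizes each voxel label
LABEL_MATERIAL = {
    "background": "coupling_medium",
    "liver": "liver",
    "necrosis": "necrosis",
    "carbonized": "carbonized",
    "abs": "abs",
}


@dataclass(frozen=True)
class RoiGrid:
    """Node lattice of the region of interest.

    ``origin`` is the physical position (mm) of node (0, 0, 0); nodes sit at
    ``origin + spacing * (i, j, k)``.
    """

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical span (mm) covered by the lattice along each axis."""
        return tuple(self.spacing * (n - 1) for n in self.shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing**3

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)
        )

    def coords(self) -> np.ndarray:
        """(n_nodes, 3) node positions in mm, x-fastest linear ordering."""
        x, y, z = self.axes()
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        return np.column_stack(
            [X.ravel(order="F"), Y.ravel(order="F"), Z.ravel(order="F")]
        )

    def linear_index(self, i: int, j: int, k: int) -> int:
        nx, ny, _ = self.shape
        return i + nx * (j + ny * k)

    def multi_index(self, idx: int) -> tuple[int, int, int]:
        nx, ny, _ = self.shape
        i = idx % nx
        j = (idx // nx) % ny
        k = idx // (nx * ny)
        return i, j, k

    def to_volume(self, values: np.ndarray) -> np.ndarray:
        """Reshape an x-fastest node vector to a (nx, ny, nz) volume."""
        return np.asarray(values).reshape(self.shape, order="F")

    def refined(self, factor: int) -> "RoiGrid":
        """Same physical extent, ``factor`` times finer spacing."""
        if int(factor) != factor or factor < 1:
            raise ConfigError("refinement factor must be a positive integer")
        factor = int(factor)
        shape = tuple((n - 1) * factor + 1 for n in self.shape)
        return RoiGrid(self.origin, self.spacing / factor, shape)


def build_grid(
    extent_mm: Sequence[float],
    spacing_mm: float,
    origin_mm: Sequence[float] = (-60.0, -51.0, 2.0),
) -> RoiGrid:
    """Node lattice spanning ``extent_mm`` inclusively at ``spacing_mm``.

    Shape per axis is extent/spacing + 1; the extent must be a positive
    multiple of the spacing.
    """
    if spacing_mm <= 0:
        raise ConfigError("grid spacing must be positive")
    shape = []
    for e in extent_mm:
        n = e / spacing_mm
        if e <= 0 or abs(n - round(n)) > 1e-9:
            raise ConfigError(
                f"extent {e} mm is not a positive multiple of spacing {spacing_mm} mm"
            )
        shape.append(int(round(n)) + 1)
    return RoiGrid(tuple(float(o) for o in origin_mm), float(spacing_mm), tuple(shape))


@dataclass(frozen=True)
class ArrayGeometry:
    """A linear multistatic array of antenna tips along x at z = 0.

    Default polarization is y: the antenna boards sit side by side along the
    array axis, so each element's linear polarization lies in the board plane,
    perpendicular to both the array axis and the boresight.
    """

    n_antennas: int = 8
    spacing_mm: float = 23.0
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    polarization: tuple[float, float, float] = (0.0, 1.0, 0.0)
    boresight: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_antennas < 2:
            raise ConfigError("array needs at least two antennas")
        if self.spacing_mm <= 0:
            raise ConfigError("antenna spacing must be positive")
        for name in ("polarization", "boresight"):
            v = np.asarray(getattr(self, name), float)
            if not np.isclose(np.linalg.norm(v), 1.0):
                raise ConfigError(f"{name} must be a unit vector")

    @property
    def tip_positions_mm(self) -> np.ndarray:
        """(n_antennas, 3) tip coordinates in mm, colinear along x."""
        offsets = (np.arange(self.n_antennas) - (self.n_antennas - 1) / 2.0) * self.spacing_mm
        pos = np.zeros((self.n_antennas, 3))
        pos[:, 0] = offsets
        return pos + np.asarray(self.center_mm)

    def check_spacing(self, background: DispersiveMaterial, frequency: float = 1e9) -> float:
        """Require spacing >= λ/4 in the background at ``frequency``.

        Returns λ/4 in mm.
        """
        quarter = wavelength_in_medium(background, frequency) / 4.0 * 1e3
        if self.spacing_mm < quarter:
            raise ConfigError(
                f"antenna spacing {self.spacing_mm} mm < λ/4 = {quarter:.2f} mm "
                f"at {frequency:.3g} Hz in {background.name!r}"
            )
        return quarter


@dataclass(frozen=True)
class PhantomSpec:
    """Two nested ellipsoids (semi-axes in mm) with optional ABS shells."""

    outer_semi_axes_mm: tuple[float, float, float] = (30.0, 20.0, 20.0)
    inner_semi_axes_mm: tuple[float, float, float] = (17.0, 6.5, 6.5)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 55.0)
    shell_thickness_mm: float = 1.5

    def __post_init__(self) -> None:
        inner = np.asarray(self.inner_semi_axes_mm)
        outer = np.asarray(self.outer_semi_axes_mm)
        if np.any(inner <= 0) or np.any(outer <= 0):
            raise ConfigError("semi-axes must be positive")
        if not np.all(inner < outer):
            raise ConfigError("inner ellipsoid must lie strictly inside the outer one")

    @property
    def near_face_z_mm(self) -> float:
        """z of the outer ellipsoid surface closest to the array."""
        return self.center_mm[2] - self.outer_semi_axes_mm[2]

    @property
    def inner_near_face_z_mm(self) -> float:
        return self.center_mm[2] - self.inner_semi_axes_mm[2]


def _ellipsoid_membership(
    points: np.ndarray, center: np.ndarray, semi_axes: np.ndarray, shell: float
) -> tuple[np.ndarray, np.ndarray]:
    """(inside, in_shell) boolean masks for an ellipsoid and its outer shell.

    The shell is the set of points whose radial distance to the surface,
    measured along the ray from the ellipsoid centre, lies in (0, shell] mm.
    """
    rel = points - center
    u = np.sqrt(np.sum((rel / semi_axes) ** 2, axis=1))
    inside = u <= 1.0
    dist = np.linalg.norm(rel, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        radial_gap = np.where(u > 0, dist * (1.0 - 1.0 / np.maximum(u, 1e-300)), -1.0)
    in_shell = (u > 1.0) & (radial_gap <= shell)
    return inside, in_shell


def _parse_label(scenario: str) -> tuple[str | None, bool]:
    """(stage, with_shell) for a scenario label; stage None for s0."""
    if scenario == "s0":
        return None, False
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    return scenario[0], scenario[1] == "2"


def material_map(
    scenario: str,
    grid: RoiGrid,
    phantom: PhantomSpec | None = None,
) -> np.ndarray:
    """Per-node material label codes (see :data:`LABEL_CODES`) for a scenario.

    Membership is a centre-point test per node.  A phantom extending outside
    the ROI is clipped with a warning, not an error.
    """
    stage, with_shell = _parse_label(scenario)
    labels = np.zeros(grid.n_nodes, dtype=np.int8)
    if stage is None:
        return labels
    phantom = phantom or PhantomSpec()

    center = np.asarray(phantom.center_mm)
    outer = np.asarray(phantom.outer_semi_axes_mm)
    reach = outer + (phantom.shell_thickness_mm if with_shell else 0.0)
    lo = np.asarray(grid.origin)
    hi = lo + np.asarray(grid.extent)
    if np.any(center - reach < lo) or np.any(center + reach > hi):
        warnings.warn(
            f"phantom for scenario {scenario!r} extends outside the ROI; clipped",
            stacklevel=2,
        )

    pts = grid.coords()
    outer_mat, inner_mat = STAGE_FILL[stage]
    in_outer, outer_shell = _ellipsoid_membership(
        pts, center, outer, phantom.shell_thickness_mm
    )
    in_inner, inner_shell = _ellipsoid_membership(
        pts, center, np.asarray(phantom.inner_semi_axes_mm), phantom.shell_thickness_mm
    )

    labels[in_outer] = LABEL_CODES[outer_mat]
    if with_shell:
        labels[outer_shell] = LABEL_CODES["abs"]
        labels[inner_shell & in_outer] = LABEL_CODES["abs"]
    labels[in_inner] = LABEL_CODES[inner_mat]
    return labels


@dataclass
class ContrastImage:
    """Complex voxel contrast Δx on a grid, plus its normalized magnitude I."""

    values: np.ndarray
    frequency: float | str
    grid: RoiGrid | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex).ravel()
        if self.grid is not None and self.values.size != self.grid.n_nodes:
            raise ContractError(
                f"contrast length {self.values.size} != grid nodes {self.grid.n_nodes}"
            )

    @property
    def normalized_magnitude(self) -> np.ndarray:
        """I = |Δx| / max|Δx| in [0, 1]; all-zero contrast stays all-zero."""
        mag = np.abs(self.values)
        peak = mag.max(initial=0.0)
        return mag / peak if peak > 0 else mag

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.values)


def ground_truth_contrast(
    scenario_pair: tuple[str, str],
    grid: RoiGrid,
    frequency: float,
    materials: Mapping[str, DispersiveMaterial] | None = None,
    phantom: PhantomSpec | None = None,
) -> ContrastImage:
    """Δx_GT = ε_eq(state 2) − ε_eq(state 1) per node, in F/m.

    ``scenario_pair`` is (state 1, state 2) = (reference, measurement); e.g.
    ("s0", "a1") is the pre-treatment phantom against the empty tank.
    Identical scenarios give a valid all-zero contrast.
    """
    materials = materials or default_materials()
    eps_by_code = np.array(
        [
            materials[LABEL_MATERIAL[LABEL_NAMES[code]]].complex_permittivity(frequency).value
            for code in sorted(LABEL_NAMES)
        ]
    )
    ref, meas = scenario_pair
    lab_ref = material_map(ref, grid, phantom)
    lab_meas = material_map(meas, grid, phantom)
    values = eps_by_code[lab_meas] - eps_by_code[lab_ref]
    return ContrastImage(values, frequency, grid)


def enumerate_pairs(scenarios: Sequence[str] = SCENARIOS) -> list[tuple[str, str]]:
    """The canonical differential data sets as (reference, measurement) pairs.

    With the full scenario list this is the ten pairs aX-s0, bX-s0, cX-s0,
    bX-aX, cX-bX for X in {1, 2}; with a subset, only the pairs whose members
    are both present.
    """
    wanted = [
        ("s0", "a1"), ("s0", "b1"), ("s0", "c1"), ("a1", "b1"), ("b1", "c1"),
        ("s0", "a2"), ("s0", "b2"), ("s0", "c2"), ("a2", "b2"), ("b2", "c2"),
    ]
    avail = set(scenarios)
    return [(r, m) for r, m in wanted if r in avail and m in avail]
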