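"""The imaging core: kernel assembly, SVD, truncation selection, TSVD inversion.

The differential data obey the linear model ΔS = K Δx under the distorted
Born approximation.  Row m of K couples voxel n to the (frequency, transmitter
p, receiver q) combination through the incident fields alone:

    K_mn = −j ΔV / (4 ω_f ε_eqCM) · E_i(r_n, p) · E_i(r_n, q)

with the non-conjugated bilinear dot product (the reciprocity-derived data
equation is bilinear, not sesquilinear) and the voxel volume ΔV of the
discretized integral.  Because images are normalized, ΔV only fixes the
absolute contrast scale.

K is severely ill-conditioned; inversion is by truncated SVD,

    Δx = Σ_{i<=ν} (u_iᴴ ΔS / σ_i) v_i,

where the truncation index ν is the regularization parameter.  Candidate ν
values are the slope changes of the dB singular-value curve; the selected ν is
the largest candidate whose normalized singular value still sits above the
noise level expected on the differential signal (−15 dB by default).

`TSVDImager` packages fit (kernel → SVD) and transform (data vectors →
images) in the scikit-learn estimator idiom, so the imaging step composes
with sklearn tooling; `tsvd_solve` / `ideal_reconstruction` are the
function-style entry points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import h5py
import numpy as np
import scipy.linalg
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, TransformerMixin

from .dielectrics import DispersiveMaterial
from .errors import ConfigError, ContractError, RankError
from .forward import IncidentFieldSet
from .scenario import ContrastImage, RoiGrid

__all__ = [
    "Kernel",
    "SvdFactors",
    "ThresholdSelection",
    "build_kernel",
    "compute_svd",
    "threshold_candidates",
    "tsvd_solve",
    "ideal_reconstruction",
    "TSVDImager",
]


@dataclass
class Kernel:
    """The discretized linear scattering operator and its row bookkeeping."""

    matrix: np.ndarray  # (n_freq·n_ant², n_nodes) complex
    row_index: list[tuple[int, int, int]]  # m -> (freq index, p, q)
    frequencies: np.ndarray
    grid: RoiGrid
    background: DispersiveMaterial

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class SvdFactors:
    """Thin SVD K = U Σ Vᴴ with σ1 >= σ2 >= … >= 0."""

    U: np.ndarray
    s: np.ndarray
    Vh: np.ndarray

    @property
    def rank(self) -> int:
        """Numerical rank: count of σ_i above σ1·1e−12."""
        if self.s.size == 0 or self.s[0] == 0:
            return 0
        return int(np.count_nonzero(self.s > self.s[0] * 1e-12))

    def sigma_db(self) -> np.ndarray:
        """20·log10(σ_i/σ1), clipped at −300 dB for exact zeros."""
        with np.errstate(divide="ignore"):
            return np.maximum(20.0 * np.log10(self.s / self.s[0]), -300.0)


def build_kernel(
    fields: IncidentFieldSet,
    background: DispersiveMaterial | None = None,
) -> Kernel:
    """Assemble K from incident fields on the imaging grid.

    Rows are ordered frequency-major, then transmitter p, then receiver q —
    identical to the data-vector ordering — so rows (f, p, q) and (f, q, p)
    are bitwise equal by commutativity of the bilinear product.
    """
    background = background or fields.background
    grid = fields.grid
    n_ant = fields.array.n_antennas
    n_freq = fields.frequencies.size
    dv = (grid.spacing * 1e-3) ** 3
    matrix = np.empty((n_freq * n_ant**2, grid.n_nodes), dtype=complex)
    row_index: list[tuple[int, int, int]] = []
    for fi, f in enumerate(fields.frequencies):
        omega = 2.0 * math.pi * f
        eps_eq = background.complex_permittivity(f).value
        coeff = -1j * dv / (4.0 * omega * eps_eq)
        E = fields.fields[:, fi]  # (n_ant, n_nodes, 3)
        prod = np.einsum("ank,bnk->abn", E, E)
        matrix[fi * n_ant**2 : (fi + 1) * n_ant**2] = coeff * prod.reshape(
            n_ant**2, grid.n_nodes
        )
        row_index.extend((fi, p, q) for p in range(n_ant) for q in range(n_ant))
    return Kernel(matrix, row_index, fields.frequencies.copy(), grid, background)


def compute_svd(
    kernel: "Kernel | np.ndarray",
    cache_path=None,
    cache_key: str | None = None,
) -> SvdFactors:
    """Thin SVD of the kernel, optionally cached to HDF5.

    The SVD depends only on geometry and background — never on the scenario —
    so one factorization serves every differential data set; this is what
    makes the imaging step itself real-time.  ``cache_path`` + ``cache_key``
    (e.g. a config hash) enable reuse across runs.
    """
    matrix = kernel.matrix if isinstance(kernel, Kernel) else np.asarray(kernel)
    if cache_path is not None:
        try:
            with h5py.File(cache_path, "r") as fh:
                if cache_key is None or fh.attrs.get("config_hash") == cache_key:
                    return SvdFactors(fh["U"][()], fh["sigma"][()], fh["Vh"][()])
        except (FileNotFoundError, OSError, KeyError):
            pass
    try:
        U, s, Vh = scipy.linalg.svd(matrix, full_matrices=False, lapack_driver="gesdd")
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare fallback
        norm = np.linalg.norm(matrix)
        raise RankError(f"SVD failed (matrix norm {norm:.3g}): {exc}") from exc
    factors = SvdFactors(U, s, Vh)
    if cache_path is not None:
        with h5py.File(cache_path, "w") as fh:
            fh.create_dataset("U", data=U)
            fh.create_dataset("sigma", data=s)
            fh.create_dataset("Vh", data=Vh)
            if cache_key is not None:
                fh.attrs["config_hash"] = cache_key
    return factors


@dataclass
class ThresholdSelection:
    """Outcome of the slope-change truncation rule (indices are 1-based ν counts)."""

    candidates: list[int]
    selected: int
    sigma_db: np.ndarray
    used_fallback: bool = False


def threshold_candidates(
    singular_values: Sequence[float],
    noise_db: float = -15.0,
    window: int = 5,
    prominence_db: float = 0.5,
) -> ThresholdSelection:
    """Detect slope changes of the dB singular-value curve and pick ν.

    The local slope left and right of each index is estimated over ``window``
    samples on the 20·log10(σ/σ1) curve; indices where the slope change
    exceeds ``prominence_db`` (dB per index) are candidates.  The selected ν
    is the largest candidate whose normalized singular value is still at or
    above ``noise_db``.  If no candidate survives, the rule falls back to the
    last index above the noise level, with a warning.
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size < 8:
        raise ConfigError("need at least 8 singular values for threshold selection")
    if np.any(np.diff(s) > s[0] * 1e-12):
        raise ConfigError("singular values must be nonincreasing")
    with np.errstate(divide="ignore"):
        sdb = np.maximum(20.0 * np.log10(s / s[0]), -300.0)
    n = s.size
    w = max(2, int(window))
    change = np.zeros(n)
    idx = np.arange(w, n - w)
    if idx.size:
        left = (sdb[idx] - sdb[idx - w]) / w
        right = (sdb[idx + w] - sdb[idx]) / w
        change[idx] = np.abs(right - left)
    peaks, _ = find_peaks(change, height=prominence_db * (1.0 - 1e-12))
    candidates = [int(i) + 1 for i in peaks]  # 1-based retained count
    above = [nu for nu in candidates if sdb[nu - 1] >= noise_db]
    if above:
        return ThresholdSelection(candidates, max(above), sdb)
    fallback = int(np.max(np.nonzero(sdb >= noise_db)[0])) + 1 if np.any(sdb >= noise_db) else 1
    warnings.warn(
        "no slope-change candidate above the noise level; "
        f"falling back to the noise-crossing index ν={fallback}",
        stacklevel=2,
    )
    return ThresholdSelection(candidates, fallback, sdb, used_fallback=True)


def _check_nu(svd: SvdFactors, nu: int) -> int:
    nu = int(nu)
    if nu < 1 or nu > svd.s.size:
        raise RankError(f"ν={nu} outside [1, {svd.s.size}]")
    if svd.s[nu - 1] <= 0:
        raise RankError(f"σ_ν = 0 at ν={nu}; kernel rank is {svd.rank}")
    return nu


def tsvd_solve(
    svd: SvdFactors,
    data: np.ndarray,
    nu: int,
    grid: RoiGrid | None = None,
    frequency: float | str = "band",
) -> ContrastImage:
    """Δx = Σ_{i<=ν} (u_iᴴ ΔS / σ_i) v_i — the regularized inverse image."""
    nu = _check_nu(svd, nu)
    data = np.asarray(data, dtype=complex).ravel()
    if data.size != svd.U.shape[0]:
        raise ContractError(f"data length {data.size} != kernel rows {svd.U.shape[0]}")
    coeffs = (svd.U[:, :nu].conj().T @ data) / svd.s[:nu]
    values = svd.Vh[:nu].conj().T @ coeffs
    return ContrastImage(values, frequency, grid)


def ideal_reconstruction(
    svd: SvdFactors,
    ground_truth: ContrastImage,
    nu: int,
) -> ContrastImage:
    """Δx_ID = V_ν V_νᴴ Δx_GT — the best image the truncated basis can express."""
    nu = _check_nu(svd, nu)
    x = ground_truth.values
    if x.size != svd.Vh.shape[1]:
        raise ContractError(f"ground truth length {x.size} != kernel columns {svd.Vh.shape[1]}")
    coeffs = svd.Vh[:nu] @ x
    values = svd.Vh[:nu].conj().T @ coeffs
    return ContrastImage(values, ground_truth.frequency, ground_truth.grid)


class TSVDImager(BaseEstimator, TransformerMixin):
    """Truncated-SVD linear imager in the scikit-learn estimator idiom.

    Parameters
    ----------
    nu : int or None
        Manual truncation index.  ``None`` selects ν with the slope-change
        rule at ``noise_db``.
    noise_db : float
        Differential noise level (dB, relative to σ1) for the selection rule.
    window, prominence_db : int, float
        Slope-estimation window and minimum slope change (dB per index) of
        the candidate detector.

    Attributes (after ``fit``)
    --------------------------
    U_, singular_values_, Vh_ : the thin SVD of the kernel.
    candidates_ : candidate truncation indices (1-based).
    nu_ : the truncation index actually used by ``transform``.
    """

    def __init__(
        self,
        nu: int | None = None,
        noise_db: float = -15.0,
        window: int = 5,
        prominence_db: float = 0.5,
    ):
        self.nu = nu
        self.noise_db = noise_db
        self.window = window
        self.prominence_db = prominence_db

    def fit(self, K, y=None) -> "TSVDImager":
        """Factorize the kernel (a Kernel object or (M, N) complex array)."""
        self.grid_ = K.grid if isinstance(K, Kernel) else None
        svd = compute_svd(K)
        self.U_, self.singular_values_, self.Vh_ = svd.U, svd.s, svd.Vh
        self.n_features_in_ = self.U_.shape[0]
        if self.nu is not None:
            self.candidates_ = [int(self.nu)]
            self.nu_ = _check_nu(svd, self.nu)
            self.selection_ = None
        else:
            sel = threshold_candidates(
                svd.s, self.noise_db, self.window, self.prominence_db
            )
            self.candidates_ = sel.candidates
            self.nu_ = sel.selected
            self.selection_ = sel
        return self

    def _svd(self) -> SvdFactors:
        return SvdFactors(self.U_, self.singular_values_, self.Vh_)

    def transform(self, dS: np.ndarray) -> np.ndarray:
        """Map differential data vectors (n_samples, M) to images (n_samples, N)."""
        dS = np.atleast_2d(np.asarray(dS, dtype=complex))
        if dS.shape[1] != self.n_features_in_:
            raise ContractError(
                f"data vectors have length {dS.shape[1]}, kernel has {self.n_features_in_} rows"
            )
        svd = self._svd()
        return np.stack([tsvd_solve(svd, row, self.nu_).values for row in dS])

    def project_truth(self, x: np.ndarray) -> np.ndarray:
        """Ideal reconstruction of ground-truth contrast vectors (same shapes)."""
        x = np.atleast_2d(np.asarray(x, dtype=complex))
        svd = self._svd()
        return np.stack(
            [ideal_reconstruction(svd, ContrastImage(row, "band"), self.nu_).values for row in x]
        )
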