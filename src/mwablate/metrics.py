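"""Quantitative evaluation of the imaging experiment.

Signal levels are Frobenius (L2) norms of the 8×8 S-matrices; differential
levels are expressed in dB relative to the reference scan, 20·log10 of the
norm ratio (identically 10·log10 of the energy ratio).  Reconstruction
quality is the normalized mean-square error against the ideal reconstruction,

    NMSE = Σ_voxels |I_ID − I|² / Σ_voxels |I_ID|²,

computed on the normalized magnitudes.  Localization of the ablated region is
summarized from the connected supra-threshold component of the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, ContractError
from .forward import ScatteringDataset, vector_to_matrices
from .scenario import ContrastImage, PhantomSpec, RoiGrid

__all__ = [
    "s_matrix_norm",
    "differential_level_db",
    "average_level_db",
    "differential_noise_level_db",
    "nmse",
    "LocalizationReport",
    "localization_report",
]


def s_matrix_norm(S: np.ndarray) -> float:
    """Frobenius norm sqrt(ΣΣ|S_ij|²) of one S-matrix."""
    S = np.asarray(S)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ContractError("expected a square S-matrix")
    return float(np.linalg.norm(S))


def differential_level_db(
    dS: "np.ndarray | ScatteringDataset",
    s_ref: ScatteringDataset,
) -> np.ndarray:
    """Per-frequency 20·log10(‖ΔS(f)‖ / ‖S_ref(f)‖).

    ``dS`` may be a dataset, a stack of per-frequency matrices, or a data
    vector in the package ordering.
    """
    if isinstance(dS, ScatteringDataset):
        if not np.allclose(dS.frequencies, s_ref.frequencies):
            raise ContractError("frequency lists differ")
        mats = dS.s_matrices
    else:
        dS = np.asarray(dS)
        mats = (
            dS
            if dS.ndim == 3
            else vector_to_matrices(dS, s_ref.frequencies.size, s_ref.n_antennas)
        )
    out = np.empty(s_ref.frequencies.size)
    for fi in range(out.size):
        ref = s_matrix_norm(s_ref.s_matrices[fi])
        if ref == 0:
            raise ConfigError("reference S-matrix has zero norm; level undefined")
        out[fi] = 20.0 * np.log10(s_matrix_norm(mats[fi]) / ref)
    return out


def average_level_db(levels_db: np.ndarray) -> float:
    """Average of per-frequency dB levels, taken in linear power."""
    levels_db = np.asarray(levels_db, dtype=float)
    return float(10.0 * np.log10(np.mean(10.0 ** (levels_db / 10.0))))


def differential_noise_level_db(snr_db: float, mean_differential_db: float) -> float:
    """Noise level relative to the differential signal, in dB.

    Measurement noise sits ``snr_db`` below the total signal while the
    differential signal sits ``mean_differential_db`` relative to it, so the
    noise-to-differential level is ``−snr_db − mean_differential_db`` — e.g.
    45 dB SNR with a −30 dB average differential level gives −15 dB.
    """
    return -snr_db - mean_differential_db


def nmse(I: np.ndarray, I_ID: np.ndarray, renormalize: bool = True) -> float:
    """Σ|I_ID − I|² / Σ|I_ID|² on normalized magnitude images.

    Both inputs are defensively re-normalized to peak 1 by default; pass
    ``renormalize=False`` to take the arrays as given.
    """
    I = np.abs(np.asarray(I, dtype=float)).ravel()
    I_ID = np.abs(np.asarray(I_ID, dtype=float)).ravel()
    if I.shape != I_ID.shape:
        raise ContractError("images have different sizes")
    if not np.any(I_ID):
        raise ConfigError("ideal image is identically zero; NMSE undefined")
    if renormalize:
        I = I / I.max() if I.max() > 0 else I
        I_ID = I_ID / I_ID.max()
    return float(np.sum((I_ID - I) ** 2) / np.sum(I_ID**2))


@dataclass
class LocalizationReport:
    """Geometry of the largest connected supra-threshold region of an image."""

    detected: bool
    threshold: float
    n_voxels: int = 0
    bbox_mm: tuple[tuple[float, float], ...] | None = None
    extent_mm: tuple[float, float, float] | None = None
    centroid_mm: tuple[float, float, float] | None = None
    near_face_z_mm: float | None = None
    z_bias_mm: float | None = None  # negative = toward the array


def localization_report(
    image: "ContrastImage | np.ndarray",
    grid: RoiGrid | None = None,
    phantom: PhantomSpec | None = None,
    threshold: float = 0.5,
    region: str = "outer",
) -> LocalizationReport:
    """Bounding box / centroid / near-face bias of the detected region.

    The image is thresholded at ``threshold`` (fraction of its peak), the
    largest 6-connected component is kept, and its z-near face is compared to
    the phantom's near face (``region`` selects the outer or inner ellipsoid).
    A z bias below zero means the target appears closer to the array than it
    really is.  An empty supra-threshold set reports ``detected=False``.
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigError("threshold must be in (0, 1)")
    if isinstance(image, ContrastImage):
        grid = grid or image.grid
        values = image.normalized_magnitude
    else:
        values = np.abs(np.asarray(image, dtype=float)).ravel()
        peak = values.max(initial=0.0)
        if peak > 0:
            values = values / peak
    if grid is None:
        raise ContractError("a grid is required to localize the image")
    vol = grid.to_volume(values)
    mask = vol >= threshold
    if not mask.any():
        return LocalizationReport(detected=False, threshold=threshold)
    labels, n_comp = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n_comp + 1))
    main = labels == (int(np.argmax(sizes)) + 1)
    ii, jj, kk = np.nonzero(main)
    x, y, z = grid.axes()
    bbox = (
        (float(x[ii.min()]), float(x[ii.max()])),
        (float(y[jj.min()]), float(y[jj.max()])),
        (float(z[kk.min()]), float(z[kk.max()])),
    )
    # extent counts the occupied voxel layers, so a perfect indicator image
    # reads the object's physical extent to within one voxel
    extent = tuple(hi - lo + grid.spacing for lo, hi in bbox)
    weights = vol[main]
    centroid = (
        float(np.average(x[ii], weights=weights)),
        float(np.average(y[jj], weights=weights)),
        float(np.average(z[kk], weights=weights)),
    )
    near_face = bbox[2][0]
    z_bias = None
    if phantom is not None:
        target_face = (
            phantom.near_face_z_mm if region == "outer" else phantom.inner_near_face_z_mm
        )
        z_bias = near_face - target_face
    return LocalizationReport(
        detected=True,
        threshold=threshold,
        n_voxels=int(main.sum()),
        bbox_mm=bbox,
        extent_mm=extent,
        centroid_mm=centroid,
        near_face_z_mm=float(near_face),
        z_bias_mm=z_bias,
    )
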