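# Methods

`mwablate` is an in-silico testbed for a microwave imaging (MWI) device that
monitors liver thermal ablation: a linear array of eight antennas immersed in
a lossy coupling medium watches a tissue-mimicking phantom whose two nested
ellipsoids are re-filled to represent the pre-treatment, ongoing and completed
stages of an ablation. The package simulates the multistatic scattering data,
reconstructs 3D differential contrast images by truncated-SVD inversion of the
linearized scattering model, and quantifies the results.

## Physical model

**Materials.** Every material is a frequency-dependent complex equivalent
permittivity ε_eq(ω) = ε_r(ω)·ε0 − j·σ(ω)/ω under the e^{+jωt} convention
(passive media have Im ε_eq ≤ 0; the complex wavenumber branch Im k < 0 makes
fields decay). The coupling medium is ε_r = 23, σ = 0.07 S/m; carbonized
tissue ε_r = 8.33, σ = 0.39 S/m (characterized at a single frequency and
treated as frequency-constant over the 600–1400 MHz band); ABS plastic
ε_r = 3, σ = 0.004 S/m. Liver and coagulation-necrosis dispersions are
shipped as *editable placeholder tables* (liver ε_r 50→46, σ 0.65→1.0 S/m;
necrosis ε_r 42→38, σ 0.55→0.85 S/m across the band, linearly interpolated):
published measurements exist but are not reproduced here, and nothing
quantitative in the test suite depends on these values — only on the
qualitative ordering liver > necrosis > medium-relative contrasts.

**Geometry.** Right-handed coordinates: x along the array, z boresight,
origin at the centre of the antenna tips; millimetres internally, Hz for
frequency. The region of interest is a node lattice spanning
120 × 102 × 102 mm at 3 mm spacing: 41 × 35 × 35 = 50,225 nodes, x-fastest
linear indexing. The z-origin of the lattice is 2 mm: node layers then fall
on z = 2, 5, …, 104 mm, which reproduces the display convention of the
reference renderings (z = 17…104 mm shown, the five layers nearest the
antennas cropped as antenna-artifact layers) as whole node layers, and keeps
every node off the source plane. The phantom's outer ellipsoid
(60 × 40 × 40 mm semi-axes 30/20/20) has its near face 35 mm from the tips,
centre (0, 0, 55); the inner ellipsoid is 34 × 13 × 13 mm. Shell variants add
1.5 mm ABS layers immediately outside each ellipsoid surface, rasterized by
radial distance-to-surface. Ellipsoid membership is a centre-point test per
node.

**Antenna surrogate.** The forward model replaces the full-wave antenna by an
elementary electric dipole in the homogeneous lossy background, with the full
near+far dyadic terms (1/r, 1/r², 1/r³). Two modelling choices matter and are
configurable:

- *Phase-centre standoff* (default 15 mm): the dipole sits behind the
  physical tip, because the phase centre of a 60 mm end-fire traveling-wave
  taper lies inside the taper. A point source directly at the tip is
  reactive-field dominated at the first ROI node layers (2–5 mm away), which
  makes those kernel columns singular and concentrates the entire truncated
  SVD basis there — behaviour the extended aperture it stands in for does not
  exhibit.
- *Polarization* (default y): antenna boards stacked 23 mm apart along x lie
  in the y–z plane, so the element's linear polarization is in-board,
  along y.

Absolute signal levels of this surrogate are not comparable to measured or
full-wave S-parameters; all imaging quantities are differential and/or
normalized. Antenna crosstalk is not modelled: the empty-tank reference s0
has identically zero scattering matrices, and the informative quantity is
always the difference of two scans.

**Forward data.** Under the distorted Born approximation the differential
data obey ΔS = K Δx with kernel entries

    K_mn = −j ΔV / (4 ω_f ε_eqCM) · E_i(r_n, p) · E_i(r_n, q),

a non-conjugated bilinear product (the reciprocity-derived data equation is
bilinear), with the voxel volume ΔV included as the Riemann-sum factor of the
discretized integral (it only scales the contrast, which is normalized away).
Rows are ordered frequency-major, then transmitter, then receiver, matching
the 5 × 8 × 8 = 320-element data vector; rows (f, p, q) and (f, q, p) are
bitwise identical.

"Measured" data are generated on a refinement-2 grid (1.5 mm) restricted to
the contrast support, so the inversion never sees data produced by its own
discretization (inverse-crime mitigation); a consistent-grid mode exists for
exact oracle tests. The measured discretization error is ≈ −26 dB relative to
the coarse-grid product for the default phantom — it, not the additive noise,
limits the usable singular spectrum depth.

**Contrast convention.** The linear model uses a single Δx for the whole
band, so the contrast (per-voxel difference of ε_eq between the two states)
is evaluated at one reference frequency, default 1 GHz (band centre), for
forward data, ground truth and ideal reconstructions alike. Material
dispersion across the band therefore does not enter the synthetic experiment
as model error; real data would add it.

**Noise.** Additive i.i.d. circular complex Gaussian noise, calibrated per
frequency: noise power per complex entry = mean |S|² per entry × 10^(−SNR/10),
default SNR 45 dB (vector-network-analyzer class). The all-zero s0 scan is
noised at the floor set by the mean phantom-scenario power (a VNA's noise
floor does not vanish when the tank is empty). All randomness derives from
one experiment seed via per-scenario substreams of `numpy`'s `SeedSequence`.

## Inversion

The kernel is factorized once per geometry/background (SVD of the 320 × 50,225
matrix, a few seconds on one core, cacheable to HDF5 keyed by a config hash);
scenario changes never trigger refactorization, which is what makes the
imaging step itself real-time. The image is the truncated-SVD solution
Δx = Σ_{i≤ν} (u_iᴴ ΔS/σ_i) v_i, reported as its normalized magnitude
I ∈ [0, 1].

**Choosing ν.** Candidates are slope changes of the dB singular-value curve:
the local slope is estimated over a 5-sample window on each side of every
index and a change above 0.5 dB/index is a candidate (the window and
prominence are config parameters; knee-picking is visual in practice and any
detector parameterizes that judgement). The selected ν is the largest
candidate whose normalized singular value is still at or above the noise
level expected on the *differential* signal; if none qualifies the rule falls
back to the noise-crossing index with a warning. The pipeline derives that
noise level from the data themselves: the s0 scan is pure noise here, so
10·log10(2·P(s0)/P(ΔS)) is the differential noise level (two scans contribute
noise to a difference) — the same arithmetic by which a 45 dB measurement SNR
and a −30 dB differential level combine to −15 dB. With the crosstalk-free
surrogate the derived level is ≈ −42 dB and the rule retains ~70 of the ~180
independent singular triples.

**Ideal reconstruction and NMSE.** The best image the truncated basis can
express is the projection Δx_ID = V_ν V_νᴴ Δx_GT of the ground-truth
contrast. Reconstructions are scored by
NMSE = Σ|I_ID − I|²/Σ|I_ID|² on the normalized magnitudes (both defensively
re-normalized). The central numerical oracle of the package is the identity
TSVD(K Δx_GT, ν) = V_ν V_νᴴ Δx_GT for noiseless consistent data, which holds
to ≤ 10⁻⁶ relative error for every ν up to the numerical rank.

**Localization.** The image is thresholded at half its peak, the largest
6-connected component kept, and its bounding box, centroid and near-face z
reported. Extent counts occupied voxel layers (max − min + one spacing), so a
perfect indicator image reads the object's physical extent to within one
voxel regardless of grid alignment. The z bias is the near face of the
detection minus the phantom's near face; negative means the target appears
closer to the array than it is — the characteristic behaviour of this
aspect-limited setup, observed here at 3–12 mm toward the array.

## What the synthetic experiment does and does not show

The generator emulates the acquisition semantics (multistatic 8 × 8 scans at
five frequencies, 45 dB additive noise, evolving two-ellipsoid contrast) but
not full-wave physics: no antenna mutual coupling or crosstalk, no multiple
scattering (data are Born-consistent by construction apart from the
refinement mismatch), and an analytic element pattern. Consequences observed
and asserted in the tests: detection and the toward-array near-face bias are
robust across seeds and stages; the half-maximum x-extent of the detection
underestimates the 60 mm ellipsoid (45–51 mm), because the analytic-dipole
kernel's singular spectrum decays to −35 dB by index ≈ 40 and even the ideal
reconstruction at any truncation spans ≤ ~51 mm at half maximum. A full-wave
kernel, whose spectrum stays above −15 dB out to index ~75, resolves the full
extent; the linear-array geometry also leaves the y-extent strongly
overestimated here, as expected for a 3D image formed from a 1D aperture.

## Numerical choices

- SVD via LAPACK `gesdd`, thin factors; numerical rank = σ > σ₁·10⁻¹²;
  truncation beyond rank raises.
- Source-clearance guard: nodes must be ≥ half a voxel (1.5 mm) from any
  dipole position (with the default standoff the actual clearance is ≥ 17 mm).
- The fine forward grid shares the coarse origin; refinement 1 reproduces the
  coarse matrix-vector product to machine rounding.
- Touchstone files are written/read in RI format, Hz, 50 Ω, row-major
  matrices, four complex pairs per line; incident fields and SVD factors use
  HDF5 containers; images export to NIfTI with a 3 mm isotropic affine.
- Degenerate inputs: identical scenario pairs yield a valid all-zero contrast;
  an all-zero image localizes as "no detection"; an all-zero ideal image makes
  NMSE undefined (error), as does noise calibration on a zero-power signal
  without an explicit reference power.

## Problem sizes

The default full-scale pipeline (kernel assembly, SVD, seven scenario
simulations on the refined support, ten inversions and reports) completes in
well under a minute on one core. The bundled "tiny" configuration
(4 antennas, 2 frequencies, 11 × 9 × 9 grid, spherical two-region phantom,
kernel 32 × 891) runs in milliseconds and carries the exact oracle tests;
noise-calibration statistics use 1000 realizations.
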