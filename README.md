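# mwablate

Differential microwave imaging, in silico, for monitoring liver thermal
ablation.

Thermal ablation destroys liver tumors by heating, but clinicians lack a
practical way to watch the ablated zone grow during treatment. Because tissue
dielectric properties change with thermal damage, a microwave imaging (MWI)
array can sense the evolving contrast between pre- and post-ablation states.
`mwablate` is a desk-scale simulator of such a device — eight antennas in a
line, immersed with a two-ellipsoid ablation phantom in a lossy coupling
medium (εr = 23, σ = 0.07 S/m) — for people designing or studying the
measurement setup and its image-formation chain: it generates the synthetic
multistatic S-parameter data, reconstructs 3D images of the dielectric
changes, and scores them.

## Model

Each scan is a set of 8 × 8 scattering matrices **S** at five frequencies
(600–1400 MHz). The difference **ΔS** between two scans (320 complex values)
is linearly related to the voxel contrast **Δx** (the change of complex
permittivity in each of the 50,225 ROI voxels) under the distorted Born
approximation:

    ΔS = K Δx,     K_mn = −j ΔV/(4 ω_f ε_eq,CM) · E_i(r_n, p) · E_i(r_n, q)

where E_i are the incident fields of transmitter p and receiver q in the
coupling medium. K is severely ill-conditioned, so the image is the truncated
SVD solution

    Δx = Σ_{i ≤ ν} (u_iᴴ ΔS / σ_i) v_i,

displayed as its normalized magnitude I ∈ [0, 1]. The truncation index ν is
picked at slope changes of the singular-value curve, keeping only modes above
the noise level expected on the differential signal. Reconstructions are
compared against the ideal reconstruction Δx_ID = V_ν V_νᴴ Δx_GT via
NMSE = Σ|I_ID − I|² / Σ|I_ID|², and localized by the bounding box of the
half-maximum region. The phantom stages — (a) all liver, (b) necrotic core,
(c) necrotic shell with carbonized core, each with or without 1.5 mm ABS
printing shells, plus the empty tank s0 — yield the ten differential data
sets aX-s0, bX-s0, cX-s0, bX-aX, cX-bX.

See `docs/methods.md` for the full model description, the antenna surrogate,
parameter defaults, and known limitations.

## Worked example

```python
import mwablate as m

cfg = m.default_config().with_overrides(scenarios=("s0", "a1", "b1"))
result = m.run_experiment(cfg)
print("selected nu:", result.nu)
print(result.nmse_table().round(4).to_string())
loc = result.pairs["a1-s0"].localization
print("a1-s0 extent (mm):", tuple(round(e, 1) for e in loc.extent_mm))
print("a1-s0 near-face z bias (mm):", loc.z_bias_mm)
```

prints

```
selected nu: 68
a1-s0    0.0004
b1-s0    0.0005
b1-a1    0.1229
a1-s0 extent (mm): (45.0, 81.0, 66.0)
a1-s0 near-face z bias (mm): -15.0
```

Reading this: the rule retained ν = 68 singular triples; the two
phantom-versus-empty reconstructions are essentially at their ideal-projection
limit (NMSE ≈ 0), while the ongoing-ablation pair b1-a1, whose differential
signal is far weaker, degrades to NMSE ≈ 0.12. The detected half-maximum
region of the pre-treatment phantom spans 45 mm along the array (the 60 mm
ellipsoid, shrunk by the finite resolution of the linear aperture), is
overestimated along y (no vertical aperture), and its near face appears
15 mm closer to the antennas than the true phantom face — this setup images
the ablation boundary from the antenna side, slightly early.

The same pipeline is scriptable from the shell:

```sh
mwablate simulate -c config.yaml -o out/      # Touchstone .s8p per scenario
mwablate spectrum -c config.yaml -o out/      # singular values + candidates
mwablate invert  --pair b1-s0 -o out/         # one reconstruction (NIfTI/PNG)
mwablate report  -c config.yaml -o out/       # everything + report.json
```

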