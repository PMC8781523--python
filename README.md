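# jmoct

Simulation and multicontrast analysis of Jones-matrix optical coherence
tomography (JM-OCT) volumes.

JM-OCT is a polarization-sensitive OCT variant that measures the full complex
2×2 Jones matrix of a sample per voxel, via polarization-multiplexed
illumination and detection.  From that single measurement one can derive
several tissue-specific contrasts at once: backscatter intensity, the
depth-resolved attenuation coefficient, local birefringence (retardance per
unit depth, a marker for fibrous tissue such as muscle and myelinated nerve),
the degree of polarization uniformity (DOPU, low in pigmented, depolarizing
tissue), and label-free angiography from the temporal decorrelation of the
complex signal across repeated frames.  It is an attractive tool for
whole-animal small-model imaging — e.g. juvenile zebrafish, whose organs
(spinal cord, skeletal muscle, gills, skin) carry distinct scattering and
polarization signatures that change with development.

Raw instrument volumes for such systems are proprietary, so this package
pairs the processing chain with a forward simulator: digital phantoms with
known per-region optical properties are rendered into fully speckled,
noise-corrupted Jones-matrix tomograms, and every estimator is validated by
recovering the ground truth.

## What is computed

For a measured Jones matrix `M(z)` per voxel (depth pixel Δ = 7.24 μm,
λ₀ = 1.31 μm by default):

- **Intensity** — mean of |entry|² over the four polarization channels,
  optionally in dB.
- **Attenuation μ (mm⁻¹)** — depth-resolved estimate from the ratio of the
  local intensity to its remaining depth integral,
  `μ̂[i] = ln(1 + I[i]/Σ_{j>i} I[j]) / (2Δ)` (exact on a sampled
  exponential; a `raw` variant without the log correction is included).
  Noise-floor subtraction, a noise-aware integration cut and an exponential
  continuation of the tail beyond the volume remove the classical truncation
  biases.
- **Local birefringence Δn** — from the local Jones matrix
  `L(z) = M(z+lag·Δ)·M(z)⁻¹`, whose eigenvalue phase difference is the local
  round-trip retardance δ ∈ [0, π]; `Δn̂ = δ·λ₀/(4π·lag·Δ)`.  The default
  estimator kernel-averages the det-normalized trace of `L`
  (±2 cos δ/2) before the arccos, which suppresses the upward noise-folding
  bias at low retardance.
- **DOPU** — per-illumination-state Stokes vectors, kernel-averaged;
  `DOPU = √(Q̄²+Ū²+V̄²)/Ī`, averaged over the two states.
- **Angiography** — complex correlation of adjacent repeat pairs aggregated
  over a kernel; `flow = 1 − ρ`.
- **Mosaics** — tiles acquired with ~5% overlap are registered by normalized
  cross-correlation of depth projections and blended with linear feathering.
- **Quantification** — box-plot statistics (median, quartiles, 1.5·IQR
  whiskers, outliers, mean ± SD) of any contrast inside organ masks, and
  signed percent changes between age groups.

## Worked example

Recover organ-scale ground truths from uniform speckled phantoms
(64×64 A-lines, 30 dB SNR):

```python
from jmoct.experiments import recover_attenuation, recover_birefringence, axial_resolution

mu_hat, n = recover_attenuation(11.6, seed=1)    # spinal-cord-like attenuation
print(f"recovered mu = {mu_hat:.2f} mm^-1 over {n} voxels (truth 11.6)")

dn_hat, n = recover_birefringence(2.2e-3, seed=1)  # spinal-cord-like birefringence
print(f"recovered dn = {dn_hat:.3e} over {n} voxels (truth 2.2e-3)")

print(f"axial FWHM = {axial_resolution():.2f} um")
```

prints

```
recovered mu = 11.51 mm^-1 over 32768 voxels (truth 11.6)
recovered dn = 2.218e-03 over 276100 voxels (truth 2.2e-3)
axial FWHM = 13.83 um
```

i.e. the attenuation comes back within 1%, the birefringence within 1%, and
the simulated point-spread function reproduces the 14 μm axial resolution of
the modelled system within a fraction of the 7.24 μm depth pixel.

The full pipeline (simulate a layered zebrafish phantom for both age groups,
compute all five contrasts, quantify per organ, compare groups) runs from the
command line:

```bash
jmoct run --preset juvenile-mini --seed 1 --out demo
```

`demo/comparison.csv` then contains, per organ and contrast, the relative
change from the 1-month to the 2-month phantom; e.g. the spine rows

```
spine,attenuation,11.140620530017024,6.537917173783154,-41.3
spine,birefringence,0.001179939525017364,0.002181956578994283,84.9
```

show the recovered spinal-cord attenuation dropping by ~41% between the two
age groups (the phantom ground truths are 11.6 → 6.8 mm⁻¹) while its
birefringence nearly doubles (1.2 → 2.2 × 10⁻³) — the two headline
age-related changes the phantom encodes.  Individual stages are also exposed
as subcommands (`simulate`, `process`, `stitch`, `quantify`, `report`).

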