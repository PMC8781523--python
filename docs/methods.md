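# Methods

## Measurement model

The simulator implements single-scatter, transpose-symmetric round-trip Jones
optics for a reciprocal medium, sampled on a (z, x, y) voxel grid with depth
pitch Δ = 7.24 μm (in tissue) and centre wavelength λ₀ = 1.31 μm.  For each
A-line, the voxel at depth index *i* carries

```
M_i = a_i · A_i · U_i,      A_i = T_iᵀ · T_i,      T_i = R_i · R_{i-1} · … · R_1
```

where `R_j` is a linear retarder with single-pass retardance
`φ_j = (2π/λ₀)·Δn_j·Δ` about an in-plane axis θ_j, and the transpose
symmetry of `A_i` encodes reciprocity of the double pass.  `U_i` is the
scatterer unitary: the identity for polarization-preserving scatterers, an
independent Haar-random 2×2 unitary with probability `depol_fraction`
(melanin-like polarization scrambling — the mechanism is a per-voxel random
unitary rather than a multiple-scattering simulation, which reproduces
kernel-scale DOPU loss at desk scale).  `a_i` is a single circular complex
Gaussian speckle amplitude shared by all four matrix entries, with

```
E[|a_i|²] = reflectivity_i · exp(−2·Δ_mm·Σ_{j≤i} μ_j)
```

— fully developed speckle with round-trip attenuation, stated explicitly as
the `exp(−2μz)` convention so that recovered coefficients are on the mm⁻¹
scale used for tissue.  The complex field is then convolved along depth with
a Gaussian kernel and independent complex Gaussian detector noise is added
per channel at `noise_floor_db` (relative to a unit surface reflector; the
default −30 dB corresponds to 30 dB surface SNR — the real system's per-voxel
SNR is not derivable from its quoted sensitivity alone, so this is a
documented free parameter; the bundled phantom presets use −45 dB).

Across repeated frames, static voxels reuse `a_i` and `U_i` (only detector
noise is fresh); voxels in `flow` regions redraw both every repeat.

**Axial resolution convention.**  `axial_fwhm` (default 14 μm) is the FWHM of
the *intensity* axial point-spread function — the convention in which OCT
axial resolutions are quoted.  The complex field kernel therefore has FWHM
√2 × `axial_fwhm`; a point-reflector simulation reproduces the 14 μm
intensity FWHM to within a fraction of a depth pixel.  A lateral PSF is not
applied by default (no quantitative claim here depends on lateral
resolution).

**Seeding.**  One root seed; independent sub-streams for speckle,
depolarization, unitaries, noise and flow are derived by `SeedSequence`
spawning, so volumes are bit-reproducible.

## Attenuation estimation

The depth-resolved estimator infers μ per voxel from the ratio of local
intensity to the remaining integrated tail.  With
`T[i] = Σ_{j>i} I[j]`:

- `log_corrected` (default): `μ̂[i] = ln(1 + I[i]/T[i]) / (2Δ)` — exact for a
  discretely sampled exponential (the geometric tail sum cancels the pitch
  bias);
- `raw`: `μ̂[i] = I[i] / (2Δ·T[i])`, which carries a known
  `(e^{2μΔ}−1)/(2μΔ)` small-pitch bias (~+9% at 11.6 mm⁻¹) and is kept for
  comparison.

Three practical corrections matter:

1. **Noise floor** — a scalar floor (or the mean of a designated background
   region) is subtracted before summation; negatives are clipped and counted.
2. **Integration cut** — when the floor is known, the tail integration stops
   at the depth where the lateral-mean signal has decayed to the floor.
   Without the cut, clipped noise residue (mean ≈ 0.37 × floor per pure-noise
   voxel) accumulates into every tail and destroys the estimate at high μ.
3. **Tail continuation** — with `tail_fit_pixels > 0`, the decay rate of the
   lateral-mean profile over the last pixels before the cut is fitted
   (split-half log slope, robust to speckle) and the geometric remainder
   beyond the cut is added to every tail sum.  The per-line end amplitude is
   decay-compensated over the last 16 pixels and smoothed laterally (3×3):
   the remainder enters the tail sums inside a logarithm, so unsmoothed
   speckle noise in it would bias the deepest estimates upward (Jensen).
   This removes the truncation bias of slowly decaying media in shallow
   volumes (μ = 0.5 mm⁻¹ recovers within ~1% even when only a third of the
   decay fits into the volume).

The estimator assumes the backscattered fraction is proportional to the local
attenuation coefficient (constant albedo).  This is inherent to the method,
not an implementation choice: with independent per-region reflectivity the
layered-phantom recovery fails by design.  The phantom presets therefore tie
`reflectivity = albedo_scale · μ`, emulating scattering-dominated tissue.

**Averaging attenuation over an ROI.**  Statistics use
`attenuation_analysis_window`, which gates by *depth* (lateral-mean signal
sufficiently above the floor), never by per-voxel intensity: speckle
intensity is exponentially distributed, and conditioning a voxel on being
bright selects the upper tail of the very numerator of its own estimate —
a per-voxel SNR gate inflates ROI means by tens of percent near the mask
edge.

## Local birefringence

`L(z) = M(z+lag·Δ)·M(z)⁻¹` is similar (via the overburden's cumulative
matrix) to the squared single-pass retarder of the slab between the two
depths, so its eigenvalue phase difference is the local round-trip retardance
δ ∈ [0, π] regardless of what lies above — this also holds when the
overburden's optic axis differs from the local one.
`Δn̂ = δ·λ₀/(4π·lag·Δ)`; retardances beyond the wrap limit
`Δn = λ₀/(4·lag·Δ)` (≈ 1.5 × 10⁻² at lag 3) alias back into range.

δ is a magnitude, so simple complex averaging of `exp(iδ)` over a kernel is
not meaningful, and per-voxel phase estimates fold noise upward at low
retardance.  Two kernel aggregations are provided:

- `trace` (default): the det-normalized trace `tr(L)/√det L = ±2·cos(δ/2)`
  (sign fixed to the non-negative real branch) is intensity-weight averaged
  over the kernel *before* the arccos.  Noise enters this statistic linearly,
  so averaging first suppresses the folding bias: at 30 dB surface SNR the
  recovered Δn is within ~3% down to 0.9 × 10⁻³, where per-voxel phase
  medians are +10–16% high.
- `median`: classical per-voxel δ, median-filtered over the kernel.

The Jones matrices are coherently averaged over repeated frames by default
(valid for static tissue, √R noise reduction — the modelled acquisition takes
four repeats anyway).  Voxels below the SNR threshold (default 15 dB over the
floor) or failing a condition-number cap on `M(z)` are flagged invalid.
This estimator plays the role that maximum-a-posteriori retardance estimators
play in the literature: it is the unbiased core such estimators regularize,
and the `aggregation` hook is the place a MAP variant would plug in.

## DOPU and angiography

DOPU: per illumination state (Jones-matrix column), the Stokes vector of the
detected field pair is computed per voxel, averaged over repeats and over the
(kz, kx) kernel (default 3×3), normalized, and the two states averaged;
values are clipped to [0, 1].  No noise-bias correction is applied (left as
an extension hook).

Angiography: complex correlation of adjacent repeat pairs,
`ρ = |Σ E_k E*_{k+1}| / √(Σ|E_k|² Σ|E_{k+1}|²)`, aggregated over the kernel;
`flow = 1 − ρ`.  Adjacent pairs (not all pairs) are the default; the first
Jones entry is used unless `channels='all'`.  Pure noise decorrelates like
flow, so an intensity mask (default 10 dB over the floor) flags noise voxels
invalid.

## Mosaics

Tiles are registered pairwise on mean-over-depth 2D projections (the stage
moves only laterally, so z-offsets are taken as zero), by exhaustive
normalized cross-correlation over ±`search_radius` integer offsets; ties
resolve toward the nominal stage offset, and if no candidate reaches
`min_score` (default 0.3) the nominal offset is kept — featureless overlap
regions otherwise produce a random argmax.  Sub-pixel registration is
deliberately out of scope.  Blending uses linear feathering with weights that
ramp from the tile borders; weights are normalized so constant fields are
conserved and single-contributor regions equal their tile exactly.
Registration defaults to the intensity contrast.

## Quantification

Box-plot statistics pool all valid voxels of a volume inside a mask
(the volumetric equivalent of B-scan-wise manual masks): median and quartiles
by linear interpolation of order statistics, whiskers at the most extreme
data points within 1.5·IQR of the quartiles, outliers counted beyond them,
plus mean and SD.  Group comparisons report
`100·(value_old − value_young)/value_young` to 0.1%.  No hypothesis testing
is performed.

## Phantom presets

`juvenile` (256×96×64 voxels) and `juvenile-mini` (160×48×32) are layered
cartoons of a juvenile zebrafish section: a water bath, a skin layer, bulk
skeletal muscle, a spinal-cord cylinder, a gill block, a flow vessel and a
pigmented depolarizing patch.  Per-organ attenuation and birefringence are
organ-scale reference means for wild-type zebrafish at 1 and 2 months
(spine 11.6 → 6.8 mm⁻¹ and 1.2 → 2.2 × 10⁻³, muscles 0.5 → 0.6 mm⁻¹ and
1.6 → 1.8 × 10⁻³, gills 2.9 → 2.0 mm⁻¹ at 0.9 × 10⁻³, skin 5.7 → 4.0 mm⁻¹
and 1.5 → 1.4 × 10⁻³); geometry is deterministic and the seed only changes
the speckle/noise realization.  Ground-truth organ masks are eroded by a
couple of voxels so that quantification avoids boundary voxels where
kernel-based estimators mix regions — the counterpart of conservative manual
segmentation.

What the phantoms do *not* emulate: multiple scattering (hence no tailing
artifacts beneath pigment), confocal/sensitivity roll-off, motion artifacts,
lateral PSF, or anatomically realistic geometry.  Passing recovery tests
therefore demonstrates correctness of the estimator chain under the stated
measurement model, not robustness to every effect present in real tissue.

## Validation choices and problem sizes

- Uniform-phantom recovery experiments use 64×64 A-lines with 400 depth
  pixels (1200 for the slowest decay, so that it is resolvable), at 30 dB
  surface SNR; attenuation recovers within 5% and birefringence within 10%
  of the ground truth, with large margins in practice.
- The end-to-end layered-phantom test uses the full `juvenile` preset: the
  mini variant is too shallow for the muscle decay, making its extrapolated
  tail fraction seed-sensitive.
- Vessel recovery by angiography is evaluated with a boundary-tolerant Dice:
  voxels in the one-voxel rim around the vessel are excluded, because under a
  finite axial PSF and a 3×3 correlation kernel the membership of
  partial-volume voxels is physically ill-defined (the rim alone is ~half the
  volume of a 3-px-radius vessel).  Outside the rim, Dice exceeds 0.98.
- Degenerate inputs: all-zero A-lines and singular local matrices are flagged
  invalid rather than raising; negative intensities after floor subtraction
  are clipped and logged; DOPU and flow are clipped to [0, 1].

## Known limitations

- The constant-albedo assumption ties the simulator's reflectivity to μ in
  presets; media violating it (e.g. specular interfaces) will bias the
  attenuation estimate, as they do for the underlying method.
- The tail-continuation fit assumes the deepest in-cut region decays at a
  single dominant rate; strongly mixed-rate bottoms reduce its accuracy.
- Integer-pixel registration only; no global bundle adjustment for many
  tiles; no illumination flat-fielding.
- Optic-axis imaging and DOPU noise-bias correction are not implemented.
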