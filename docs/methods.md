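# Methods

This note documents the models, numerical choices and known limitations of
`beamtrack`. It is written for users who want to understand what the
implementation assumes, what the synthetic-data generator does and does not
emulate, and where the genuinely open design decisions were made.

## Physical model and assumptions

The retrieval operates entirely in the geometrical-optics (ray)
approximation: a beamlet crossing the sample is attenuated by
exp(−∫μ ds) and deflected by the refraction angle α = (1/k)∇⊥ΔΦ, producing
a transverse displacement z_od·α on the detector. No Fresnel propagation or
coherent diffraction is modelled; the approximation is adequate for
propagation distances up to the order of a metre at hard-X-ray energies,
which covers the geometries this package targets (z_od from a few cm to
~1.3 m). The beam is treated as monochromatic at its stated mean energy
(default configurations use 16 or 27 keV); a polychromatic ("pink") beam is
reduced to a single effective wavenumber k = 2πE/(hc), with
hc = 1.23984198 keV·nm. Beamlet broadening (ultra-small-angle scattering /
dark-field) is deliberately not retrieved or simulated.

All internal lengths are metres; micrometres and centimetres appear only in
configuration files, where each length carries an explicit unit. This avoids
the silent power-of-ten errors that mixed µm/cm bookkeeping invites.

## Synthetic-data generator

The simulator exists so that every downstream stage can be tested
quantitatively without beamline data. It emulates:

* parallel-beam line integrals of voxelized δ and μ maps, computed by
  resampling rays through the volume with bilinear interpolation (the
  volume is never rotated, so oracle comparisons don't stack two
  interpolations);
* beamlets as isotropic Gaussian spots (σ = 2 px by default, FWHM ≈ 4.7 px
  ≈ 12 µm at 2.6 µm pixels, near the 15 µm front apertures of a typical
  mask) on a regular grid with the period/pixel ratio of the configured
  geometry (50/2.6 ≈ 19.23 px by default), displaced by z_od·α converted to
  pixels and scaled by the local transmission;
* photon counting (Poisson, default 10⁴ photons per beamlet per frame —
  this puts single-frame registration noise around 0.02 px, i.e. ~40 nrad
  at z_od = 1.28 m, the sensitivity scale such instruments reach) and a
  detector dark level of 100 counts with Gaussian read noise of σ = 2;
* the two raster modes: tomography (modulator steps by period/n per axis,
  sample fixed, one flat per modulator position) and planar (grid fixed,
  interpreted as the sample having moved by the opposite offset).

It does **not** emulate: source-size or scintillator blur (so the measured
flat-field visibility of a real instrument is not reproduced — beamlet σ is
the single knob), detector distortion or PSF beyond the Gaussian spot,
beam hardening, partial coherence, or dark-field contrast. Passing tests
therefore demonstrate the correctness of the retrieval/reconstruction chain
under the stated forward model, not robustness to every artefact of real
beamline data.

The default two-material cylinder phantom uses soft-tissue-like δ
(4×10⁻⁷ and 10⁻⁶). Its μ values (800 and 2000 m⁻¹) are intentionally larger
than tissue's tens-per-metre: a desk-scale phantom is a few hundred µm
across rather than a few mm, and scaling μ up preserves the optical depth
(−ln t of a few tenths) that a real sample presents. Without this, the
attenuation channel of a small phantom would be pure photon noise and no
quantitative statement about the attenuation pipeline could be made.

## Retrieval

Each beamlet is analysed in a fixed window (default 20×20 px) centred on its
*nominal* lattice position — the window does not follow the displaced spot,
and windows are allowed to overlap by the ~1 px that a 19.23 px pitch
implies. Windows crossing the frame edge, with non-positive flat counts, or
constant content are masked (NaN) rather than clipped or guessed.

Subpixel registration uses single-step upsampled DFT cross-correlation
(scikit-image's `phase_cross_correlation`) with `normalization=None`: the
plain cross-correlation of the original algorithm. The default spectral
whitening ("phase correlation") variant is measurably unreliable on small,
smooth, band-limited spots such as beamlets — on a 16–24 px Gaussian spot it
misestimates a 0.5 px shift by a factor of ~3 — whereas the unnormalized
form recovers imposed shifts to the 1/upsampling quantum (default 1/100 px
≈ 26 nm ≈ 20 nrad at 1.28 m). An exhaustive correlation-peak scan at
0.001 px steps serves as the independent oracle in the tests.

Sign conventions: +x/+y follow the detector pixel axes; displacement and
refraction angle are positive when the beamlet moves toward +axis; the
registration routine flips the sign of the library's output, which reports
the shift needed to move the sample *back* onto the flat. With
ΔΦ = −k∫δ ds, a δ > 0 object produces a negative phase dip and outward
refraction. If a downstream convention differs, only a global sign flips.

Stitching interleaves the n² raster maps so that output pixel
(i·n + b, j·n + a) comes from raster offset (a, b)'s beamlet (i, j):
increasing modulator offset along +x fills increasing output x. The
operation is a pure permutation; `unstitch` inverts it exactly.

Flat frames are expected per raster position (tomography mode); repeated
flats (e.g. before/after a scan) are averaged with `average_frames` — no
temporal interpolation is attempted. When frames arrive without grid
metadata, `locate_grid` finds the lattice by peak-finding on a
period-smoothed flat and least-squares snapping to a regular grid
(±0.5 px origin accuracy is ample, since windows are rounded to integer
pixels anyway).

## Phase integration

The complex Fourier method divides the transform of g_x + i·g_y by
2πi(u + iv), with frequencies in cycles/m from the map pitch. The DC term is
undefined (the method cannot recover the mean) and is set to zero; the
result is then re-anchored to zero mean over a declared sample-free
background region (the pipeline uses vertical strips at the left/right FOV
edges). This anchoring matters quantitatively: an arbitrary constant per
projection would bias the δ sinogram.

Boundary handling is selectable. The default `extension="mirror"` extends
both gradient maps to 2× size with the symmetry of an evenly mirrored
potential (g_x odd in x / even in y; g_y the reverse), which makes the
extended field periodic and suppresses wrap-around leakage for fields whose
gradients decay toward the FOV edges — the measurement situation, since the
sample sits inside the reconstruction circle. For fields that are already
periodic on the grid, the mirror seam itself introduces a gradient
discontinuity and `extension="periodic"` (no padding) is exact; synthetic
periodic test fields use it. Neither mode attempts phase unwrapping (the
integrated ΔΦ is not wrapped in this method) and no weighted/iterative
least-squares variants are provided.

## Tomography

Both sinograms (−ln t and −ΔΦ/k) are reconstructed slice-by-slice with a
self-contained parallel-beam FBP: Ram-Lak filter and linear-interpolation
back projection, rotation centre at (n−1)/2, reconstruction grid equal to
the stitched-projection grid. The filter is built from the band-limited
real-space kernel (¼ at zero lag, −1/(πn)² at odd lags) rather than the
continuous 2|f| ramp; the continuous form underweights low frequencies on a
discrete grid and was measured to bias reconstructed values low by 3–8% on
disc phantoms, while the kernel form is accurate to ~0.1%. Masked or
non-positive sinogram bins are inpainted by 1D linear interpolation along
the detector row before filtering (the ramp filter does not tolerate NaN).
A `backend` hook on `fbp_reconstruct` accepts an external (sino2d, angles)
→ slice engine, but the built-in implementation is the reference and is
cross-checked against scikit-image's `iradon` in the tests (on odd-sized
grids, where the two center conventions coincide, they agree to machine
precision). No ring-artefact correction, centre-of-rotation calibration or
iterative methods are included.

Line integrals are computed and back-projected at unit pixel spacing and
divided by the pitch once, so voxel values carry physical units directly
(μ in 1/m, δ dimensionless).

## Metrics

* **Angular sensitivity**: per-window standard deviation of the refraction
  map over declared sample-free windows; the estimate is the mean and its
  standard error over windows (defaults of 8 windows; 5×40 px suits raw
  per-beamlet maps, 8×8 px stitched maps — the shape is a free parameter).
  Windows containing masked beamlets are excluded with a warning.
* **Scaling studies**: empty-beam scans tracked against a noiseless flat.
  Registration noise in pixels is set by photon statistics alone, so the
  angle noise falls as 1/z_od with distance and as N^(−1/2) with N averaged
  frames while Poisson noise dominates. The studies default to a 12×12
  beamlet grid, 10³ photons/beamlet and upsampling 200, so that the
  registration quantum (1/200 px) stays well below the smallest noise level
  measured and does not flatten the N-scaling.
* **Visibility**: intensities folded onto one (pitch × pitch) unit cell of
  the beamlet lattice and bin-averaged; contrast from the robust 99th/1st
  percentiles of the folded profile, (I_max − I_min)/(I_max + I_min).
* **FRC**: rings of one Fourier-pixel width; threshold 3/√(N(r)/2) per ring
  (the 3σ criterion); the crossing is the lowest frequency at which the
  curve first falls below the threshold, scanning outward with linear
  interpolation between rings. The innermost rings, where the threshold
  exceeds 1 (which an FRC can never beat), are skipped as uninformative; DC
  is excluded. No crossing means the resolution is sampling-limited, at
  best the pitch. Curves of several adjacent slices (the pipeline uses 5
  from mid-volume) are averaged ring-by-ring before thresholding to reduce
  estimator noise. Resolution = pitch / crossing frequency. The half-bit
  and other alternative thresholds are not implemented.

## Problem sizes

The tests and the acceptance script run simulations sized for a single CPU:
end-to-end recovery uses a 32-voxel-wide cylinder (2×2 raster, 48
projections, 10⁴ photons/beamlet — about 10 s), the scaling studies a 12×12
empty-beam grid over 4 distances and 5 averaging depths (a few seconds
each), and oracle checks 256² grids. At these sizes the end-to-end μ and δ
means land within ~1–2% of ground truth, comfortably inside the 5%
acceptance band, and the scaling exponents within ±0.05 of −1 and −0.5.

## Known limitations

* Quantitative accuracy statements hold under the simulator's forward
  model; real data add mask defects, flat-field drift, scintillator blur
  and spectral effects that are out of scope here.
* The registration window is fixed to the nominal lattice; very large
  refraction (displacements approaching the window half-width) would bias
  the retrieval. At the default geometry this corresponds to tens of µrad,
  far beyond soft-tissue gradients.
* The Fourier integrator recovers only the curl-free component of the
  gradient field and no absolute offset; quantitative δ requires a genuine
  sample-free background region in every projection.
* FBP assumes ideal parallel-beam geometry and equally spaced angles over
  [0, π); the half-dataset split halves angular sampling, so FRC resolution
  estimates are conservative for marginally sampled scans.
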