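# beamtrack

Analysis toolkit for **two-directional beam-tracking (2DBT) X-ray
phase-contrast tomography** — the modulator-based, Shack–Hartmann-style
technique in which an absorbing mask with a regular grid of apertures
structures a synchrotron beam into an array of independent beamlets that are
resolved by a high-resolution detector. A sample placed after the mask
attenuates each beamlet and, by refraction, displaces it on the detector;
tracking both effects per beamlet yields transmission and two orthogonal
phase-gradient images simultaneously, from a non-interferometric, single-shot
geometry.

The package is aimed at instrument scientists and method developers who need
a self-contained, testable implementation of the full analysis chain — from
raw beamlet frames (or a synthetic-data generator standing in for them) to
quantitative attenuation and refractive-index-decrement volumes and the
standard characterization metrics.

## Model

With detector pixel pitch *p*, object-to-detector distance *z*<sub>od</sub>
and vacuum wavenumber *k* = 2πE/(hc), a beamlet displacement (Δx, Δy) in
pixels measured against the flat (no-sample) frame gives, under geometrical
optics and for small angles, the refraction angle and phase gradient

    α_x = Δx · p / z_od = (1/k) ∂ΔΦ/∂x        (same for y)

The per-beamlet transmission is the windowed intensity ratio
*t* = ΣI<sub>s</sub> / ΣI<sub>0</sub>. Both retrieved quantities are line
integrals of the two material coefficients:

    −ln t  = ∫ μ ds          μ: linear attenuation coefficient (1/m)
    ΔΦ     = −k ∫ δ ds       δ: refractive-index decrement

ΔΦ is obtained by Fourier-space integration of the two measured gradients
(complex Kottler method), and parallel-beam filtered back projection of the
two sinograms reconstructs μ and δ volumes. Sub-pitch raster scanning of the
modulator in *n* × *n* steps and interleaving ("stitching") the per-beamlet
maps gives a sampling of period/*n* — e.g. 6.25 µm from a 50 µm mask
rastered 8 × 8, a factor 2.4 finer than the 15 µm apertures.

Characterization follows the field's conventions: **angular sensitivity** is
the standard deviation of retrieved refraction angles in sample-free windows
(mean ± standard error over windows); **spatial resolution** is estimated by
Fourier ring correlation between reconstructions of two interleaved halves
of the projections, with the 3σ threshold 3/√(N(r)/2).

## Worked example

The packaged demo simulates a two-material cylinder phantom (soft-tissue-like
δ of 4×10⁻⁷ and 10⁻⁶), runs the whole chain and writes every intermediate
artefact (frames + manifest, stitched projections, phase maps, full- and
half-dataset volumes, FRC curves, metrics):

```sh
beamtrack demo-config demo.yaml
beamtrack -v run --config demo.yaml --out out --seed 1
cat out/metrics.json
```

which takes ~10 s on one CPU and prints

```json
{
 "provenance": {"config_hash": "3c4b7eeaff5c", "seed": 1, "version": "0.1.0"},
 "sensitivity_rad": {"mean": 8.28898266825666e-08, "sem": 1.243054604252349e-09, "n_windows": 8},
 "frc_mu":    {"crossing_cyc_per_px": 0.2321079718781645, "resolution_um": 107.70849358471287, "sampling_limited": false},
 "frc_delta": {"crossing_cyc_per_px": 0.3913814155169817, "resolution_um": 63.87630840104432, "sampling_limited": false}
}
```

Reading: at 10⁴ photons/beamlet and z<sub>od</sub> = 1.28 m the empty-beam
angular sensitivity is ≈ 83 nrad per 2×2-stitched map; and the FRC crossing
of the δ (phase) half-volumes sits at a markedly higher spatial frequency
than that of the μ (attenuation) half-volumes — phase contrast resolves
finer detail at equal exposure, the hallmark of the technique on weakly
absorbing samples. Each stage is idempotent: delete a downstream artefact
and re-run to recompute only from that point. Individual stages are exposed
as `simulate`, `track`, `integrate`, `reconstruct`, `frc`, `sensitivity`.

The same chain is available as a library:

```python
import beamtrack as bt
from beamtrack.cli import track_scan, integrate_projections, reconstruct_volumes

geom = bt.SetupGeometry(z_od=1.28, mean_energy=16.0, pixel_size=2.6e-6,
                        modulator_period=50e-6, aperture_diameter=15e-6,
                        n_subpitch=2)
phantom = bt.cylinder_phantom(n=32, n_slices=8, voxel_size=bt.sampling_pitch(geom))
sim = bt.simulate_scan(phantom, geom, n_projections=48, flux=1e4, seed=3)
projections = track_scan(sim, geom, window=16)
phase_maps = integrate_projections(projections, geom.wavenumber)
mu_vol, delta_vol = reconstruct_volumes(projections, phase_maps, geom.wavenumber)
```

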