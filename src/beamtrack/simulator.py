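"""Synthetic beamlet-frame generator.

Forward model, under geometrical optics (ray) approximation:

* a phantom is a pair of voxel maps — refractive-index decrement ``delta``
  (dimensionless) and linear attenuation coefficient ``mu`` (1/m);
* a parallel-beam projection at angle ``theta`` gives transmission
  ``t = exp(-integral mu ds)`` and phase shift ``dphi = -k integral delta ds``;
* each modulator aperture forms a beamlet rendered as an isotropic Gaussian
  spot on the detector, scaled by the local transmission and displaced by
  ``z_od * alpha`` where the refraction angle ``alpha = grad(dphi) / k``;
* photon counting adds Poisson noise; the detector adds a constant dark
  offset with Gaussian read noise.

No Fresnel propagation, no beamlet broadening (dark-field) and no detector
PSF beyond the Gaussian spot are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .core import SetupGeometry, sampling_pitch

__all__ = [
    "Phantom",
    "BeamletFrame",
    "ProjectedFields",
    "ScanSimulation",
    "cylinder_phantom",
    "project_phantom",
    "render_beamlets",
    "render_flat",
    "render_dark",
    "simulate_scan",
]

#: default Gaussian beamlet width (pixels); FWHM ~ 4.7 px ~ 12 um at 2.6 um
#: pixels, close to the 15 um front-face apertures.
DEFAULT_BEAMLET_SIGMA_PX = 2.0
#: default detector dark level (counts) and read noise (counts, 1 sigma)
DEFAULT_DARK_LEVEL = 100.0
DEFAULT_READ_SIGMA = 2.0


@dataclass
class Phantom:
    """Voxel maps of delta and mu on a shared isotropic grid.

    Arrays are indexed ``(z, y, x)``; rotation is about the z axis.
    """

    delta: np.ndarray
    mu: np.ndarray
    voxel_size: float  # m

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.delta.shape != self.mu.shape:
            raise ValueError("delta and mu grids must share a shape")
        if self.delta.ndim != 3:
            raise ValueError("phantom grids must be 3D (z, y, x)")
        if self.delta.shape[1] != self.delta.shape[2]:
            raise ValueError("phantom xy slices must be square")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if (self.delta < 0).any() or (self.mu < 0).any():
            raise ValueError("delta and mu must be non-negative")


@dataclass
class BeamletFrame:
    """One detector frame holding a regular grid of beamlets.

    ``grid_origin`` is the (x, y) pixel position of beamlet (0, 0);
    ``grid_pitch`` the beamlet spacing in pixels (may be fractional);
    ``grid_shape`` the (rows, cols) beamlet count;
    ``modulator_offset`` the sub-pitch raster displacement (m, per axis).
    """

    intensity: np.ndarray
    grid_origin: tuple[float, float]
    grid_pitch: float
    grid_shape: tuple[int, int]
    modulator_offset: tuple[float, float] = (0.0, 0.0)

    def beamlet_center(self, i: int, j: int) -> tuple[float, float]:
        """Nominal (x, y) pixel centre of beamlet row i, col j."""
        return (
            self.grid_origin[0] + j * self.grid_pitch,
            self.grid_origin[1] + i * self.grid_pitch,
        )


@dataclass
class ProjectedFields:
    """Ground-truth projection of a phantom at one viewing angle."""

    t: np.ndarray  # transmission
    dphi: np.ndarray  # phase shift (rad)
    gradx: np.ndarray  # d(dphi)/dx (rad/m)
    grady: np.ndarray  # d(dphi)/dy (rad/m)
    pitch: float  # lateral sampling (m)
    angle: float = 0.0  # rad


def cylinder_phantom(
    n: int,
    n_slices: int,
    voxel_size: float,
    outer_radius_frac: float = 0.38,
    inner_radius_frac: float = 0.18,
    delta_outer: float = 4e-7,
    delta_inner: float = 1e-6,
    mu_outer: float = 800.0,
    mu_inner: float = 2000.0,
) -> Phantom:
    """Two-material concentric cylinder, axis along z.

    Default delta values are soft-tissue-like magnitudes in the 10-30 keV
    range.  The default mu values are scaled up from tissue-like ~50-120 1/m
    so that a desk-scale phantom (a few hundred um across) presents the same
    optical depth (-ln t of a few tenths) as the few-mm samples this kind of
    set-up actually images; without that, attenuation contrast at realistic
    photon counts would be essentially pure noise at this phantom size.
    Radii are fractions of the grid width so the object stays inside the
    tomographic reconstruction circle.
    """
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    r2 = (xx - c) ** 2 + (yy - c) ** 2
    outer = r2 <= (outer_radius_frac * n) ** 2
    inner = r2 <= (inner_radius_frac * n) ** 2
    delta = np.where(inner, delta_inner, np.where(outer, delta_outer, 0.0))
    mu = np.where(inner, mu_inner, np.where(outer, mu_outer, 0.0))
    return Phantom(
        delta=np.broadcast_to(delta, (n_slices, n, n)).copy(),
        mu=np.broadcast_to(mu, (n_slices, n, n)).copy(),
        voxel_size=voxel_size,
    )


def _project_slices(vol: np.ndarray, angle: float) -> np.ndarray:
    """Parallel-beam line integrals of each z slice (unit ray step).

    Rays are resampled through the volume with bilinear interpolation
    (the volume itself is never rotated).  The angle convention matches
    ``skimage.transform.radon``.  Returns an array (n_slices, n_det).
    """
    n = vol.shape[2]
    c = (n - 1) / 2.0
    th = -angle
    u = np.arange(n) - c  # detector coordinate
    s = np.arange(n) - c  # along-ray coordinate
    U, S = np.meshgrid(u, s, indexing="xy")
    X = (U * math.cos(th) - S * math.sin(th) + c).ravel()
    Y = (U * math.sin(th) + S * math.cos(th) + c).ravel()
    out = np.empty((vol.shape[0], n))
    for iz in range(vol.shape[0]):
        vals = ndi.map_coordinates(vol[iz], [Y, X], order=1, cval=0.0)
        out[iz] = vals.reshape(n, n).sum(axis=0)
    return out


def project_phantom(phantom: Phantom, angle: float, k: float) -> ProjectedFields:
    """Project a phantom at one rotation angle.

    Returns transmission ``t = exp(-integral mu ds)``, phase shift
    ``dphi = -k integral delta ds`` and the transverse gradients of the
    phase shift, all sampled on the projection grid (pitch = voxel size).
    An empty phantom gives t = 1 and zero gradients everywhere.
    """
    vs = phantom.voxel_size
    mu_li = _project_slices(phantom.mu, angle) * vs
    delta_li = _project_slices(phantom.delta, angle) * vs
    t = np.exp(-mu_li)
    dphi = -k * delta_li
    gradx = np.gradient(dphi, vs, axis=1) if dphi.shape[1] > 1 else np.zeros_like(dphi)
    grady = np.gradient(dphi, vs, axis=0) if dphi.shape[0] > 1 else np.zeros_like(dphi)
    return ProjectedFields(t=t, dphi=dphi, gradx=gradx, grady=grady, pitch=vs, angle=angle)


def _render_grid(
    t_b: np.ndarray,
    dx_px: np.ndarray,
    dy_px: np.ndarray,
    geom: SetupGeometry,
    flux: float,
    rng: np.random.Generator | None,
    sigma_px: float,
    grid_origin: tuple[float, float],
    shape: tuple[int, int],
    dark_level: float,
    read_sigma: float,
) -> np.ndarray:
    """Accumulate Gaussian spots, then apply Poisson + detector noise."""
    img = np.zeros(shape)
    pitch = geom.grid_pitch_px
    rad = int(math.ceil(5 * sigma_px))
    n_by, n_bx = t_b.shape
    for i in range(n_by):
        for j in range(n_bx):
            cx = grid_origin[0] + j * pitch + dx_px[i, j]
            cy = grid_origin[1] + i * pitch + dy_px[i, j]
            x0, x1 = int(math.floor(cx)) - rad, int(math.floor(cx)) + rad + 1
            y0, y1 = int(math.floor(cy)) - rad, int(math.floor(cy)) + rad + 1
            x0c, x1c = max(x0, 0), min(x1, shape[1])
            y0c, y1c = max(y0, 0), min(y1, shape[0])
            if x0c >= x1c or y0c >= y1c:
                continue
            xs = np.arange(x0c, x1c)
            ys = np.arange(y0c, y1c)
            gx = np.exp(-((xs - cx) ** 2) / (2 * sigma_px**2))
            gy = np.exp(-((ys - cy) ** 2) / (2 * sigma_px**2))
            spot = np.outer(gy, gx)
            amp = flux * t_b[i, j] / (2 * math.pi * sigma_px**2)
            img[y0c:y1c, x0c:x1c] += amp * spot
    if rng is not None:
        img = rng.poisson(img).astype(float)
        img += dark_level + rng.normal(0.0, read_sigma, size=img.shape)
    else:
        img += dark_level
    return img


def render_beamlets(
    t_image: np.ndarray,
    gradx: np.ndarray,
    grady: np.ndarray,
    geom: SetupGeometry,
    flux: float,
    seed: int | None = None,
    sigma_px: float = DEFAULT_BEAMLET_SIGMA_PX,
    modulator_offset: tuple[float, float] = (0.0, 0.0),
    margin_px: int | None = None,
    dark_level: float = DEFAULT_DARK_LEVEL,
    read_sigma: float = DEFAULT_READ_SIGMA,
    move_grid: bool = True,
) -> BeamletFrame:
    """Render one sample frame from fields sampled at the beamlet grid.

    ``t_image``, ``gradx``, ``grady`` must have one value per beamlet.
    Each beamlet carries ``flux * t`` expected photons and is displaced by
    ``z_od * grad / k`` (converted to pixels).  ``seed=None`` renders a
    noiseless frame (no Poisson or read noise, exact dark offset).

    ``move_grid`` selects tomography mode (the modulator raster moves the
    beamlet grid on the detector); planar mode (sample moves instead) keeps
    the grid fixed.
    """
    if flux < 0:
        raise ValueError("flux must be non-negative")
    t_image, gradx, grady = (np.asarray(a, dtype=float) for a in (t_image, gradx, grady))
    if not (t_image.shape == gradx.shape == grady.shape):
        raise ValueError("t and gradient images must share a shape")
    k = geom.wavenumber
    dx_px = geom.z_od * gradx / k / geom.pixel_size
    dy_px = geom.z_od * grady / k / geom.pixel_size
    pitch = geom.grid_pitch_px
    if margin_px is None:
        margin_px = int(math.ceil(pitch))
    off_px = (
        (modulator_offset[0] / geom.pixel_size, modulator_offset[1] / geom.pixel_size)
        if move_grid
        else (0.0, 0.0)
    )
    origin = (margin_px + off_px[0], margin_px + off_px[1])
    n_by, n_bx = t_image.shape
    shape = (
        int(math.ceil((n_by - 1) * pitch + 2 * margin_px + pitch)),
        int(math.ceil((n_bx - 1) * pitch + 2 * margin_px + pitch)),
    )
    rng = np.random.default_rng(seed) if seed is not None else None
    img = _render_grid(
        t_image, dx_px, dy_px, geom, flux, rng, sigma_px, origin, shape, dark_level, read_sigma
    )
    return BeamletFrame(
        intensity=img,
        grid_origin=origin,
        grid_pitch=pitch,
        grid_shape=(n_by, n_bx),
        modulator_offset=tuple(modulator_offset),
    )


def render_flat(
    grid_shape: tuple[int, int],
    geom: SetupGeometry,
    flux: float,
    seed: int | None = None,
    **kwargs,
) -> BeamletFrame:
    """Flat frame: unit transmission, no refraction."""
    ones = np.ones(grid_shape)
    zeros = np.zeros(grid_shape)
    return render_beamlets(ones, zeros, zeros, geom, flux, seed=seed, **kwargs)


def render_dark(
    shape: tuple[int, int],
    seed: int | None = None,
    dark_level: float = DEFAULT_DARK_LEVEL,
    read_sigma: float = DEFAULT_READ_SIGMA,
) -> np.ndarray:
    """Dark frame: constant offset plus Gaussian read noise."""
    if seed is None:
        return np.full(shape, dark_level)
    rng = np.random.default_rng(seed)
    return dark_level + rng.normal(0.0, read_sigma, size=shape)


@dataclass
class ScanSimulation:
    """Output of :func:`simulate_scan`.

    ``frames[(ia, a, b)]`` is the sample frame at angle index ``ia`` and
    raster offset indices ``(a, b)`` (x and y sub-pitch steps);
    ``flats[(a, b)]`` the matching flat frames; ``truth[ia]`` the
    ground-truth projected fields at the full stitched sampling.
    """

    geom: SetupGeometry
    angles: np.ndarray
    frames: dict = field(default_factory=dict)
    flats: dict = field(default_factory=dict)
    dark: np.ndarray | None = None
    truth: list = field(default_factory=list)


def simulate_scan(
    phantom: Phantom,
    geom: SetupGeometry,
    n_projections: int,
    flux: float = 1e4,
    seed: int | None = 0,
    sigma_px: float = DEFAULT_BEAMLET_SIGMA_PX,
    mode: str = "tomography",
    dark_level: float = DEFAULT_DARK_LEVEL,
    read_sigma: float = DEFAULT_READ_SIGMA,
) -> ScanSimulation:
    """Simulate a full scan: all (angle, raster) sample frames plus flats.

    Angles are equally spaced over [0, pi).  The phantom voxel pitch must
    equal the sub-pitch sampling (period / n_subpitch) and its transverse
    size must be a multiple of n_subpitch, so that each beamlet at raster
    offset (a, b) samples exactly one stitched-grid pixel.
    """
    n = geom.n_subpitch
    sp = sampling_pitch(geom)
    if not math.isclose(phantom.voxel_size, sp, rel_tol=1e-9):
        raise ValueError(
            f"phantom voxel size {phantom.voxel_size} must equal the sampling pitch {sp}"
        )
    nz, _, nx = phantom.delta.shape
    if nx % n or nz % n:
        raise ValueError("phantom size must be a multiple of n_subpitch")
    if mode not in ("tomography", "planar"):
        raise ValueError(f"unknown scan mode {mode!r}")
    angles = np.arange(n_projections) * math.pi / n_projections
    k = geom.wavenumber
    sim = ScanSimulation(geom=geom, angles=angles)
    ss = np.random.SeedSequence(seed) if seed is not None else None
    child = iter(ss.spawn(n_projections * n * n + n * n + 1)) if ss is not None else None

    def next_seed():
        return int(next(child).generate_state(1)[0] % 2**31) if child is not None else None

    move_grid = mode == "tomography"
    for a in range(n):
        for b in range(n):
            sim.flats[(a, b)] = render_flat(
                (nz // n, nx // n),
                geom,
                flux,
                seed=next_seed(),
                sigma_px=sigma_px,
                modulator_offset=(a * sp, b * sp),
                dark_level=dark_level,
                read_sigma=read_sigma,
                move_grid=move_grid,
            )
    dark_shape = sim.flats[(0, 0)].intensity.shape
    sim.dark = render_dark(dark_shape, seed=next_seed(), dark_level=dark_level, read_sigma=read_sigma)
    for ia, angle in enumerate(angles):
        fields = project_phantom(phantom, angle, k)
        sim.truth.append(fields)
        for a in range(n):
            for b in range(n):
                t_b = fields.t[b::n, a::n]
                gx_b = fields.gradx[b::n, a::n]
                gy_b = fields.grady[b::n, a::n]
                sim.frames[(ia, a, b)] = render_beamlets(
                    t_b,
                    gx_b,
                    gy_b,
                    geom,
                    flux,
                    seed=next_seed(),
                    sigma_px=sigma_px,
                    modulator_offset=(a * sp, b * sp),
                    dark_level=dark_level,
                    read_sigma=read_sigma,
                    move_grid=move_grid,
                )
    return sim
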