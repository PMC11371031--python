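"""Characterization metrics: angular sensitivity, visibility, trend fits
and Fourier ring correlation (FRC) resolution.

Angular sensitivity is the smallest resolvable refraction angle, estimated
as the standard deviation of retrieved angles in sample-free windows (mean
and standard error over several windows).  Spatial resolution is estimated
from two reconstructions of independent projection halves with FRC and the
3-sigma criterion: resolution is the inverse of the lowest ring frequency
at which the correlation drops below three standard deviations of the
pure-noise correlation, 3 / sqrt(N_ring / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import simulator, tracking
from .core import SetupGeometry

__all__ = [
    "SensitivityEstimate",
    "FRCCurve",
    "angular_sensitivity",
    "visibility",
    "fit_power_law",
    "frc",
    "frc_averaged",
    "crossing_to_resolution",
    "sensitivity_vs_distance",
    "sensitivity_vs_frames",
]


@dataclass
class SensitivityEstimate:
    """Mean/SEM of the per-window std of refraction angles (rad)."""

    sigma_alpha_mean: float
    sigma_alpha_sem: float
    window_shape: tuple[int, int]
    n_windows: int


@dataclass
class FRCCurve:
    """FRC per Fourier ring, its 3-sigma threshold and the crossing.

    ``resolution`` is pitch / crossing_freq in the units of ``pitch``
    (or None when the curve never crosses: sampling-limited).
    """

    freq: np.ndarray  # cycles / px
    frc: np.ndarray
    threshold: np.ndarray
    crossing_freq: float | None
    resolution: float | None
    pitch: float = 1.0

    @property
    def sampling_limited(self) -> bool:
        return self.crossing_freq is None


def angular_sensitivity(
    alpha_map: np.ndarray, windows: list[tuple[slice, slice]]
) -> SensitivityEstimate:
    """Per-window std of the angle map; mean and SEM across windows.

    Windows containing NaN (untracked beamlets) are excluded with a warning.
    """
    stds = []
    shape = None
    for win in windows:
        patch = np.asarray(alpha_map)[win]
        if not np.isfinite(patch).all():
            warnings.warn("window with untracked beamlets excluded from sensitivity")
            continue
        stds.append(patch.std(ddof=1))
        shape = patch.shape
    if len(stds) < 2:
        raise ValueError("need at least 2 valid windows")
    stds = np.array(stds)
    return SensitivityEstimate(
        sigma_alpha_mean=float(stds.mean()),
        sigma_alpha_sem=float(stds.std(ddof=1) / np.sqrt(len(stds))),
        window_shape=tuple(shape),
        n_windows=len(stds),
    )


def visibility(flat_frame, n_bins: int = 64) -> float:
    """Modulation contrast (I_max - I_min)/(I_max + I_min) of the beamlet
    pattern, from the period-folded intensity profile.

    Pixel intensities are folded onto one (pitch x pitch) unit cell of the
    beamlet lattice and bin-averaged; robust 99th/1st percentiles of the
    folded profile stand in for max/min.  Accepts a BeamletFrame or a plain
    array with ``pitch``/``origin`` given via a BeamletFrame only.
    """
    img = flat_frame.intensity.astype(float)
    pitch = flat_frame.grid_pitch
    x0, y0 = flat_frame.grid_origin
    if np.ptp(img) == 0:
        return 0.0
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    fx = np.mod(xx - x0 + pitch / 2.0, pitch)
    fy = np.mod(yy - y0 + pitch / 2.0, pitch)
    bx = np.minimum((fx / pitch * n_bins).astype(int), n_bins - 1)
    by = np.minimum((fy / pitch * n_bins).astype(int), n_bins - 1)
    flatidx = by.ravel() * n_bins + bx.ravel()
    sums = np.bincount(flatidx, weights=img.ravel(), minlength=n_bins * n_bins)
    counts = np.bincount(flatidx, minlength=n_bins * n_bins)
    prof = sums[counts > 0] / counts[counts > 0]
    hi = np.percentile(prof, 99)
    lo = np.percentile(prof, 1)
    if hi + lo == 0:
        return 0.0
    return float((hi - lo) / (hi + lo))


def fit_power_law(x, y) -> tuple[float, float]:
    """Least-squares power-law fit y = A * x**p in log-log space.

    Returns (exponent, prefactor).  Requires >= 3 strictly positive points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 (x, y) pairs")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("power-law fit requires positive data")
    p, loga = np.polyfit(np.log(x), np.log(y), 1)
    return float(p), float(np.exp(loga))


def _ring_labels(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Integer ring index per Fourier pixel and the ring frequencies."""
    ny, nx = shape
    u = np.fft.fftfreq(nx)
    v = np.fft.fftfreq(ny)
    U, V = np.meshgrid(u, v)
    r = np.sqrt(U**2 + V**2)
    n_rings = min(ny, nx) // 2 + 1
    labels = np.minimum(np.round(r * min(ny, nx)).astype(int), n_rings)
    freq = np.arange(n_rings) / min(ny, nx)
    return labels, freq


def _frc_rings(f1: np.ndarray, f2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    labels, freq = _ring_labels(f1.shape)
    n_rings = len(freq)
    lab = labels.ravel()
    cross = np.bincount(lab, weights=np.real(f1 * np.conj(f2)).ravel(), minlength=n_rings + 1)
    crossi = np.bincount(lab, weights=np.imag(f1 * np.conj(f2)).ravel(), minlength=n_rings + 1)
    p1 = np.bincount(lab, weights=(np.abs(f1) ** 2).ravel(), minlength=n_rings + 1)
    p2 = np.bincount(lab, weights=(np.abs(f2) ** 2).ravel(), minlength=n_rings + 1)
    npix = np.bincount(lab, minlength=n_rings + 1)
    num = np.abs(cross[:n_rings] + 1j * crossi[:n_rings])
    den = np.sqrt(p1[:n_rings] * p2[:n_rings])
    with np.errstate(divide="ignore", invalid="ignore"):
        curve = np.where(den > 0, num / den, 0.0)
    return freq, curve, npix[:n_rings]


def _threshold_and_crossing(
    freq: np.ndarray, curve: np.ndarray, npix: np.ndarray, pitch: float
) -> FRCCurve:
    with np.errstate(divide="ignore"):
        thr = np.where(npix > 0, 3.0 / np.sqrt(np.maximum(npix, 1) / 2.0), np.inf)
    crossing = None
    for r in range(1, len(freq)):  # DC ring excluded from the search
        if npix[r] == 0:
            continue
        if thr[r] >= 1.0:
            # FRC <= 1 can never exceed such a threshold; the innermost
            # rings have too few pixels to be informative
            continue
        if curve[r] < thr[r]:
            # sub-ring precision: linear interpolation from the last ring
            # that was still above its threshold
            if r >= 2 and npix[r - 1] > 0 and curve[r - 1] >= thr[r - 1]:
                d0 = curve[r - 1] - thr[r - 1]
                d1 = thr[r] - curve[r]
                crossing = float(freq[r - 1] + (freq[r] - freq[r - 1]) * d0 / (d0 + d1))
            else:
                crossing = float(freq[r])
            break
    res = None if crossing is None or crossing <= 0 else pitch / crossing
    return FRCCurve(
        freq=freq, frc=curve, threshold=thr, crossing_freq=crossing, resolution=res, pitch=pitch
    )


def frc(image_1: np.ndarray, image_2: np.ndarray, pitch: float = 1.0) -> FRCCurve:
    """Fourier ring correlation between two same-shape real images.

    FRC(r) = |sum_r F1 F2*| / sqrt(sum_r |F1|^2 sum_r |F2|^2) over rings of
    one Fourier-pixel width; threshold(r) = 3 / sqrt(N(r)/2).  The crossing
    is the lowest frequency (scanning outward, DC excluded) where the curve
    falls below the threshold, linearly interpolated between rings; absent a
    crossing the resolution is sampling-limited.
    """
    a = np.asarray(image_1, dtype=float)
    b = np.asarray(image_2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    f1 = np.fft.fft2(a - a.mean())
    f2 = np.fft.fft2(b - b.mean())
    freq, curve, npix = _frc_rings(f1, f2)
    return _threshold_and_crossing(freq, curve, npix, pitch)


def frc_averaged(
    volume_1: np.ndarray, volume_2: np.ndarray, slice_indices, pitch: float = 1.0
) -> FRCCurve:
    """FRC averaged over adjacent slices (noise reduction of the estimate).

    The single-slice curves of the given (typically 5 adjacent, mid-volume)
    slices are averaged ring-by-ring, then thresholded as in :func:`frc`.
    """
    slice_indices = list(slice_indices)
    if len(slice_indices) < 1:
        raise ValueError("need at least one slice")
    v1 = np.asarray(volume_1, dtype=float)
    v2 = np.asarray(volume_2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("volumes must share a shape")
    if max(slice_indices) >= v1.shape[0]:
        raise ValueError("slice index outside the volume")
    curves = []
    npix = None
    freq = None
    for s in slice_indices:
        a = v1[s] - v1[s].mean()
        b = v2[s] - v2[s].mean()
        freq, curve, npix = _frc_rings(np.fft.fft2(a), np.fft.fft2(b))
        curves.append(curve)
    mean_curve = np.mean(curves, axis=0)
    return _threshold_and_crossing(freq, mean_curve, npix, pitch)


def crossing_to_resolution(crossing_freq: float | None, pitch: float):
    """Real-space resolution from an FRC crossing frequency.

    ``pitch / crossing_freq`` for a crossing in (0, 0.5] cycles/px; a missing
    crossing means the resolution is sampling-limited (at best the pitch).
    """
    if crossing_freq is None:
        return f"sampling-limited: resolution <= {pitch}"
    if not (0 < crossing_freq <= 0.5):
        raise ValueError("crossing frequency must lie in (0, 0.5] cycles/px")
    return pitch / crossing_freq


# ---------------------------------------------------------------------------
# Empty-beam sensitivity studies (simulate -> track -> std of alpha)
# ---------------------------------------------------------------------------

def _empty_beam_sigma(
    geom: SetupGeometry,
    grid_shape: tuple[int, int],
    flux: float,
    n_avg: int,
    seed: int,
    n_repeats: int = 3,
    window: int = tracking.DEFAULT_WINDOW,
    upsampling: int = tracking.DEFAULT_UPSAMPLING,
) -> float:
    """Std of retrieved refraction angles on empty (sample-free) frames.

    ``n_avg`` noisy empty frames are averaged before tracking against a
    noiseless flat; the pooled std over beamlets and repeats is returned.
    """
    flat = simulator.render_flat(grid_shape, geom, flux, seed=None, dark_level=0.0)
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.spawn(n_repeats * n_avg))
    alphas = []
    for _ in range(n_repeats):
        frames = [
            simulator.render_flat(
                grid_shape,
                geom,
                flux,
                seed=int(next(seeds).generate_state(1)[0] % 2**31),
                dark_level=0.0,
                read_sigma=0.0,
            )
            for _ in range(n_avg)
        ]
        avg = tracking.average_frames(frames)
        maps = tracking.track_frame(avg, flat, None, geom, window=window, upsampling=upsampling)
        alphas.append(maps.alpha_x[np.isfinite(maps.alpha_x)])
    return float(np.concatenate(alphas).std(ddof=1))


def sensitivity_vs_distance(
    z_ods,
    geom: SetupGeometry,
    grid_shape: tuple[int, int] = (12, 12),
    flux: float = 1e3,
    seed: int = 0,
    upsampling: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Angular sensitivity of empty-beam retrieval vs propagation distance.

    The registration noise in pixels is set by photon statistics alone, so
    the angle noise falls as 1/z_od.  Returns (z_ods, sigma_alpha).
    """
    sigmas = []
    for i, z in enumerate(z_ods):
        g = SetupGeometry(
            z_od=z,
            mean_energy=geom.mean_energy,
            pixel_size=geom.pixel_size,
            modulator_period=geom.modulator_period,
            aperture_diameter=geom.aperture_diameter,
            n_subpitch=geom.n_subpitch,
        )
        sigmas.append(
            _empty_beam_sigma(g, grid_shape, flux, 1, seed + 1000 * i, upsampling=upsampling)
        )
    return np.asarray(z_ods, dtype=float), np.array(sigmas)


def sensitivity_vs_frames(
    n_frames_list,
    geom: SetupGeometry,
    grid_shape: tuple[int, int] = (12, 12),
    flux: float = 1e3,
    seed: int = 0,
    upsampling: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Angular sensitivity vs number of averaged frames (Poisson regime).

    Averaging N frames multiplies the photon count by N, so the sensitivity
    improves as N**-1/2 while photon noise dominates.
    """
    sigmas = [
        _empty_beam_sigma(geom, grid_shape, flux, int(n), seed + 1000 * i, upsampling=upsampling)
        for i, n in enumerate(n_frames_list)
    ]
    return np.asarray(n_frames_list, dtype=float), np.array(sigmas)
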